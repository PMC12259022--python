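"""Shared statistical helpers: the moderated two-sample t statistic used by
both the differential-binding and promoter-activity modules, and BH FDR.

The moderated statistic shrinks each feature's pooled variance toward the
across-feature mean variance with a fixed prior weight ``d0`` (an
empirical-Bayes style stabilizer for few-replicate designs); the reference
null is t with ``d0 + n_a + n_b - 2`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PRIOR_DF = 4.0


@dataclass
class ModeratedTestResult:
    mean_a: np.ndarray
    mean_b: np.ndarray
    delta: np.ndarray  # mean_b - mean_a on the input (log) scale
    t: np.ndarray
    p: np.ndarray
    df: float
    s2_prior: float


def moderated_ttest(
    a: np.ndarray, b: np.ndarray, prior_df: float = DEFAULT_PRIOR_DF
) -> ModeratedTestResult:
    """Row-wise moderated two-sample t test.

    Parameters
    ----------
    a, b : arrays of shape (n_features, n_replicates)
        Per-replicate values (normally log2 signal) for the two conditions.
    prior_df : float
        Weight of the shrinkage target (the mean pooled variance across
        features) relative to the per-feature residual degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("a and b must be 2-D with matching row counts")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per condition")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    d_resid = na + nb - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d_resid
    s2_prior = float(np.mean(s2))
    s2_mod = (prior_df * s2_prior + d_resid * s2) / (prior_df + d_resid)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    delta = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    df = prior_df + d_resid
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return ModeratedTestResult(mean_a, mean_b, delta, t, p, df, s2_prior)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
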