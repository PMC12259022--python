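"""Promoter activity from TSS-window signal, two-condition differential
calls, repressed-gene set logic, and the binding-enrichment Fisher test.

Promoter activity is the mean normalized signal in [TSS - 500, TSS + 500)
(strand-symmetric).  Differential calls use the same moderated t statistic
as the differential-binding module, thresholded at p < alpha (default
0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import DEFAULT_PRIOR_DF, bh_adjust, moderated_ttest
from .coverage import DEFAULT_PSEUDOCOUNT, CoverageTrack
from .errors import CswitchError
from .intervals import GeneModel

PROMOTER_HALF_WIDTH = 500


def quantify_promoters(
    genes: list[GeneModel],
    tracks: list[CoverageTrack],
    window: int = PROMOTER_HALF_WIDTH,
) -> pd.DataFrame:
    """Per-gene mean signal over [TSS - window, TSS + window) for each
    replicate track.  Windows truncated at a chromosome start are flagged
    with a warning."""
    values = np.zeros((len(genes), len(tracks)))
    truncated = []
    for i, gene in enumerate(genes):
        start = gene.tss - window
        end = gene.tss + window
        if start < 0:
            truncated.append(gene.gene_id)
            start = 0
        for j, track in enumerate(tracks):
            values[i, j] = track.region_mean(gene.chrom, start, end)
    if truncated:
        warnings.warn(
            f"promoter window truncated at chrom start for {len(truncated)} gene(s)"
        )
    return pd.DataFrame(
        values,
        index=[g.gene_id for g in genes],
        columns=[f"rep{j}" for j in range(len(tracks))],
    )


@dataclass
class DifferentialActivityResult:
    table: pd.DataFrame  # gene, mean_a, mean_b, log2fc, p, q
    up: set[str]
    down: set[str]


def differential_activity(
    signal_a: pd.DataFrame,
    signal_b: pd.DataFrame,
    alpha: float = 0.01,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> DifferentialActivityResult:
    """Moderated differential promoter activity between condition A and B.

    ``signal_a`` / ``signal_b`` are genes x replicates tables from
    :func:`quantify_promoters` over a shared gene index.  Genes with zero
    signal everywhere are dropped with a warning.  ``up`` and ``down`` are
    the gene sets with log2FC > 0 (resp. < 0) at p < alpha — activity
    higher (resp. lower) in condition B.
    """
    if not signal_a.index.equals(signal_b.index):
        raise CswitchError("gene indices differ between conditions")
    if signal_a.shape[1] < 2 or signal_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    a = signal_a.to_numpy(float)
    b = signal_b.to_numpy(float)
    keep = ~((a.sum(axis=1) == 0) & (b.sum(axis=1) == 0))
    if not np.all(keep):
        warnings.warn(f"dropped {int((~keep).sum())} gene(s) with zero signal")
    genes = signal_a.index[keep]
    a, b = a[keep], b[keep]
    res = moderated_ttest(np.log2(a + pseudocount), np.log2(b + pseudocount),
                          prior_df=prior_df)
    q = bh_adjust(res.p)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": res.p,
            "q": q,
        }
    ).set_index("gene_id")
    sig = table["p"] < alpha
    up = set(table.index[sig & (table["log2fc"] > 0)])
    down = set(table.index[sig & (table["log2fc"] < 0)])
    return DifferentialActivityResult(table=table, up=up, down=down)


@dataclass
class GeneSetReport:
    """Repressed/activated set bookkeeping for two comparisons sharing a
    gene universe, plus binding-filtered target subsets."""

    repressed_a: set[str]
    repressed_b: set[str]
    co_repressed: set[str] = field(init=False)
    repressed_a_only: set[str] = field(init=False)
    bound: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.co_repressed = self.repressed_a & self.repressed_b
        self.repressed_a_only = self.repressed_a - self.repressed_b

    @property
    def co_repressed_bound(self) -> set[str]:
        return self.co_repressed & self.bound

    @property
    def repressed_a_only_bound(self) -> set[str]:
        return self.repressed_a_only & self.bound


def gene_set_logic(
    down_a: set[str],
    down_b: set[str],
    bound_genes: set[str],
    universe: set[str],
) -> GeneSetReport:
    """Intersect two repressed-gene sets and annotate binding status.

    All genes must come from the shared quantified universe; unknown ids are
    an error (they indicate a mismatch between quantification and set
    construction).
    """
    for label, s in (("down_a", down_a), ("down_b", down_b), ("bound", bound_genes)):
        outside = s - universe
        if outside:
            raise CswitchError(
                f"{label}: {len(outside)} gene(s) outside the universe, "
                f"e.g. {sorted(outside)[:3]}"
            )
    return GeneSetReport(
        repressed_a=set(down_a), repressed_b=set(down_b), bound=set(bound_genes)
    )


@dataclass
class FisherResult:
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def binding_enrichment_fisher(
    group1: tuple[int, int], group2: tuple[int, int]
) -> FisherResult:
    """Fisher's exact test of binding enrichment between two gene groups.

    ``group1``/``group2`` are (bound, total) pairs; the 2x2 table is
    [[bound1, total1 - bound1], [bound2, total2 - bound2]].  The one-sided
    p tests enrichment of binding in group 1 (alternative "greater"); the
    two-sided p is also reported.  Odds ratio is the sample (a*d)/(b*c).
    """
    (a, n1), (c, n2) = group1, group2
    if a > n1 or c > n2 or min(a, c, n1 - a, n2 - c) < 0:
        raise ValueError("bound counts must satisfy 0 <= bound <= total")
    b, d = n1 - a, n2 - c
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table: a zero margin; p = 1")
        return FisherResult(float("nan"), 1.0, 1.0, table, degenerate=True)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    _, p_greater = stats.fisher_exact(table, alternative="greater")
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(odds, float(p_greater), float(p_two), table)
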