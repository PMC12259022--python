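"""Statistics on per-cell dot-count tables from multiplexed single-molecule
in situ experiments.

Each row of the count table is a cell with a tissue-region label (CH or
ChP), a genotype (wt or mut) and a replicate id; each gene column holds the
integer dot count (~ one dot per mRNA).  Group comparisons use the ROC AUC
with the half-credit tie convention — the probability that a random cell of
group 2 has a higher count than a random cell of group 1, plus half the tie
probability — whose null is the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CswitchError

REGIONS = ("CH", "ChP")
GENOTYPES = ("wt", "mut")
META_COLUMNS = ("cell_id", "region", "genotype", "replicate")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a per-cell dot-count table (cell_id, region, genotype,
    replicate, one integer column per gene)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise CswitchError(f"counts table missing columns: {sorted(missing)}")
    bad_region = set(df["region"]) - set(REGIONS)
    bad_geno = set(df["genotype"]) - set(GENOTYPES)
    if bad_region or bad_geno:
        raise CswitchError(
            f"unknown region/genotype labels: {sorted(bad_region | bad_geno)}"
        )
    genes = [c for c in df.columns if c not in META_COLUMNS]
    for g in genes:
        col = df[g]
        if (col < 0).any() or not np.allclose(col, col.astype(int)):
            raise CswitchError(f"gene {g}: counts must be nonnegative integers")
        df[g] = col.astype(int)
    return df


def gene_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


@dataclass
class AucResult:
    auc: float
    p: float
    n1: int
    n2: int


def auc_compare(group1: np.ndarray, group2: np.ndarray) -> AucResult:
    """ROC AUC for group2 > group1 with half credit for ties, and the
    two-sided rank-sum p value."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise CswitchError("both groups must be nonempty")
    u = stats.mannwhitneyu(g2, g1, alternative="two-sided")
    auc = u.statistic / (len(g1) * len(g2))
    return AucResult(float(auc), float(u.pvalue), len(g1), len(g2))


def genotype_auc_table(
    counts: pd.DataFrame,
    genes: list[str] | None = None,
    region: str | None = None,
) -> pd.DataFrame:
    """Per-gene wt-vs-mut AUC, cells pooled across replicates, plus a
    per-replicate mean-count breakdown."""
    genes = genes or gene_columns(counts)
    sub = counts if region is None else counts[counts["region"] == region]
    wt = sub[sub["genotype"] == "wt"]
    mut = sub[sub["genotype"] == "mut"]
    rows = []
    for g in genes:
        res = auc_compare(wt[g].to_numpy(), mut[g].to_numpy())
        row = {
            "gene": g,
            "region": region or "all",
            "auc_mut_vs_wt": res.auc,
            "p": res.p,
            "n_wt": res.n1,
            "n_mut": res.n2,
        }
        for (geno, rep), grp in sub.groupby(["genotype", "replicate"]):
            row[f"mean_{geno}_rep{rep}"] = float(grp[g].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(
    counts: pd.DataFrame, genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise product-moment correlation across cells with two-sided p
    values.  Zero-variance genes yield NaN entries (flagged via warning by
    scipy's constant-input path being bypassed here)."""
    genes = genes or gene_columns(counts)
    if len(counts) < 3:
        raise CswitchError("need >= 3 cells for correlation")
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    p = pd.DataFrame(np.zeros((len(genes), len(genes))), index=genes, columns=genes)
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if j <= i:
                continue
            x = counts[gi].to_numpy(float)
            y = counts[gj].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = float("nan"), float("nan")
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[gi, gj] = r.loc[gj, gi] = rij
            p.loc[gi, gj] = p.loc[gj, gi] = pij
            p.loc[gi, gi] = 0.0
    return r, p


@dataclass
class MultivarFit:
    response: str
    predictors: list[str]
    intercept: float
    coefficients: pd.Series
    r_squared: float
    n: int


def multivar_fit(
    counts: pd.DataFrame, response: str, predictors: list[str]
) -> MultivarFit:
    """Ordinary least squares of one gene's counts on several others.

    Raises on exactly collinear predictors, naming an offending pair.
    """
    y = counts[response].to_numpy(float)
    x = counts[list(predictors)].to_numpy(float)
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for i in range(len(predictors)):
            for j in range(i + 1, len(predictors)):
                xi, xj = x[:, i], x[:, j]
                if np.std(xi) == 0 or np.std(xj) == 0 or abs(
                    np.corrcoef(xi, xj)[0, 1]
                ) > 1 - 1e-12:
                    raise CswitchError(
                        f"collinear predictors: {predictors[i]} and {predictors[j]}"
                    )
        raise CswitchError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MultivarFit(
        response=response,
        predictors=list(predictors),
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=list(predictors)),
        r_squared=r2,
        n=len(y),
    )
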