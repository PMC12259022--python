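"""Co-binding classification, occupancy-dependence testing and relocation
statistics.

This is the analytical core: SMAD-type binding sites are stratified by
whether a co-factor peak overlaps them (>= 1 bp), the co-factor dependence
of their occupancy is tested between genotypes, and non-co-bound sites
lying within a distance window (default 200 kb) of a co-bound site are
examined for gained ("ectopic") binding in the co-factor-null condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import DEFAULT_PRIOR_DF, bh_adjust, moderated_ttest
from .coverage import DEFAULT_PSEUDOCOUNT, CoverageTrack
from .intervals import GenomicInterval, merge_direct_overlap

DEFAULT_SITE_WINDOW = 500  # half-width of the per-site signal window (bp)
DEFAULT_RELOCATION_WINDOW = 200_000


@dataclass
class CoBindingRecord:
    """One SMAD-type site with its co-binding status.

    ``nearest_cobound_distance`` is the summit-to-summit distance to the
    nearest co-bound site: 0 for co-bound sites themselves, ``inf`` for
    sites on chromosomes without any co-bound site.
    """

    site_id: str
    interval: GenomicInterval
    cobound: bool
    summit: int
    nearest_cobound_distance: float = math.inf


@dataclass
class DifferentialRecord:
    """Per-site two-condition comparison."""

    site_id: str
    site_class: str  # cobound / flanking / solo
    mean_a: float
    mean_b: float
    log2fc: float
    p: float
    q: float = float("nan")


def classify_cobound(
    smad_peaks: list[GenomicInterval],
    cofactor_peaks: list[GenomicInterval],
) -> list[CoBindingRecord]:
    """Label each SMAD peak co-bound iff it overlaps (>= 1 bp) a co-factor
    peak; for solo sites compute the distance to the nearest co-bound
    summit.

    Both inputs should already be merged within themselves.  Summits default
    to interval midpoints when the peak caller did not set one.
    """
    smad = merge_direct_overlap(smad_peaks)
    cof = merge_direct_overlap(cofactor_peaks)
    cof_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in cof:
        cof_by_chrom.setdefault(iv.chrom, []).append(iv)

    names = [iv.name for iv in smad]
    # input names are kept only when they identify sites unambiguously
    use_names = all(names) and len(set(names)) == len(names)
    records: list[CoBindingRecord] = []
    for i, iv in enumerate(smad):
        hits = [
            c
            for c in cof_by_chrom.get(iv.chrom, [])
            if c.start < iv.end and iv.start < c.end
        ]
        summit = iv.summit if iv.summit is not None else iv.midpoint
        records.append(
            CoBindingRecord(
                site_id=iv.name if use_names else f"site_{i:05d}",
                interval=iv,
                cobound=bool(hits),
                summit=summit,
            )
        )
    cobound_summits: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.cobound:
            cobound_summits.setdefault(rec.interval.chrom, []).append(rec.summit)
    cobound_summits = {c: np.sort(np.array(v)) for c, v in cobound_summits.items()}
    for rec in records:
        if rec.cobound:
            rec.nearest_cobound_distance = 0.0
        else:
            arr = cobound_summits.get(rec.interval.chrom)
            if arr is None or len(arr) == 0:
                rec.nearest_cobound_distance = math.inf
            else:
                rec.nearest_cobound_distance = float(
                    np.min(np.abs(arr - rec.summit))
                )
    return records


def site_signal_matrix(
    records: list[CoBindingRecord],
    tracks: list[CoverageTrack],
    window: int = DEFAULT_SITE_WINDOW,
) -> np.ndarray:
    """Per-site mean normalized coverage in [summit - window, summit + window)
    for each replicate track: shape (n_sites, n_tracks)."""
    out = np.zeros((len(records), len(tracks)))
    for i, rec in enumerate(records):
        start = max(0, rec.summit - window)
        end = rec.summit + window
        for j, track in enumerate(tracks):
            out[i, j] = track.region_mean(rec.interval.chrom, start, end)
    return out


@dataclass
class DependenceSummary:
    stratum: str
    n_sites: int
    mean_a: float
    mean_b: float
    mean_log2fc: float
    t: float
    p: float


def dependence_test(
    records: list[CoBindingRecord],
    tracks_a: list[CoverageTrack],
    tracks_b: list[CoverageTrack],
    window: int = DEFAULT_SITE_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DependenceSummary]:
    """Two-tailed paired-by-site t test of per-site mean coverage between
    conditions, per co-binding stratum.

    Each site contributes its across-replicate mean per condition; the test
    pairs the two values site by site.  With identical conditions the
    difference is exactly zero for every site and p is reported as 1.
    """
    sig_a = site_signal_matrix(records, tracks_a, window).mean(axis=1)
    sig_b = site_signal_matrix(records, tracks_b, window).mean(axis=1)
    out = []
    for stratum, flag in (("cobound", True), ("solo", False)):
        idx = np.array([r.cobound == flag for r in records])
        n = int(idx.sum())
        if n == 0:
            continue
        a, b = sig_a[idx], sig_b[idx]
        log2fc = float(
            np.mean(np.log2((b + pseudocount) / (a + pseudocount)))
        )
        if n < 2:
            warnings.warn(f"stratum {stratum}: single site, p undefined")
            t_stat, p = float("nan"), float("nan")
        elif np.allclose(a, b):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(b, a)
        out.append(
            DependenceSummary(
                stratum, n, float(a.mean()), float(b.mean()), log2fc,
                float(t_stat), float(p),
            )
        )
    return out


def flanking_sites(
    records: list[CoBindingRecord],
    window: int = DEFAULT_RELOCATION_WINDOW,
) -> list[CoBindingRecord]:
    """Non-co-bound sites whose summit lies within +/- window of at least one
    co-bound summit (the co-bound sites themselves are excluded).  A site
    near several co-bound sites is returned once."""
    return [
        r
        for r in records
        if not r.cobound and r.nearest_cobound_distance <= window
    ]


def differential_binding(
    sites: list[CoBindingRecord],
    tracks_a: list[CoverageTrack],
    tracks_b: list[CoverageTrack],
    fdr: float = 0.1,
    window: int = DEFAULT_SITE_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float = DEFAULT_PRIOR_DF,
    site_classes: dict[str, str] | None = None,
) -> tuple[list[DifferentialRecord], pd.DataFrame]:
    """Moderated per-site differential occupancy between two conditions.

    Per-site per-replicate signal is the mean normalized coverage in a
    +/- ``window`` bp window around the summit, log2-transformed with a
    pseudocount; a moderated two-sample t statistic (variance shrunk toward
    the across-site mean with prior weight ``prior_df``) yields p values,
    BH-adjusted jointly across all tested sites.  Significance is q < fdr.

    Returns the per-site records plus a per-class summary table with mean
    log2 fold changes and significant-site counts.
    """
    if len(tracks_a) < 2 or len(tracks_b) < 2:
        raise ValueError("need >= 2 replicate tracks per condition")
    classes = site_classes or {
        r.site_id: ("cobound" if r.cobound else "flanking")
        for r in sites
    }
    mat_a = site_signal_matrix(sites, tracks_a, window)
    mat_b = site_signal_matrix(sites, tracks_b, window)
    keep = ~((mat_a.sum(axis=1) == 0) & (mat_b.sum(axis=1) == 0))
    if not np.all(keep):
        warnings.warn(f"dropped {int((~keep).sum())} site(s) with zero signal")
    sites = [s for s, k in zip(sites, keep) if k]
    mat_a, mat_b = mat_a[keep], mat_b[keep]
    if len(sites) == 0:
        return [], pd.DataFrame()
    la = np.log2(mat_a + pseudocount)
    lb = np.log2(mat_b + pseudocount)
    res = moderated_ttest(la, lb, prior_df=prior_df)
    q = bh_adjust(res.p)
    mean_a = mat_a.mean(axis=1)
    mean_b = mat_b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    records = [
        DifferentialRecord(
            site_id=s.site_id,
            site_class=classes.get(s.site_id, "solo"),
            mean_a=float(mean_a[i]),
            mean_b=float(mean_b[i]),
            log2fc=float(log2fc[i]),
            p=float(res.p[i]),
            q=float(q[i]),
        )
        for i, s in enumerate(sites)
    ]
    df = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "class": r.site_class,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "significant": r.q < fdr,
            }
            for r in records
        ]
    )
    summary = (
        df.groupby("class")
        .agg(
            n_sites=("site_id", "size"),
            mean_log2fc=("log2fc", "mean"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    return records, summary


def volcano_table(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "class": r.site_class,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
            }
            for r in records
        ]
    )
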