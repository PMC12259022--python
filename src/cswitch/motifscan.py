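"""IUPAC degenerate-motif scanning and peak-level motif statistics.

Matches are reported on both strands.  A pattern that equals its own
reverse complement (e.g. the SMAD palindrome GTCTAGAC) produces identical
match sets on the two strands, so such matches are reported once with
strand ".".

The built-in motif catalogue covers the two GTCT-based SMAD motifs (the
palindrome and the GTCT direct repeat), two GC-rich SMAD-binding elements,
and an AP1 site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import CswitchError
from .intervals import GenomicInterval

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

MOTIF_CLASSES = ("palindromic", "direct_repeat", "gc_rich", "ap1")


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC-encoded motif with a class label."""

    name: str
    iupac: str
    motif_class: str

    def __post_init__(self) -> None:
        if len(self.iupac) < 4:
            raise CswitchError(f"motif {self.name}: length must be >= 4")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise CswitchError(
                f"motif {self.name}: invalid IUPAC letter(s) {sorted(bad)}"
            )
        if self.motif_class not in MOTIF_CLASSES:
            raise CswitchError(f"motif {self.name}: unknown class {self.motif_class}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    @property
    def is_palindrome(self) -> bool:
        return self.iupac == reverse_complement_iupac(self.iupac)


def reverse_complement_iupac(pattern: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))


# Motif catalogue.  The GC-rich element written "GGCGCC-AN4-GNCV" is read
# as GGCGCC + A + NNNN + GNCV; the AN4 spacer reading is configurable by
# supplying a custom pattern table.
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("SBE_palindrome", "GTCTAGAC", "palindromic"),
    MotifPattern("GTCT_repeat", "GTCTGTCTGTCT", "direct_repeat"),
    MotifPattern("GC_SBE_1", "GGCGCCANNNNGNCV", "gc_rich"),
    MotifPattern("GC_SBE_2", "GRCGNCNNNNNGTCT", "gc_rich"),
    MotifPattern("AP1", "TGASTCA", "ap1"),
)


def _regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern
    )
    return re.compile(f"(?=({body}))")


def iupac_scan(pattern: MotifPattern | str, sequence: str) -> list[tuple[int, str]]:
    """All match offsets of an IUPAC pattern in a DNA sequence, both strands.

    Returns (offset, strand) pairs, offsets on the forward strand.  A minus
    strand match at offset i means the reverse complement of the pattern
    matches the forward sequence at i.  Self-reverse-complement patterns
    are reported once per offset with strand ".".
    """
    if isinstance(pattern, str):
        pattern = MotifPattern("adhoc", pattern, "palindromic"
                               if pattern.upper() == reverse_complement_iupac(pattern)
                               else "gc_rich")
    seq = sequence.upper()
    fwd = [(m.start(), "+") for m in _regex(pattern.iupac).finditer(seq)]
    if pattern.is_palindrome:
        return [(off, ".") for off, _ in fwd]
    rc = reverse_complement_iupac(pattern.iupac)
    rev = [(m.start(), "-") for m in _regex(rc).finditer(seq)]
    return sorted(fwd + rev)


def peak_motif_counts(
    peaks: Sequence[GenomicInterval],
    genome: dict[str, str],
    patterns: Iterable[MotifPattern] = DEFAULT_MOTIFS,
) -> pd.DataFrame:
    """Count matches fully contained in each peak, per pattern.

    Returns a DataFrame indexed by peak name (or ``chrom:start-end`` when
    unnamed) with one integer column per motif name.
    """
    patterns = list(patterns)
    rows = {}
    for pk in peaks:
        if pk.chrom not in genome:
            raise CswitchError(f"peak {pk.name or pk.chrom}: unknown chromosome")
        if pk.end > len(genome[pk.chrom]):
            raise CswitchError(
                f"peak {pk.name or f'{pk.chrom}:{pk.start}-{pk.end}'} "
                "extends beyond chromosome end"
            )
        seq = genome[pk.chrom][pk.start : pk.end]
        key = pk.name or f"{pk.chrom}:{pk.start}-{pk.end}"
        rows[key] = {p.name: len(iupac_scan(p, seq)) for p in patterns}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[p.name for p in patterns], dtype=int
    )


def binned_frequency(
    peaks: Sequence[GenomicInterval],
    cobound: Sequence[bool],
    counts: pd.DataFrame,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Motif occurrence frequency across score-binned peaks, per co-binding
    stratum.

    Within each stratum (co-bound / solo), peaks are ranked by score and cut
    into ``n_bins`` equal-count bins (bin 1 = lowest scores; edge ties are
    broken by rank order).  The primary frequency is the fraction of the
    bin's peaks containing at least one match; ``matches_per_kb`` is emitted
    as a secondary density column.
    """
    if len(peaks) != len(cobound):
        raise ValueError("peaks and cobound flags differ in length")
    motif_names = list(counts.columns)
    records = []
    for stratum, flag in (("cobound", True), ("solo", False)):
        idx = [i for i, f in enumerate(cobound) if bool(f) == flag]
        if not idx:
            continue
        if len(idx) < n_bins:
            raise CswitchError(
                f"stratum {stratum!r} has {len(idx)} peaks, fewer than "
                f"{n_bins} bins; use fewer bins"
            )
        order = sorted(idx, key=lambda i: (peaks[i].score, i))
        # equal-count bins, lowest scores first
        edges = [round(j * len(order) / n_bins) for j in range(n_bins + 1)]
        for b in range(n_bins):
            members = order[edges[b] : edges[b + 1]]
            keys = [
                peaks[i].name or f"{peaks[i].chrom}:{peaks[i].start}-{peaks[i].end}"
                for i in members
            ]
            sub = counts.loc[keys]
            widths_kb = sum(peaks[i].width for i in members) / 1000.0
            for m in motif_names:
                n_with = int((sub[m] > 0).sum())
                records.append(
                    {
                        "bin": b + 1,
                        "stratum": stratum,
                        "motif": m,
                        "n_peaks": len(members),
                        "n_with_match": n_with,
                        "frequency": n_with / len(members),
                        "matches_per_kb": float(sub[m].sum()) / widths_kb,
                    }
                )
    return pd.DataFrame.from_records(records)


def read_motif_tsv(path) -> list[MotifPattern]:
    """Read a motif table with columns name, iupac, class."""
    df = pd.read_csv(path, sep="\t")
    return [
        MotifPattern(r["name"], r["iupac"], r["class"]) for _, r in df.iterrows()
    ]


def write_motif_tsv(patterns: Iterable[MotifPattern], path) -> None:
    pd.DataFrame(
        [(p.name, p.iupac, p.motif_class) for p in patterns],
        columns=["name", "iupac", "class"],
    ).to_csv(path, sep="\t", index=False)
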