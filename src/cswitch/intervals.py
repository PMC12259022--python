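"""Genomic interval algebra.

All coordinates are 0-based half-open, as in BED and bedGraph.  "Direct
overlap" means at least one shared base: book-ended intervals
([100,200) and [200,300)) do not overlap and are never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import BedFormatError

STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A scored, stranded half-open genomic region with an optional summit.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open coordinates; ``start < end``.
    name : str
        Feature name (BED column 4); empty string if absent.
    score : float
        Non-negative signal total associated with the region.
    strand : str
        One of ``+``, ``-`` or ``.``.
    summit : int or None
        Absolute position of maximum signal, in ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise BedFormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in STRANDS:
            raise BedFormatError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise BedFormatError(
                f"summit {self.summit} outside [{self.start},{self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class VennCounts:
    """Two-set peak Venn bookkeeping: loci private to each set plus shared loci.

    ``only_a`` are "lost" and ``only_b`` "gained" when A is the reference
    condition and B the comparison.
    """

    only_a: int
    only_b: int
    common: int

    @property
    def total_a(self) -> int:
        return self.only_a + self.common

    @property
    def total_b(self) -> int:
        return self.only_b + self.common

    @classmethod
    def from_totals(cls, total_a: int, total_b: int, only_a: int) -> "VennCounts":
        """Complete the Venn from set totals and the count private to A.

        ``common = total_a - only_a`` and ``only_b = total_b - common``;
        this is the arithmetic used to read a two-set Venn from published
        set sizes.
        """
        common = total_a - only_a
        if common < 0 or common > total_b:
            raise ValueError("inconsistent Venn totals")
        return cls(only_a=only_a, only_b=total_b - common, common=common)


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end, iv.name)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=_sort_key)


def parse_bed(path) -> list[GenomicInterval]:
    """Parse a 3+ column tab-separated BED file.

    Missing score/strand columns default to 0 and ".".  A seventh column,
    when present and integral, is read as a summit offset relative to
    ``start`` (the convention used by this package's peak caller output).
    Malformed lines raise :class:`BedFormatError` citing the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            summit = None
            if len(fields) > 6 and fields[6] not in ("", "."):
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise BedFormatError(
                        f"{path}: line {lineno}: bad summit offset"
                    ) from exc
            try:
                out.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except BedFormatError as exc:
                raise BedFormatError(f"{path}: line {lineno}: {exc}") from exc
    return sort_intervals(out)


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write BED6(+summit offset) with tab separation."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name or ".",
                f"{iv.score:g}",
                iv.strand,
            ]
            if iv.summit is not None:
                cols.append(str(iv.summit - iv.start))
            fh.write("\t".join(cols) + "\n")


def merge_direct_overlap(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge every maximal chain of directly (>=1 bp) overlapping intervals.

    The merged interval spans the union of its members, its score is the
    sum of member scores, and its summit is taken from the highest-scoring
    member carrying one.  Book-ended intervals are left separate.
    """
    ivs = sort_intervals(intervals)
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    cur_best: GenomicInterval | None = None
    for iv in ivs:
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            new_end = max(cur.end, iv.end)
            if cur_best is None or (iv.summit is not None and iv.score > cur_best.score):
                if iv.summit is not None:
                    cur_best = iv
            cur = replace(cur, end=new_end, score=cur.score + iv.score,
                          summit=cur_best.summit if cur_best else None)
        else:
            if cur is not None:
                merged.append(cur)
            cur_best = iv if iv.summit is not None else None
            cur = replace(iv)
    if cur is not None:
        merged.append(cur)
    return merged


def consensus_common(
    replicate_peaksets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Consensus peaks supported by every replicate.

    Candidate loci are the merged union of all replicate peaks; a locus is
    kept iff at least one peak from *every* replicate contributed to it.
    The returned coordinates span the merged union of the supporting peaks.
    """
    if len(replicate_peaksets) < 2:
        raise ValueError("consensus requires >= 2 replicates")
    for i, peaks in enumerate(replicate_peaksets):
        if len(peaks) == 0:
            warnings.warn(f"replicate {i} has no peaks; consensus is empty")
            return []
    tagged: list[GenomicInterval] = []
    for rep_idx, peaks in enumerate(replicate_peaksets):
        for iv in peaks:
            tagged.append(replace(iv, name=f"rep{rep_idx}"))
    tagged = sort_intervals(tagged)
    n_reps = len(replicate_peaksets)
    out: list[GenomicInterval] = []
    # sweep chains of direct overlap, tracking which replicates contribute
    chain: list[GenomicInterval] = []
    chain_end = -1

    def flush():
        if not chain:
            return
        reps = {iv.name for iv in chain}
        if len(reps) == n_reps:
            start = min(iv.start for iv in chain)
            end = max(iv.end for iv in chain)
            score = sum(iv.score for iv in chain)
            out.append(
                GenomicInterval(chain[0].chrom, start, end, "", score, ".")
            )

    for iv in tagged:
        if chain and iv.chrom == chain[0].chrom and iv.start < chain_end:
            chain.append(iv)
            chain_end = max(chain_end, iv.end)
        else:
            flush()
            chain = [iv]
            chain_end = iv.end
    flush()
    for i, iv in enumerate(out):
        iv.name = f"consensus_{i}"
    return out


def venn(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> tuple[VennCounts, dict[str, list[GenomicInterval]]]:
    """Two-set Venn of merged peak loci.

    Both sets are merged internally, then merged jointly; each joint locus
    is labelled ``lost`` (members from A only), ``gained`` (B only) or
    ``common`` (both), so a shared locus is counted once.
    """
    a = [replace(iv, name="A") for iv in merge_direct_overlap(set_a)]
    b = [replace(iv, name="B") for iv in merge_direct_overlap(set_b)]
    tagged = sort_intervals(a + b)
    labels: dict[str, list[GenomicInterval]] = {"lost": [], "gained": [], "common": []}
    chain: list[GenomicInterval] = []
    chain_end = -1

    def flush():
        if not chain:
            return
        sets = {iv.name for iv in chain}
        locus = GenomicInterval(
            chain[0].chrom,
            min(iv.start for iv in chain),
            max(iv.end for iv in chain),
            "",
            sum(iv.score for iv in chain),
            ".",
        )
        if sets == {"A"}:
            labels["lost"].append(locus)
        elif sets == {"B"}:
            labels["gained"].append(locus)
        else:
            labels["common"].append(locus)

    for iv in tagged:
        if chain and iv.chrom == chain[0].chrom and iv.start < chain_end:
            chain.append(iv)
            chain_end = max(chain_end, iv.end)
        else:
            flush()
            chain = [iv]
            chain_end = iv.end
    flush()
    counts = VennCounts(
        only_a=len(labels["lost"]),
        only_b=len(labels["gained"]),
        common=len(labels["common"]),
    )
    return counts, labels


@dataclass
class GeneModel:
    """Minimal gene annotation: a TSS with a strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


def read_genes_tsv(path) -> list[GeneModel]:
    """Read the 4-column genes table (gene_id, chrom, tss, strand; 0-based)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gid = f[idx["gene_id"]]
            if gid in seen:
                raise BedFormatError(f"duplicate gene id {gid}")
            seen.add(gid)
            genes.append(
                GeneModel(gid, f[idx["chrom"]], int(f[idx["tss"]]), f[idx["strand"]])
            )
    return genes


def promoter_window(gene: GeneModel, window: int = 500) -> GenomicInterval:
    """Promoter region [TSS - window, TSS + window); strand-symmetric."""
    return GenomicInterval(
        gene.chrom, max(0, gene.tss - window), gene.tss + window, gene.gene_id
    )


def assign_to_promoters(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 500,
) -> dict[str, list[GenomicInterval]]:
    """Map peaks to promoters: a peak maps to every gene whose
    [TSS-window, TSS+window) promoter it overlaps by >= 1 bp.

    Returns a gene_id -> peaks dict covering every gene (empty lists for
    unbound genes).  Genes on chromosomes absent from the peak set simply
    receive no peaks.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for pk in sort_intervals(peaks):
        by_chrom.setdefault(pk.chrom, []).append(pk)
    result: dict[str, list[GenomicInterval]] = {}
    for gene in genes:
        prom = promoter_window(gene, window)
        hits = [
            pk
            for pk in by_chrom.get(gene.chrom, [])
            if pk.start < prom.end and prom.start < pk.end
        ]
        result[gene.gene_id] = hits
    return result


def bound_genes(
    assignment: dict[str, list[GenomicInterval]]
) -> set[str]:
    """Gene ids with at least one assigned peak."""
    return {g for g, pks in assignment.items() if pks}
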