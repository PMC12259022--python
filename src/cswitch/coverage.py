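"""Per-base signal tracks stored as run-length runs, with library
normalization (reads per million per base, RPM), summit finding and
summit-centred signal matrices.

Bases not covered by any run read as 0.  Tracks share the 0-based
half-open coordinate convention of the interval module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BedFormatError, TrackStateError
from .intervals import GenomicInterval

DEFAULT_PSEUDOCOUNT = 0.1  # RPM added before ratios / log fold changes


@dataclass
class _ChromRuns:
    starts: np.ndarray  # int64, sorted, non-overlapping
    ends: np.ndarray
    values: np.ndarray  # float64, > 0 entries only after compaction


@dataclass
class CoverageTrack:
    """Sparse per-base coverage with library-size metadata.

    ``library_size`` is the total signal (sum of value x run length); for a
    raw count track this is the read count used for RPM scaling.
    """

    runs: dict[str, _ChromRuns] = field(default_factory=dict)
    library_size: float = 0.0
    normalized: bool = False

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_dense(cls, arrays: dict[str, np.ndarray],
                   normalized: bool = False) -> "CoverageTrack":
        """Build a track from dense per-base arrays (one per chromosome)."""
        track = cls(normalized=normalized)
        total = 0.0
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            total += float(arr.sum())
            track.runs[chrom] = _rle(arr)
        track.library_size = total
        return track

    @classmethod
    def from_positions(cls, positions: dict[str, np.ndarray]) -> "CoverageTrack":
        """Build a raw count track from per-base read positions (one array of
        integer positions per chromosome; duplicates accumulate)."""
        track = cls(normalized=False)
        total = 0.0
        for chrom, pos in positions.items():
            uniq, cnt = np.unique(np.asarray(pos, dtype=np.int64),
                                  return_counts=True)
            total += float(cnt.sum())
            if len(uniq) == 0:
                z = np.zeros(0, dtype=np.int64)
                track.runs[chrom] = _ChromRuns(z, z.copy(), np.zeros(0))
                continue
            # merge adjacent bases with equal counts into single runs
            brk = np.flatnonzero((np.diff(uniq) != 1) | (np.diff(cnt) != 0)) + 1
            first = np.concatenate(([0], brk))
            last = np.concatenate((brk, [len(uniq)])) - 1
            track.runs[chrom] = _ChromRuns(
                uniq[first], uniq[last] + 1, cnt[first].astype(float)
            )
        track.library_size = total
        return track

    @classmethod
    def read_bedgraph(cls, path, library_size: float | None = None,
                      normalized: bool = False) -> "CoverageTrack":
        """Read a 4-column bedGraph.  If ``library_size`` is None it is set
        to the track's own total signal (appropriate for raw count tracks)."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) != 4:
                    raise BedFormatError(f"{path}: line {lineno}: expected 4 columns")
                try:
                    start, end, value = int(f[1]), int(f[2]), float(f[3])
                except ValueError as exc:
                    raise BedFormatError(f"{path}: line {lineno}: bad fields") from exc
                if start >= end:
                    raise BedFormatError(f"{path}: line {lineno}: start >= end")
                per_chrom.setdefault(f[0], []).append((start, end, value))
        track = cls(normalized=normalized)
        total = 0.0
        for chrom, triplets in per_chrom.items():
            triplets.sort()
            starts = np.array([t[0] for t in triplets], dtype=np.int64)
            ends = np.array([t[1] for t in triplets], dtype=np.int64)
            values = np.array([t[2] for t in triplets], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise BedFormatError(f"{path}: overlapping runs on {chrom}")
            total += float(np.sum(values * (ends - starts)))
            track.runs[chrom] = _ChromRuns(starts, ends, values)
        track.library_size = total if library_size is None else library_size
        return track

    # --------------------------------------------------------------- queries
    @property
    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def chrom_end(self, chrom: str) -> int:
        cr = self.runs.get(chrom)
        return int(cr.ends[-1]) if cr is not None and len(cr.ends) else 0

    def total_signal(self) -> float:
        return sum(
            float(np.sum(cr.values * (cr.ends - cr.starts)))
            for cr in self.runs.values()
        )

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense values over [start, end); positions outside any run are 0."""
        if end <= start:
            raise ValueError("empty window")
        out = np.zeros(end - start, dtype=float)
        cr = self.runs.get(chrom)
        if cr is None or len(cr.starts) == 0:
            return out
        lo = int(np.searchsorted(cr.ends, start, side="right"))
        hi = int(np.searchsorted(cr.starts, end, side="left"))
        if lo >= hi:
            return out
        s = np.maximum(cr.starts[lo:hi], start) - start
        e = np.minimum(cr.ends[lo:hi], end) - start
        widths = e - s
        total = int(widths.sum())
        begin = np.cumsum(widths) - widths
        idx = np.arange(total) - np.repeat(begin, widths) + np.repeat(s, widths)
        out[idx] = np.repeat(cr.values[lo:hi], widths)
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        cr = self.runs.get(chrom)
        if cr is None or len(cr.starts) == 0:
            return 0.0
        lo = int(np.searchsorted(cr.ends, start, side="right"))
        hi = int(np.searchsorted(cr.starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(cr.starts[lo:hi], start)
        e = np.minimum(cr.ends[lo:hi], end)
        return float(np.sum(cr.values[lo:hi] * (e - s)))

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        return self.region_sum(chrom, start, end) / (end - start)

    # ----------------------------------------------------------------- I/O
    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                cr = self.runs[chrom]
                for s, e, v in zip(cr.starts, cr.ends, cr.values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _rle(arr: np.ndarray) -> _ChromRuns:
    """Run-length encode a dense array, dropping zero runs."""
    if arr.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return _ChromRuns(z, z.copy(), np.zeros(0))
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    values = arr[starts]
    keep = values != 0
    return _ChromRuns(
        starts[keep].astype(np.int64), ends[keep].astype(np.int64), values[keep]
    )


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw count track to reads per million per base."""
    if track.normalized:
        raise TrackStateError("track is already RPM-normalized")
    if track.library_size <= 0:
        raise TrackStateError("library size must be positive")
    factor = 1e6 / track.library_size
    out = CoverageTrack(library_size=track.library_size, normalized=True)
    for chrom, cr in track.runs.items():
        out.runs[chrom] = _ChromRuns(
            cr.starts.copy(), cr.ends.copy(), cr.values * factor
        )
    return out


def _value_at(cr: _ChromRuns | None, pos: np.ndarray) -> np.ndarray:
    """Vectorized point lookup into a run list."""
    out = np.zeros(len(pos), dtype=float)
    if cr is None or len(cr.starts) == 0:
        return out
    idx = np.searchsorted(cr.starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= cr.ends[idx[ok]] > pos[ok]
    out[ok] = cr.values[idx[ok]]
    return out


def input_normalize(
    chip: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CoverageTrack:
    """Per-base enrichment ratio (chip + c) / (control + c).

    Both tracks must be RPM-normalized and cover the same assembly
    (identical chromosome name sets).
    """
    if not (chip.normalized and control.normalized):
        raise TrackStateError("input normalization requires RPM tracks")
    if set(chip.runs) != set(control.runs):
        raise TrackStateError("assembly mismatch between chip and control")
    out = CoverageTrack(library_size=chip.library_size, normalized=True)
    for chrom in chip.runs:
        a, b = chip.runs[chrom], control.runs[chrom]
        length = max(chip.chrom_end(chrom), control.chrom_end(chrom))
        bounds = np.unique(
            np.concatenate(
                ([0, length], a.starts, a.ends, b.starts, b.ends)
            )
        )
        bounds = bounds[bounds <= length]
        seg_starts = bounds[:-1]
        seg_ends = bounds[1:]
        if len(seg_starts) == 0:
            z = np.zeros(0, dtype=np.int64)
            out.runs[chrom] = _ChromRuns(z, z.copy(), np.zeros(0))
            continue
        va = _value_at(a, seg_starts)
        vb = _value_at(b, seg_starts)
        ratio = (va + pseudocount) / (vb + pseudocount)
        # compact equal neighbours
        keep = np.concatenate(([True], ratio[1:] != ratio[:-1]))
        starts = seg_starts[keep]
        values = ratio[keep]
        ends = np.concatenate((starts[1:], [seg_ends[-1]])) if len(starts) else seg_ends[:0]
        nz = values != 0
        out.runs[chrom] = _ChromRuns(
            starts[nz].astype(np.int64), ends[nz].astype(np.int64), values[nz]
        )
    return out


def summit_of(peak: GenomicInterval, track: CoverageTrack) -> tuple[int, bool]:
    """Position of maximum signal inside the peak (leftmost on ties).

    Returns ``(summit, flagged)`` where ``flagged`` is True when the peak
    carries no signal and the midpoint was used instead.
    """
    vals = track.window(peak.chrom, peak.start, peak.end)
    if not np.any(vals > 0):
        return peak.midpoint, True
    return peak.start + int(np.argmax(vals)), False


@dataclass
class SignalMatrix:
    """Summit-aligned signal matrix: rows are sites, columns are fixed-width
    bins covering [-flank, +flank) around each summit."""

    matrix: np.ndarray  # sites x bins
    site_ids: list[str]
    flank: int
    bin_width: int

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.arange(-self.flank, self.flank + 1, self.bin_width)
        return (edges[:-1] + edges[1:]) / 2

    @property
    def column_mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0) if len(self.matrix) else np.zeros(0)

    @property
    def site_mean(self) -> np.ndarray:
        return self.matrix.mean(axis=1) if len(self.matrix) else np.zeros(0)


def metaplot(
    summits: list[tuple[str, int]],
    track: CoverageTrack,
    flank: int = 2000,
    bin_width: int = 10,
    site_ids: list[str] | None = None,
) -> SignalMatrix:
    """Mean signal per bin in [-flank, +flank) around each summit.

    ``flank`` must be a multiple of ``bin_width`` (the column-count contract
    is exactly ``2*flank/bin_width``).  Summits closer than ``flank`` to a
    chromosome start are dropped with a warning.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    rows = []
    kept_ids = []
    ids = site_ids or [f"site_{i}" for i in range(len(summits))]
    for sid, (chrom, pos) in zip(ids, summits):
        if pos - flank < 0:
            warnings.warn(f"summit {chrom}:{pos} within {flank} of chrom start; dropped")
            continue
        vals = track.window(chrom, pos - flank, pos + flank)
        rows.append(vals.reshape(n_bins, bin_width).mean(axis=1))
        kept_ids.append(sid)
    matrix = np.array(rows) if rows else np.zeros((0, n_bins))
    return SignalMatrix(matrix, kept_ids, flank, bin_width)
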