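"""Brute-force reference implementations shared across test modules.
These are deliberately naive (quadratic closures, positionwise matching)
and independent of the package code paths they check."""

from cswitch.intervals import GenomicInterval
from cswitch.motifscan import IUPAC, reverse_complement_iupac


def brute_merge(intervals):
    """Pairwise-union closure: repeatedly merge any two overlapping
    intervals until a fixed point."""
    items = [[i.chrom, i.start, i.end, i.score] for i in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2]), a[3] + b[3]]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e, sc) for c, s, e, sc in items)


def random_intervals(rng, n, span=2000, max_len=60):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(
            GenomicInterval("chr1", start, start + int(rng.integers(1, max_len)))
        )
    return out


def oracle_scan(pattern: str, seq: str):
    """Positionwise character-set matching on both strands, no regex."""

    def matches_at(pat, s, i):
        if i + len(pat) > len(s):
            return False
        return all(s[i + k] in IUPAC[pat[k]] for k in range(len(pat)))

    rc = reverse_complement_iupac(pattern)
    is_pal = rc == pattern
    hits = []
    for i in range(len(seq)):
        fwd = matches_at(pattern, seq, i)
        rev = matches_at(rc, seq, i)
        if is_pal:
            if fwd:
                hits.append((i, "."))
        else:
            if fwd:
                hits.append((i, "+"))
            if rev:
                hits.append((i, "-"))
    return sorted(hits)
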