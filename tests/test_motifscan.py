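"""IUPAC scanning against a character-class expansion oracle, palindrome
strand handling, per-peak counting and score-binned frequency curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cswitch.errors import CswitchError
from cswitch.intervals import GenomicInterval
from cswitch.motifscan import (
    DEFAULT_MOTIFS,
    IUPAC,
    MotifPattern,
    binned_frequency,
    iupac_scan,
    peak_motif_counts,
    reverse_complement_iupac,
)

PATTERNS = {m.name: m for m in DEFAULT_MOTIFS}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


from _oracles import oracle_scan  # noqa: E402


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIupacScan:
    def test_palindrome_reported_once_with_dot_strand(self):
        assert iupac_scan(PATTERNS["SBE_palindrome"], "AAGTCTAGACTT") == [(2, ".")]

    def test_degenerate_letter_semantics(self):
        # V = {A,C,G}, N = anything
        assert iupac_scan("GNCV", "GACA") == [(0, "+"), (0, "-")] or iupac_scan(
            "GNCV", "GACA"
        ) == [(0, "+")]
        assert (0, "+") in iupac_scan("GNCV", "GACA")

    def test_minus_strand_match(self):
        # GC_SBE_1 is not self-reverse-complementary; plant its reverse
        # complement and expect a minus-strand hit at the same offset
        concrete = "GGCGCCATTTTGACA"  # instance of GGCGCCANNNNGNCV
        rc = "".join(COMP[c] for c in reversed(concrete))
        seq = "TT" + rc + "TT"
        hits = iupac_scan(PATTERNS["GC_SBE_1"], seq)
        assert (2, "-") in hits

    def test_ap1_motif_is_its_own_reverse_complement(self):
        seq = "TTTGAGTCATT"  # TGAGTCA instance of TGASTCA at offset 2
        assert iupac_scan(PATTERNS["AP1"], seq) == [(2, ".")]

    def test_invalid_letter_rejected_at_load(self):
        with pytest.raises(CswitchError, match="IUPAC"):
            MotifPattern("bad", "GTCX", "gc_rich")

    @pytest.mark.parametrize("motif", list(PATTERNS))
    def test_matches_expansion_oracle_on_random_sequence(self, motif, rng):
        seq = random_seq(rng, 10_000)
        pat = PATTERNS[motif]
        assert iupac_scan(pat, seq) == oracle_scan(pat.iupac, seq)

    def test_matches_oracle_with_planted_instances(self, rng):
        seq = list(random_seq(rng, 5_000))
        for pos in (100, 2_000, 2_010, 4_990):
            seq[pos : pos + 8] = "GTCTAGAC"
        seq = "".join(seq)[:5_000]
        pat = PATTERNS["SBE_palindrome"]
        got = iupac_scan(pat, seq)
        assert got == oracle_scan(pat.iupac, seq)
        assert {100, 2_000, 2_010} <= {off for off, _ in got}

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=200),
           st.sampled_from(["GTCTAGAC", "GGCGCC", "TGASTCA"]))
    def test_property_strand_sets_mirror(self, seq, pattern):
        """+ matches of a pattern equal - matches of its reverse complement."""
        rc = reverse_complement_iupac(pattern)
        fwd = {o for o, s in oracle_scan(pattern, seq) if s in "+."}
        via_rc = {o for o, s in oracle_scan(rc, seq) if s in "-."} if rc != pattern else fwd
        got_fwd = {o for o, s in iupac_scan(pattern, seq) if s in "+."}
        assert got_fwd == fwd
        if rc == pattern:
            assert {s for _, s in iupac_scan(pattern, seq)} <= {"."}


class TestPeakMotifCounts:
    def test_planted_motif_counted_once(self):
        genome = {"chr1": "A" * 50 + "GTCTAGAC" + "A" * 50}
        peak = GenomicInterval("chr1", 40, 70, "p0")
        counts = peak_motif_counts([peak], genome)
        assert counts.loc["p0", "SBE_palindrome"] == 1

    def test_match_must_be_fully_inside(self):
        genome = {"chr1": "A" * 50 + "GTCTAGAC" + "A" * 50}
        peak = GenomicInterval("chr1", 40, 54, "p0")  # cuts the motif
        counts = peak_motif_counts([peak], genome)
        assert counts.loc["p0", "SBE_palindrome"] == 0

    def test_empty_peak_list(self):
        assert peak_motif_counts([], {"chr1": "ACGT" * 10}).empty

    def test_peak_beyond_chrom_end_rejected(self):
        with pytest.raises(CswitchError, match="beyond"):
            peak_motif_counts(
                [GenomicInterval("chr1", 0, 100, "p")], {"chr1": "ACGT"}
            )

    def test_recovers_planted_placements(self, small_dataset):
        ds = small_dataset
        planted = ds.truth_sites[ds.truth_sites.planted_motif != ""]
        peaks = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.site_id)
            for r in planted.itertuples()
        ]
        counts = peak_motif_counts(peaks, ds.genome)
        for r in planted.itertuples():
            assert counts.loc[r.site_id, r.planted_motif] >= 1
            # and retrievable at exactly the planted coordinate
            seq = ds.genome[r.chrom][int(r.start) : int(r.end)]
            offsets = [o for o, _ in iupac_scan(
                {m.name: m for m in DEFAULT_MOTIFS}[r.planted_motif], seq
            )]
            assert int(r.motif_start) - int(r.start) in offsets


def make_peaks(scores):
    return [
        GenomicInterval("chr1", 100 * i, 100 * i + 50, f"p{i}", s)
        for i, s in enumerate(scores)
    ]


def counts_frame(peaks, hits):
    return pd.DataFrame({"m": hits}, index=[p.name for p in peaks])


class TestBinnedFrequency:
    def test_all_peaks_with_motif_give_unit_frequency(self):
        peaks = make_peaks(range(10))
        tbl = binned_frequency(peaks, [True] * 10, counts_frame(peaks, [1] * 10))
        assert (tbl["frequency"] == 1.0).all()

    def test_motif_restricted_to_top_bin(self):
        peaks = make_peaks(range(50))
        hits = [0] * 45 + [1] * 5  # only the top decile carries the motif
        tbl = binned_frequency(peaks, [True] * 50, counts_frame(peaks, hits))
        by_bin = tbl.set_index("bin")["frequency"]
        assert by_bin.loc[5] == 0.5
        assert (by_bin.loc[[1, 2, 3, 4]] == 0).all()

    def test_invariant_to_monotone_score_rescaling(self, rng):
        scores = rng.random(40)
        hits = (rng.random(40) < 0.5).astype(int)
        flags = [True] * 40
        p1 = make_peaks(scores)
        p2 = make_peaks(np.exp(5 * scores))  # monotone transform
        t1 = binned_frequency(p1, flags, counts_frame(p1, hits))
        t2 = binned_frequency(p2, flags, counts_frame(p2, hits))
        assert t1["frequency"].tolist() == t2["frequency"].tolist()

    def test_bin_sizes_partition_stratum(self, rng):
        scores = rng.random(37)
        flags = [i % 2 == 0 for i in range(37)]
        peaks = make_peaks(scores)
        tbl = binned_frequency(peaks, flags, counts_frame(peaks, [0] * 37))
        for stratum, n in (("cobound", 19), ("solo", 18)):
            sizes = tbl[tbl.stratum == stratum].groupby("bin")["n_peaks"].first()
            assert sizes.sum() == n

    def test_small_stratum_rejected(self):
        peaks = make_peaks(range(6))
        with pytest.raises(CswitchError, match="fewer"):
            binned_frequency(peaks, [True] * 3 + [False] * 3,
                             counts_frame(peaks, [0] * 6))

    def test_planted_palindrome_enriched_in_cobound_stratum(self, default_dataset):
        ds = default_dataset
        sites = ds.truth_sites.query("site_class in ('cobound', 'solo')")
        peaks = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.site_id)
            for r in sites.itertuples()
        ]
        flags = [c == "cobound" for c in sites.site_class]
        counts = peak_motif_counts(peaks, ds.genome)
        # stratum-level frequency against the truth-table planted fraction
        cobound_freq = float(
            (counts.loc[[p.name for p, f in zip(peaks, flags) if f],
                        "SBE_palindrome"] > 0).mean()
        )
        cb = ds.truth_sites.query("site_class == 'cobound'")
        realized = float((cb.planted_motif == "SBE_palindrome").mean())
        assert cobound_freq >= realized  # planted plus chance occurrences
        assert cobound_freq <= realized + 0.1
        solo_freq = float(
            (counts.loc[[p.name for p, f in zip(peaks, flags) if not f],
                        "SBE_palindrome"] > 0).mean()
        )
        assert solo_freq < 0.2
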