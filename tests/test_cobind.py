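"""Co-binding classification, dependence testing and relocation
differential: boundary rules, quadratic distance oracles, formula-level
oracles for the moderated statistic and BH adjustment, and planted-truth
recovery on the synthetic dataset."""

import math

import numpy as np
import pytest

from cswitch._stats import bh_adjust, moderated_ttest
from cswitch.cobind_switch import (
    CoBindingRecord,
    classify_cobound,
    dependence_test,
    differential_binding,
    flanking_sites,
)
from cswitch.coverage import CoverageTrack, normalize_rpm
from cswitch.intervals import GenomicInterval


def iv(start, end, chrom="chr1", name=""):
    return GenomicInterval(chrom, start, end, name)


class TestClassify:
    def test_one_bp_overlap_is_cobound(self):
        (rec,) = classify_cobound([iv(100, 200)], [iv(150, 160)])
        assert rec.cobound and rec.nearest_cobound_distance == 0

    def test_bookended_cofactor_is_solo(self):
        recs = classify_cobound(
            [iv(100, 200), iv(1000, 1100)], [iv(200, 300), iv(1000, 1050)]
        )
        by_pos = {r.interval.start: r for r in recs}
        assert not by_pos[100].cobound
        assert by_pos[1000].cobound
        # distance measured summit-to-summit toward the co-bound site
        assert by_pos[100].nearest_cobound_distance == abs(150 - 1050)

    def test_no_cobound_on_chrom_gives_infinite_distance(self):
        recs = classify_cobound(
            [iv(0, 10, chrom="chrA"), iv(0, 10, chrom="chrB")],
            [iv(5, 8, chrom="chrA")],
        )
        solo = [r for r in recs if not r.cobound]
        assert len(solo) == 1 and math.isinf(solo[0].nearest_cobound_distance)

    def test_recovers_planted_classes(self, default_dataset):
        ds = default_dataset
        smad = ds.site_intervals()
        cof = ds.site_intervals(classes=("cobound",))
        recs = classify_cobound(smad, cof)
        truth = dict(zip(ds.truth_sites.site_id, ds.truth_sites.site_class))
        for rec in recs:
            assert rec.cobound == (truth[rec.site_id] == "cobound")


class TestFlanking:
    def make(self, positions, cobound):
        recs = []
        for i, (pos, cb) in enumerate(zip(positions, cobound)):
            rec = CoBindingRecord(
                site_id=f"s{i}",
                interval=iv(pos - 50, pos + 50),
                cobound=cb,
                summit=pos,
            )
            recs.append(rec)
        # fill distances as classify_cobound would
        cb_pos = [p for p, c in zip(positions, cobound) if c]
        for rec in recs:
            rec.nearest_cobound_distance = (
                0.0
                if rec.cobound
                else min(abs(rec.summit - p) for p in cb_pos)
            )
        return recs

    def test_inside_window_included(self):
        recs = self.make([1_000_000, 1_150_000], [True, False])
        assert [r.site_id for r in flanking_sites(recs)] == ["s1"]

    def test_boundary_exclusive_beyond_window(self):
        recs = self.make([1_000_000, 1_250_001], [True, False])
        assert flanking_sites(recs, window=200_000) == []
        recs = self.make([1_000_000, 1_200_000], [True, False])
        assert len(flanking_sites(recs, window=200_000)) == 1

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        positions = sorted(int(p) for p in rng.integers(0, 3_000_000, size=120))
        cobound = rng.random(120) < 0.3
        recs = self.make(positions, cobound.tolist())
        got = {r.site_id for r in flanking_sites(recs, window=150_000)}
        oracle = set()
        cb = [(r.site_id, r.summit) for r in recs if r.cobound]
        for r in recs:
            if r.cobound:
                continue
            if any(abs(r.summit - p) <= 150_000 for _, p in cb):
                oracle.add(r.site_id)
        assert got == oracle


class TestDependence:
    def test_identical_conditions_null(self, small_dataset):
        ds = small_dataset
        tracks = [normalize_rpm(ds.tracks[("smad", "wt", r)]) for r in range(3)]
        recs = classify_cobound(
            ds.site_intervals(), ds.site_intervals(classes=("cobound",))
        )
        res = dependence_test(recs, tracks, tracks)
        for summary in res:
            assert summary.p == pytest.approx(1.0)
            assert summary.mean_log2fc == pytest.approx(0.0)

    def test_planted_effect_confined_to_cobound_stratum(
        self, default_dataset, norm_tracks
    ):
        ds = default_dataset
        recs = classify_cobound(
            ds.site_intervals(classes=("cobound", "solo")),
            ds.site_intervals(classes=("cobound",)),
        )
        res = {s.stratum: s for s in dependence_test(
            recs, norm_tracks["wt"], norm_tracks["ko"]
        )}
        assert res["cobound"].p < 0.01
        assert res["cobound"].mean_log2fc == pytest.approx(-1.0, abs=0.15)
        assert res["solo"].p > 0.05

    def test_statistic_matches_naive_formula(self, small_dataset):
        from scipy import stats as sps

        ds = small_dataset
        wt = [normalize_rpm(ds.tracks[("smad", "wt", r)]) for r in range(3)]
        ko = [normalize_rpm(ds.tracks[("smad", "ko", r)]) for r in range(3)]
        recs = classify_cobound(
            ds.site_intervals(classes=("cobound", "solo")),
            ds.site_intervals(classes=("cobound",)),
        )
        res = {s.stratum: s for s in dependence_test(recs, wt, ko)}
        # oracle: recompute per-site window means and a paired t by hand
        for stratum, flag in (("cobound", True), ("solo", False)):
            a, b = [], []
            for r in recs:
                if r.cobound != flag:
                    continue
                win = (r.summit - 500, r.summit + 500)
                a.append(np.mean([t.region_mean(r.interval.chrom, *win) for t in wt]))
                b.append(np.mean([t.region_mean(r.interval.chrom, *win) for t in ko]))
            d = np.array(b) - np.array(a)
            t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p_oracle = 2 * sps.t.sf(abs(t_oracle), len(d) - 1)
            assert res[stratum].t == pytest.approx(t_oracle)
            assert res[stratum].p == pytest.approx(p_oracle)


class TestModeratedStats:
    def test_matches_direct_formula(self, rng):
        a = rng.normal(0, 1, size=(50, 3))
        b = rng.normal(0.5, 1, size=(50, 3))
        res = moderated_ttest(a, b, prior_df=4.0)
        # longhand oracle for a handful of rows
        s2 = (
            ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
            + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        ) / 4.0
        s2_prior = s2.mean()
        for i in (0, 7, 23, 49):
            s2_mod = (4 * s2_prior + 4 * s2[i]) / 8.0
            t_oracle = (b[i].mean() - a[i].mean()) / np.sqrt(s2_mod * (2 / 3))
            assert res.t[i] == pytest.approx(t_oracle)

    def test_swapping_conditions_negates_statistics(self, rng):
        a = rng.normal(0, 1, size=(30, 3))
        b = rng.normal(1, 1, size=(30, 3))
        fwd = moderated_ttest(a, b)
        rev = moderated_ttest(b, a)
        np.testing.assert_allclose(fwd.t, -rev.t)
        np.testing.assert_allclose(fwd.p, rev.p)

    def test_bh_matches_sort_and_adjust_oracle(self, rng):
        p = rng.random(200) ** 2
        got = bh_adjust(p)
        n = len(p)
        order = np.argsort(p)
        oracle = np.empty(n)
        running = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * n / rank_from_top)
            oracle[i] = running
        np.testing.assert_allclose(got, oracle)
        # q >= p and monotone in p-rank
        assert (got >= p - 1e-12).all()
        assert (np.diff(got[order]) >= -1e-12).all()


class TestDifferentialBinding:
    def test_identical_conditions_all_null(self, small_dataset):
        ds = small_dataset
        tracks = [normalize_rpm(ds.tracks[("smad", "wt", r)]) for r in range(3)]
        recs = classify_cobound(
            ds.site_intervals(classes=("cobound", "solo")),
            ds.site_intervals(classes=("cobound",)),
        )
        diff, _ = differential_binding(recs, tracks, tracks)
        assert all(r.log2fc == 0 for r in diff)
        assert all(r.q > 0.99 for r in diff)

    def test_swap_negates_log2fc(self, small_dataset):
        ds = small_dataset
        wt = [normalize_rpm(ds.tracks[("smad", "wt", r)]) for r in range(3)]
        ko = [normalize_rpm(ds.tracks[("smad", "ko", r)]) for r in range(3)]
        recs = classify_cobound(
            ds.site_intervals(classes=("cobound", "solo")),
            ds.site_intervals(classes=("cobound",)),
        )
        fwd, _ = differential_binding(recs, wt, ko)
        rev, _ = differential_binding(recs, ko, wt)
        np.testing.assert_allclose(
            [r.log2fc for r in fwd], [-r.log2fc for r in rev]
        )
        np.testing.assert_allclose([r.p for r in fwd], [r.p for r in rev])

    def test_planted_recovery(self, default_dataset, norm_tracks):
        ds = default_dataset
        smad = ds.site_intervals()
        recs = classify_cobound(smad, ds.site_intervals(classes=("cobound",)))
        flank = flanking_sites(recs, window=ds.config.relocation_distance)
        tested = [r for r in recs if r.cobound] + flank
        diff, summary = differential_binding(
            tested, norm_tracks["wt"], norm_tracks["ko"], fdr=0.1
        )
        by_class = summary.set_index("class")
        assert by_class.loc["cobound", "mean_log2fc"] == pytest.approx(-1.0, abs=0.15)
        assert by_class.loc["flanking", "mean_log2fc"] > 0
        n_ectopic = (ds.truth_sites.site_class == "ectopic").sum()
        assert by_class.loc["flanking", "n_significant"] >= 0.8 * n_ectopic

    def test_type_i_error_calibrated_under_null(self, null_dataset):
        ds = null_dataset
        wt = [normalize_rpm(ds.tracks[("smad", "wt", r)]) for r in range(3)]
        ko = [normalize_rpm(ds.tracks[("smad", "ko", r)]) for r in range(3)]
        recs = classify_cobound(
            ds.site_intervals(classes=("cobound", "solo")),
            ds.site_intervals(classes=("cobound",)),
        )
        diff, _ = differential_binding(recs, wt, ko)
        frac = np.mean([r.p < 0.05 for r in diff])
        assert frac == pytest.approx(0.05, abs=0.02)
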