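"""RIL re-sequencing scan: genotype calling, filtering, orientation, the
group-difference window statistic, sustained-peak thresholds and peak calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomap import rilscan as rs


def _gm(calls, spacing=10_000, chrom="2L", classes=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_sites = calls.shape
    sites = pd.DataFrame({"chrom": chrom,
                          "pos": np.arange(1, n_sites + 1) * spacing})
    return rs.GenotypeMatrix([f"l{i}" for i in range(n_lines)], sites, calls,
                             classes or {})


class TestCallGenotype:
    def test_majority_rule(self):
        assert rs.call_genotype(np.array([5]), np.array([1]), 2)[0] == rs.ALLELE_W

    def test_tie_is_missing(self):
        assert rs.call_genotype(np.array([3]), np.array([3]), 2)[0] == rs.MISSING

    def test_zero_depth_is_missing(self):
        assert rs.call_genotype(np.array([0]), np.array([0]), 1)[0] == rs.MISSING

    def test_depth_floor(self):
        assert rs.call_genotype(np.array([1]), np.array([0]), 2)[0] == rs.MISSING


class TestFilterThin:
    def test_filter_requires_both_genotypes_in_three_lines(self):
        calls = np.array([[1], [1], [0], [0], [0], [-1]])  # W in 2 lines only
        assert len(rs.filter_sites(_gm(calls)).sites) == 0
        calls = np.array([[1]] * 3 + [[0]] * 20)
        assert len(rs.filter_sites(_gm(calls)).sites) == 1

    def test_monomorphic_site_dropped(self):
        calls = np.array([[1]] * 6)
        assert len(rs.filter_sites(_gm(calls)).sites) == 0

    def test_thin_keeps_one_site_per_bin(self):
        calls = np.ones((2, 10), dtype=np.int8)
        gm = _gm(calls, spacing=500)  # ten sites inside one 10 kb bin
        assert len(rs.thin_sites(gm, 10_000).sites) == 1

    def test_thin_uniform_kilobase_grid(self):
        calls = np.ones((2, 1000), dtype=np.int8)
        gm = _gm(calls, spacing=1_000)  # 1 kb grid over 1 Mb
        assert len(rs.thin_sites(gm, 10_000).sites) == 100

    def test_thin_bin_edges_half_open(self):
        sites = pd.DataFrame({"chrom": "2L", "pos": [10_000, 10_001, 20_000, 20_001]})
        gm = rs.GenotypeMatrix(["a"], sites, np.ones((1, 4), np.int8))
        out = rs.thin_sites(gm, 10_000)
        assert out.sites["pos"].tolist() == [10_000, 10_001, 20_001]


class TestOrientation:
    def test_major_allele_by_count(self):
        calls = np.array([[1]] * 15 + [[0]] * 8)
        om = rs.orient_major_allele(_gm(calls))
        assert om.major_allele[0] == rs.ALLELE_W
        calls = np.array([[0]] * 15 + [[1]] * 8)
        om = rs.orient_major_allele(_gm(calls))
        assert om.major_allele[0] == rs.ALLELE_Y

    def test_tie_designates_we70_major(self):
        calls = np.array([[1]] * 5 + [[0]] * 5)
        om = rs.orient_major_allele(_gm(calls))
        assert om.major_allele[0] == rs.ALLELE_W

    def test_recode_preserves_counts(self, rng):
        calls = rng.choice([-1, 0, 1], size=(23, 200)).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        carriers = (om.carries == 1).sum(0) + (om.carries == 0).sum(0)
        known = (calls != rs.MISSING).sum(0)
        np.testing.assert_array_equal(carriers, known)


class TestGroupDifference:
    def test_fully_penetrant_contrast_is_plus_six(self):
        calls = np.vstack([np.ones((6, 100)), np.zeros((6, 100))]).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        diff = rs.group_difference(om, [f"l{i}" for i in range(6)],
                                   [f"l{i}" for i in range(6, 12)])
        assert np.all(diff == 6)

    def test_identical_groups_give_zero(self, rng):
        row = rng.choice([0, 1], 50).astype(np.int8)
        calls = np.vstack([row] * 12)
        om = rs.orient_major_allele(_gm(calls))
        diff = rs.group_difference(om, [f"l{i}" for i in range(6)],
                                   [f"l{i}" for i in range(6, 12)])
        assert np.all(diff == 0)

    def test_six_vs_five_asymmetric_bounds(self):
        calls = np.vstack([np.ones((6, 10)), np.zeros((5, 10))]).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        g1 = [f"l{i}" for i in range(6)]
        g2 = [f"l{i}" for i in range(6, 11)]
        assert np.all(rs.group_difference(om, g1, g2) == 6)
        assert np.all(rs.group_difference(om, g2, g1) == -6)
        # flip orientation: make yw the major allele
        calls = np.vstack([np.zeros((6, 10)), np.ones((5, 10))]).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        assert np.all(rs.group_difference(om, g1, g2) == 6)

    def test_antisymmetry_six_vs_six(self, rng):
        calls = rng.choice([-1, 0, 1], size=(12, 80)).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        g1 = [f"l{i}" for i in range(6)]
        g2 = [f"l{i}" for i in range(6, 12)]
        np.testing.assert_array_equal(rs.group_difference(om, g1, g2),
                                      -rs.group_difference(om, g2, g1))

    def test_missing_line_lowers_attainable_bound(self):
        # two extra W lines outside the contrast keep W the panel-major allele
        calls = np.vstack([np.ones((5, 10)), np.full((1, 10), -1),
                           np.zeros((6, 10)), np.ones((2, 10))]).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        diff = rs.group_difference(om, [f"l{i}" for i in range(6)],
                                   [f"l{i}" for i in range(6, 12)])
        assert np.all(diff == 5)

    def test_overlapping_groups_rejected(self):
        om = rs.orient_major_allele(_gm(np.ones((4, 5), dtype=np.int8)))
        with pytest.raises(ValueError):
            rs.group_difference(om, ["l0", "l1"], ["l1", "l2"])

    def test_profile_values_within_group_bounds(self, rng):
        calls = rng.choice([-1, 0, 1], size=(12, 400), p=[0.05, 0.45, 0.5]).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls))
        diff = rs.group_difference(om, [f"l{i}" for i in range(6)],
                                   [f"l{i}" for i in range(6, 12)])
        prof = rs.ril_window_profile(diff, om.sites, window=100)
        assert prof.windows["value"].between(-6, 6).all()


def _brute_sustained(values, starts, ends, min_span):
    best = -np.inf
    n = len(values)
    for i in range(n):
        for j in range(i, n):
            if ends[j] - starts[i] >= min_span:
                seg = values[i:j + 1]
                best = max(best, seg.min(), (-np.asarray(seg)).min())
                break  # longer runs only lower the min
    return best


class TestSustainedStatistic:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=60),
           st.integers(500, 8000))
    def test_property_matches_brute_force(self, values, min_span):
        values = np.asarray(values)
        starts = np.arange(values.size, dtype=float) * 200.0
        ends = starts + 150.0
        fast = rs.sustained_peak_height(values, starts, ends, float(min_span))
        brute = _brute_sustained(values, starts, ends, float(min_span))
        assert fast == pytest.approx(brute)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            n = rng.integers(30, 120)
            starts = np.sort(rng.choice(10_000, n, replace=False)).astype(float)
            ends = starts + 500.0
            values = rng.normal(size=n)
            min_span = float(rng.integers(1_000, 5_000))
            fast = rs.sustained_peak_height(values, starts, ends, min_span)
            brute = _brute_sustained(values, starts, ends, min_span)
            assert fast == pytest.approx(brute)

    def test_unattainable_span_gives_minus_inf(self):
        out = rs.sustained_peak_height(np.ones(5), np.arange(5.0),
                                       np.arange(5.0) + 1, 1e9)
        assert out == -np.inf


class TestCallPeaks:
    def _profile(self, values, spacing=100_000):
        n = len(values)
        rows = [("2L", (i + 1) * spacing, (i + 1) * spacing + spacing - 1, 100, v)
                for i, v in enumerate(values)]
        from cardiomap.bsa import WindowProfile

        return WindowProfile(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n", "value"]), window=100)

    def test_subthreshold_profile_yields_no_peaks(self):
        prof = self._profile(np.full(200, 1.0))
        assert rs.call_peaks(prof, 1.8) == []

    def test_wide_plateau_called_once(self):
        values = np.zeros(300)
        values[100:221] = 2.0  # 121 windows * 100 kb spacing > 10 Mb span
        prof = self._profile(values)
        peaks = rs.call_peaks(prof, 1.8)
        assert len(peaks) == 1
        assert peaks[0].direction == "group1-excess"
        assert peaks[0].span >= 10_000_000

    def test_narrow_plateau_filtered_by_span(self):
        values = np.zeros(300)
        values[100:180] = 2.0  # ~8 Mb: below the 10 Mb span floor
        prof = self._profile(values)
        assert rs.call_peaks(prof, 1.8) == []

    def test_negative_peak_direction(self):
        values = np.zeros(300)
        values[50:171] = -2.5
        peaks = rs.call_peaks(self._profile(values), 1.8)
        assert len(peaks) == 1 and peaks[0].direction == "group2-excess"
        assert peaks[0].value == -2.5


class TestThresholdCalibration:
    def test_unlinked_null_exceedance_near_five_percent(self):
        """With independent 50/50 genotypes, ~5% of fresh random draws sustain
        a >= 10 Mb run beyond the 95th-percentile threshold, by construction."""
        rng = np.random.default_rng(100)
        n_sites = 3_000  # one 30 Mb chromosome at 10 kb
        calls = rng.choice([0, 1], size=(23, n_sites)).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls, spacing=10_000, chrom="3R"))
        thr, maxima = rs.ril_threshold(om, (6, 6), n_perm=400, seed=1,
                                       return_maxima=True)
        _, fresh = rs.ril_threshold(om, (6, 6), n_perm=400, seed=2,
                                    return_maxima=True)
        exceed = (fresh > thr).mean()
        assert 0.01 <= exceed <= 0.10

    def test_threshold_shrinks_with_window_size(self):
        rng = np.random.default_rng(101)
        calls = rng.choice([0, 1], size=(23, 3_000)).astype(np.int8)
        om = rs.orient_major_allele(_gm(calls, spacing=10_000, chrom="3R"))
        thr_small = rs.ril_threshold(om, (6, 6), n_perm=150, window=50, seed=3)
        thr_large = rs.ril_threshold(om, (6, 6), n_perm=150, window=400, seed=3)
        assert abs(thr_large) < abs(thr_small)

    def test_too_few_lines_rejected(self):
        om = rs.orient_major_allele(_gm(np.ones((8, 50), dtype=np.int8)))
        with pytest.raises(ValueError):
            rs.ril_threshold(om, (6, 6), n_perm=30)


class TestLocalization:
    def test_end_to_end_localizes_fully_penetrant_locus(self, default_map):
        """Representative seeded panel: a fully penetrant recessive locus on
        3R is localized by the span-sustained peak of the parental-oriented
        scan contrasting all aberrant against all normal lines."""
        from cardiomap import simulate as sim

        mono = sim.monogenic_model(("3R", 20_000_000), affected_traits=("SD",))
        sub = np.random.SeedSequence(77).spawn(1)[0].spawn(3)
        panel = sim.make_ril_panel(default_map, 23, 12, seed=sub[0])
        genomes = {f"R{i:02d}": g for i, g in enumerate(panel)}
        om = rs.sequence_panel(genomes, default_map, seed=sub[1])
        aberrant = [lid for lid, g in genomes.items()
                    if sim.is_aberrant_genotype(g, mono, default_map)]
        normal = [lid for lid in genomes if lid not in aberrant]
        diff = rs.group_difference_parental(om, normal, aberrant)
        peak = rs.localize_peak(diff, om.sites)
        assert peak is not None and peak.chrom == "3R"
        assert peak.start <= 20_000_000 <= peak.end
        assert peak.direction == "group2-excess"  # aberrant lines carry WE70

    def test_parental_orientation_round_trip(self, rng):
        calls = rng.choice([-1, 0, 1], size=(9, 120)).astype(np.int8)
        gm = _gm(calls)
        om = rs.orient_major_allele(gm)
        np.testing.assert_array_equal(om.parental_calls(), calls)


class TestSequencePanel:
    def test_pipeline_produces_oriented_matrix(self, small_map):
        from cardiomap import simulate as sim

        panel = sim.make_ril_panel(small_map, 12, 12, seed=21)
        genomes = {f"R{i}": g for i, g in enumerate(panel)}
        om = rs.sequence_panel(genomes, small_map, spacing=50_000, seed=5)
        assert len(om.line_ids) == 12
        assert om.carries.shape[1] == len(om.sites)
        assert set(np.unique(om.carries)) <= {-1, 0, 1}
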