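"""Profile extraction, smoothing, averaging, correlation, enrichment, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from hypothesis.extra import numpy as hnp

import serptools as st
from serptools.io_formats import GeneModel
from serptools.profiles import _moving_average


def brute_force_moving_average(values, window, alignment="centered"):
    out = np.empty(values.size)
    for i in range(values.size):
        if alignment == "centered":
            lo, hi = i - window // 2, i + (window - 1) // 2
        else:
            lo, hi = i - window + 1, i
        out[i] = values[max(0, lo):hi + 1].mean()
    return out


finite_profiles = hnp.arrays(
    np.float64, hst.integers(5, 300),
    elements=hst.floats(0, 1e4, allow_nan=False, allow_infinity=False),
)


class TestExtraction:
    def _track(self, values):
        return st.CountTrack("ip", "bait", 1, {"chrS": np.asarray(values, float)})

    def test_plus_strand_keeps_genomic_order(self):
        track = self._track([9, 1, 2, 3, 9])
        gene = GeneModel("g", "chrS", "+", ((2, 4),))
        assert st.extract_gene_profile(track, gene).values.tolist() == [1, 2, 3]

    def test_minus_strand_reverses_to_start_codon_side(self):
        track = self._track([9, 1, 2, 3, 9])
        gene = GeneModel("g", "chrS", "-", ((2, 4),))
        assert st.extract_gene_profile(track, gene).values.tolist() == [3, 2, 1]

    def test_intron_positions_keep_counts_with_mask_false(self):
        track = self._track([1, 2, 7, 7, 3, 4])
        gene = GeneModel("g", "chrS", "+", ((1, 2), (5, 6)))
        prof = st.extract_gene_profile(track, gene)
        assert prof.values.tolist() == [1, 2, 7, 7, 3, 4]
        assert prof.exon_mask.tolist() == [True, True, False, False, True, True]
        assert prof.orf_values().tolist() == [1, 2, 3, 4]

    def test_minus_strand_mask_reversed_with_values(self):
        track = self._track([1, 2, 7, 7, 3, 4])
        gene = GeneModel("g", "chrS", "-", ((1, 2), (5, 6)))
        prof = st.extract_gene_profile(track, gene)
        assert prof.orf_values().tolist() == [4, 3, 2, 1]


class TestSmoothing:
    def test_constant_profile_is_preserved_exactly(self, profile_factory):
        prof = profile_factory(np.full(137, 3.25))
        out = st.smooth_profile(prof, 100)
        assert np.array_equal(out.values, prof.values)

    def test_window_one_is_identity(self, profile_factory):
        values = np.random.default_rng(0).random(50)
        out = st.smooth_profile(profile_factory(values), 1)
        assert np.array_equal(out.values, values)

    def test_impulse_matches_per_position_oracle(self, profile_factory):
        values = np.zeros(300)
        values[150] = 1.0
        out = st.smooth_profile(profile_factory(values), 100)
        expected = brute_force_moving_average(values, 100)
        np.testing.assert_allclose(out.values, expected, atol=1e-15)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(values=finite_profiles, window=hst.integers(1, 120),
           alignment=hst.sampled_from(["centered", "trailing"]))
    def test_matches_brute_force_for_any_window_and_alignment(
            self, values, window, alignment):
        if window > 10 * values.size:
            window = values.size
        got = _moving_average(values, window, alignment)
        expected = brute_force_moving_average(values, window, alignment)
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_commutes_with_scalar_multiplication(self, profile_factory):
        values = np.random.default_rng(1).random(80) * 10
        a = st.smooth_profile(profile_factory(values * 3.5), 20).values
        b = st.smooth_profile(profile_factory(values), 20).values * 3.5
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_oversized_window_clamped_with_warning(self, profile_factory):
        prof = profile_factory(np.arange(5, dtype=float))
        with pytest.warns(UserWarning, match="clamping"):
            out = st.smooth_profile(prof, 100)
        assert out.window == 5
        np.testing.assert_allclose(
            out.values, brute_force_moving_average(prof.values, 5))


class TestAveragingAndCorrelation:
    def test_positionwise_mean(self, profile_factory):
        avg = st.average_replicates([profile_factory([0, 2]), profile_factory([2, 0])])
        assert avg.values.tolist() == [1, 1] and avg.replicate == "averaged"

    def test_single_replicate_is_identity_with_warning(self, profile_factory):
        prof = profile_factory([1, 2, 3])
        with pytest.warns(UserWarning, match="single replicate"):
            avg = st.average_replicates([prof])
        assert np.array_equal(avg.values, prof.values)

    def test_four_replicates_match_independent_summation_order(self, profile_factory):
        rng = np.random.default_rng(2)
        reps = [rng.random(200) for _ in range(4)]
        avg = st.average_replicates([profile_factory(v) for v in reps])
        oracle = sum(reps[::-1]) / 4.0  # reversed accumulation order
        np.testing.assert_allclose(avg.values, oracle, atol=1e-12)

    def test_length_mismatch_rejected(self, profile_factory):
        with pytest.raises(st.ValidationError):
            st.average_replicates([profile_factory([1, 2]), profile_factory([1, 2, 3])])

    def test_identical_replicates_correlate_perfectly(self, profile_factory):
        v = np.random.default_rng(3).random(60)
        r = st.replicate_correlation([profile_factory(v), profile_factory(v.copy())])
        assert r == pytest.approx(1.0)

    def test_opposite_trends_correlate_minus_one(self, profile_factory):
        v = np.linspace(0, 5, 40)
        r = st.replicate_correlation([profile_factory(v), profile_factory(10 - v)])
        assert r == pytest.approx(-1.0)

    def test_mean_pairwise_matches_textbook_formula(self, profile_factory):
        rng = np.random.default_rng(4)
        vs = [rng.random(200) for _ in range(3)]

        def pearson(x, y):
            n = x.size
            sx, sy = x.sum(), y.sum()
            num = n * (x * y).sum() - sx * sy
            den = np.sqrt(n * (x ** 2).sum() - sx ** 2) * np.sqrt(
                n * (y ** 2).sum() - sy ** 2)
            return num / den

        expected = np.mean([pearson(vs[0], vs[1]), pearson(vs[0], vs[2]),
                            pearson(vs[1], vs[2])])
        got = st.replicate_correlation([profile_factory(v) for v in vs])
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_pairs_are_undefined(self, profile_factory):
        flat = profile_factory(np.full(30, 2.0))
        assert np.isnan(st.replicate_correlation([flat, flat]))
        varying = profile_factory(np.arange(30, dtype=float))
        # one defined pair out of three
        r = st.replicate_correlation([flat, varying,
                                      profile_factory(np.arange(30)[::-1].astype(float))])
        assert r == pytest.approx(-1.0)


class TestCoverageAndEnrichment:
    def test_coverage_boundary_cases(self, profile_factory):
        assert st.coverage_percent(profile_factory(np.ones(10))) == 100.0
        assert st.coverage_percent(profile_factory(np.zeros(10))) == 0.0
        half = np.concatenate([np.ones(5), np.zeros(5)])
        assert st.coverage_percent(profile_factory(half)) == 50.0

    def test_ip_equal_total_gives_all_ones(self, profile_factory):
        v = np.random.default_rng(5).random(30) + 0.1
        enr = st.enrichment_profile(profile_factory(v), profile_factory(v.copy()))
        np.testing.assert_allclose(enr.values, 1.0)

    def test_zero_total_is_undefined_not_zero(self, profile_factory):
        ip = profile_factory([1.0, 2.0, 3.0])
        total = profile_factory([2.0, 0.0, 1.0])
        enr = st.enrichment_profile(ip, total)
        assert enr.values[0] == 0.5 and np.isnan(enr.values[1]) and enr.values[2] == 3.0

    def test_matches_elementwise_division_oracle(self, profile_factory):
        rng = np.random.default_rng(6)
        ip, total = rng.random(100) + 0.5, rng.random(100) + 0.5
        enr = st.enrichment_profile(profile_factory(ip), profile_factory(total))
        np.testing.assert_allclose(enr.values, ip / total)

    def test_scale_invariance(self, profile_factory):
        rng = np.random.default_rng(7)
        ip, total = rng.random(50) + 0.1, rng.random(50) + 0.1
        a = st.enrichment_profile(profile_factory(ip), profile_factory(total))
        b = st.enrichment_profile(profile_factory(ip * 7.3), profile_factory(total * 7.3))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestAuc:
    def test_constant_closed_form(self):
        assert st.auc(np.full(10, 3.0)) == pytest.approx(3.0 * 9)

    def test_linear_ramp_closed_form(self):
        assert st.auc(np.linspace(0, 1, 101)) == pytest.approx(50.0)

    def test_intron_masked_matches_bruteforce_trapezoid(self):
        rng = np.random.default_rng(8)
        values = rng.random(120)
        mask = np.ones(120, bool)
        mask[40:70] = False
        kept = values[mask]
        oracle = sum((kept[i] + kept[i + 1]) / 2 for i in range(kept.size - 1))
        assert st.auc(values, mask) == pytest.approx(oracle, rel=1e-12)

    def test_undefined_positions_dropped_like_introns(self):
        values = np.array([1.0, np.nan, 2.0, 3.0])
        kept = np.array([1.0, 2.0, 3.0])
        assert st.auc(values) == pytest.approx(np.trapezoid(kept))

    def test_fewer_than_two_usable_positions_gives_zero(self):
        assert st.auc(np.array([5.0])) == 0.0
        assert st.auc(np.array([5.0, np.nan])) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(values=finite_profiles, scale=hst.floats(0, 100))
    def test_positive_homogeneity(self, values, scale):
        assert st.auc(values * scale) == pytest.approx(
            scale * st.auc(values), rel=1e-9, abs=1e-9)

    def test_identical_ip_total_enrichment_auc_is_length_minus_one(
            self, profile_factory):
        v = np.random.default_rng(9).random(75) + 0.2
        mask = np.ones(75, bool)
        mask[10:20] = False
        enr = st.enrichment_profile(profile_factory(v, mask),
                                    profile_factory(v.copy(), mask))
        assert st.enrichment_auc(enr) == pytest.approx(mask.sum() - 1)
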