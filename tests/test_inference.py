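"""Inference procedures: cohort χ² test, band statistics, kinetics, dose response."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimcnv import (
    BandTable,
    CohortCounts,
    GrowthCurve,
    cohort_rate_test,
    competition_change,
    dose_response,
    max_growth_rate,
    percent_deviating,
    percent_low_copy,
    probe_correct,
    smooth_curve,
)
from stimcnv.errors import DomainError, InputError, ParameterError, UndefinedTestError
from stimcnv.synthetic import gen_growth_curves

#: counts printed for the copper cohort experiment
TREATED = CohortCounts(events=31, alleles_assayed=112, viability=0.40)
UNTREATED = CohortCounts(events=7, alleles_assayed=256, viability=0.89)


class TestCohortRateTest:
    def test_observed_equals_expected_gives_null(self):
        """O = E exactly: χ² = 0, p = 1."""
        treated = CohortCounts(events=10, alleles_assayed=100, viability=1.0)
        untreated = CohortCounts(events=10, alleles_assayed=100, viability=1.0)
        t = cohort_rate_test(treated, untreated)
        assert t.expected == pytest.approx(10.0)
        assert t.chi2 == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_printed_cohort_counts(self):
        """The copper cohort: viability-normalised background gives E ≈ 6.8
        expected events against 31 observed, a strong excess."""
        t = cohort_rate_test(TREATED, UNTREATED)
        assert t.background_rate == pytest.approx(7 * 0.89 / 256)
        assert t.n_treated == pytest.approx(112 / 0.40)
        assert t.expected == pytest.approx(t.background_rate * 280.0)
        assert t.observed == 31
        assert t.chi2 > 80
        assert t.p_value < 1e-15
        assert t.fold == pytest.approx((31 / 112) / (7 / 256))

    def test_p_monotone_in_observed(self):
        """For fixed background, more treated events means smaller p."""
        untreated = CohortCounts(events=8, alleles_assayed=200, viability=0.8)
        ps = []
        for obs in range(10, 60, 5):
            treated = CohortCounts(events=obs, alleles_assayed=150, viability=0.5)
            ps.append(cohort_rate_test(treated, untreated).p_value)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_background_undefined(self):
        untreated = CohortCounts(events=0, alleles_assayed=100, viability=0.9)
        treated = CohortCounts(events=5, alleles_assayed=100, viability=0.5)
        with pytest.raises(UndefinedTestError):
            cohort_rate_test(treated, untreated)

    def test_zero_viability_rejected(self):
        with pytest.raises(DomainError):
            CohortCounts(events=1, alleles_assayed=10, viability=0.0)

    def test_agrees_with_binomial_monte_carlo(self):
        """The χ² p agrees with the exact binomial null of the same statistic
        within a factor of 2 at moderate significance (E >= 5)."""
        untreated = CohortCounts(events=10, alleles_assayed=500, viability=1.0)
        treated = CohortCounts(events=18, alleles_assayed=500, viability=1.0)
        t = cohort_rate_test(treated, untreated)
        rng = np.random.default_rng(99)
        n = int(round(t.n_treated))
        draws = rng.binomial(n, t.background_rate, size=200_000)
        e = t.expected
        stat = (draws - e) ** 2 / e + (draws - e) ** 2 / (n - e)
        p_mc = float((stat >= t.chi2 - 1e-12).mean())
        assert 0.5 * t.p_value <= p_mc <= 2.0 * t.p_value


class TestPercentDeviating:
    @pytest.mark.parametrize(
        "events, alleles, expected",
        [(6, 112, 5.0), (7, 256, 3.0), (1, 256, 0.0), (31, 112, 28.0)],
    )
    def test_count_mode_nearest_rounding(self, events, alleles, expected):
        assert percent_deviating((events, alleles)) == expected

    def test_cohort_mode(self):
        copies = [13] * 95 + [11] * 3 + [15] * 2
        assert percent_deviating(copies, parental_copy=13) == 5.0
        assert percent_deviating(copies, parental_copy=13, rounding="none") == pytest.approx(5.0)

    def test_all_parental_is_zero(self):
        assert percent_deviating([13] * 50, parental_copy=13) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            percent_deviating([], parental_copy=13)

    def test_invariance_to_order_and_duplication(self):
        copies = [13] * 7 + [12, 15, 15]
        base = percent_deviating(copies, parental_copy=13, rounding="none")
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(copies))
        assert percent_deviating(shuffled, 13, "none") == pytest.approx(base)
        assert percent_deviating(copies * 3, 13, "none") == pytest.approx(base)

    def test_band_mode_uses_probe_correction(self):
        """Equal intensities at 3 copies (3 sites) and 6 copies (6 sites)
        are 2/3 vs 1/3 molar: 33% deviating from a 3-copy parent."""
        table = BandTable.from_records([(3, 500.0, 3), (6, 500.0, 6)])
        assert percent_deviating(table, parental_copy=3, rounding="none") == pytest.approx(100 / 3)


class TestProbeCorrection:
    def test_equal_intensity_two_band_example(self):
        table = BandTable.from_records([(3, 100.0, 3), (6, 100.0, 6)])
        frac = probe_correct(table)
        assert frac[3] == pytest.approx(2 / 3)
        assert frac[6] == pytest.approx(1 / 3)

    def test_single_site_identity(self):
        table = BandTable.from_records([(1, 10.0, 1), (2, 30.0, 1)])
        frac = probe_correct(table)
        assert frac[1] == pytest.approx(0.25)
        assert frac[2] == pytest.approx(0.75)

    @given(
        intensities=st.lists(
            st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=8
        ),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_fractions_normalised_and_scale_invariant(self, intensities, scale):
        rows = [(i + 1, v, i + 1) for i, v in enumerate(intensities)]
        base = probe_correct(BandTable.from_records(rows))
        scaled = probe_correct(
            BandTable.from_records([(c, v * scale, s) for c, v, s in rows])
        )
        assert base.sum() == pytest.approx(1.0)
        assert np.allclose(base.values, scaled.values, rtol=1e-9)

    def test_all_zero_intensities_rejected(self):
        table = BandTable.from_records([(3, 0.0, 3), (6, 0.0, 6)])
        with pytest.raises(DomainError):
            probe_correct(table)


class TestPercentLowCopy:
    def test_parental_only_is_zero(self):
        table = BandTable.from_records([(17, 900.0, 17)])
        assert percent_low_copy(table) == 0.0

    def test_all_low_copy_is_hundred(self):
        table = BandTable.from_records([(2, 40.0, 2)])
        assert percent_low_copy(table) == pytest.approx(100.0)

    def test_mixed_table_matches_hand_computation(self):
        # corrected: 2 -> 30/2=15, 3 -> 30/3=10, 17 -> 170/17=10; low = 25/35
        table = BandTable.from_records([(2, 30.0, 2), (3, 30.0, 3), (17, 170.0, 17)])
        assert percent_low_copy(table) == pytest.approx(100 * 25 / 35)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        curve = GrowthCurve(times=np.arange(20) * 0.25, od=np.full(20, 0.3))
        assert np.allclose(smooth_curve(curve).od, 0.3)

    def test_window_one_is_identity(self):
        od = np.random.default_rng(0).uniform(0, 1, 15)
        curve = GrowthCurve(times=np.arange(15.0), od=od)
        assert np.allclose(smooth_curve(curve, window=1).od, od)

    def test_linear_ramp_interior_unchanged(self):
        """A centred moving average of a linear function reproduces it at
        every full-window (interior) point."""
        t = np.arange(30) * 0.25
        curve = GrowthCurve(times=t, od=0.02 * t + 0.05)
        sm = smooth_curve(curve, window=9)
        assert np.allclose(sm.od[4:-4], curve.od[4:-4])

    def test_bad_windows_rejected(self):
        curve = GrowthCurve(times=np.arange(10.0), od=np.ones(10))
        with pytest.raises(ParameterError):
            smooth_curve(curve, window=4)
        with pytest.raises(ParameterError):
            smooth_curve(curve, window=11)

    def test_mean_conserved_on_noisy_constant(self):
        rng = np.random.default_rng(7)
        od = 0.5 + rng.normal(0, 0.01, 400)
        curve = GrowthCurve(times=np.arange(400) * 0.25, od=np.maximum(od, 0))
        sm = smooth_curve(curve)
        se = 0.01 / math.sqrt(len(od))
        assert abs(sm.od[4:-4].mean() - od.mean()) < 3 * se


class TestMaxGrowthRate:
    def test_flat_curve_zero_rate(self):
        curve = GrowthCurve(times=np.arange(20) * 0.25, od=np.full(20, 0.2))
        m = max_growth_rate(curve)
        assert m.rate == 0.0
        assert m.nonpositive

    def test_noiseless_logistic_matches_closed_form(self):
        """μC/4 within 2% at 15-minute sampling."""
        curves, truth = gen_growth_curves(noise_sd=0.0, n_replicates=1, seed=0)
        m = max_growth_rate(curves[0])
        assert m.rate == pytest.approx(truth.planted["max_growth_rate"], rel=0.02)

    def test_decreasing_curve_flagged(self):
        t = np.arange(20) * 0.25
        curve = GrowthCurve(times=t, od=1.0 - 0.01 * t)
        m = max_growth_rate(curve)
        assert m.rate <= 0
        assert m.nonpositive

    def test_short_series_rejected(self):
        curve = GrowthCurve(times=np.arange(8.0), od=np.ones(8))
        with pytest.raises(DomainError):
            max_growth_rate(curve, window=9)


class TestDoseResponse:
    def test_constant_od_censored(self):
        dr = dose_response([0.0, 0.5, 1.0], [0.8, 0.8, 0.8])
        assert dr.censored
        assert dr.gi50 == 1.0
        assert dr.auc == pytest.approx(0.8)

    def test_exact_grid_crossing(self):
        dr = dose_response([0.0, 0.5, 1.0], [1.0, 0.5, 0.0])
        assert not dr.censored
        assert dr.gi50 == pytest.approx(0.5)

    def test_hill_response_recovers_half_inhibition(self):
        """GI50 interpolated from a Hill-shaped response lands within one
        grid step of the true half-inhibition constant."""
        K, h = 0.62, 3.0
        conc = np.arange(0.0, 2.01, 0.25)
        od = 1.1 / (1.0 + (conc / K) ** h)
        dr = dose_response(conc, od)
        assert abs(dr.gi50 - K) <= 0.25

    def test_auc_linear_in_od_scale(self):
        conc = [0.0, 0.3, 0.6, 1.0]
        od = np.array([1.0, 0.7, 0.4, 0.2])
        assert dose_response(conc, 3 * od).auc == pytest.approx(3 * dose_response(conc, od).auc)

    def test_missing_zero_reference_rejected(self):
        with pytest.raises(DomainError):
            dose_response([0.1, 0.5], [1.0, 0.5])


class TestCompetitionChange:
    def test_no_change(self):
        assert competition_change([50, 50], [50, 50]) == 0.0

    def test_forty_point_gain(self):
        assert competition_change([50, 50], [90, 10]) == pytest.approx(40.0)

    def test_bad_share_sums_rejected(self):
        with pytest.raises(InputError):
            competition_change([60, 50], [50, 50])
        with pytest.raises(InputError):
            competition_change([50, 50], [10, 10])
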