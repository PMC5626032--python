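"""Line fits, breakpoint profiling, model selection, NPQ correction, rates."""

import numpy as np
import pytest

from sinkassay import (
    SegmentedLinearModel,
    amplitudes,
    correct_npq_rise,
    extract_rates,
    fit_line,
    fit_segmented,
    select_model,
)
from sinkassay.segmented import _solve_at_psi


def piecewise(t, a, b1, b2, psi):
    return np.where(t <= psi, a + b1 * t, a + b1 * psi + b2 * (t - psi))


class TestFitLine:
    def test_exact_line_recovered(self):
        t = np.arange(0, 40, 2.0)
        fit = fit_line(t, 3.8 - 0.02 * t)
        assert fit.slope == pytest.approx(-0.02, abs=1e-12)
        assert fit.intercept == pytest.approx(3.8, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_fixed_intercept_closed_form(self):
        """Pinned-intercept slope equals sum t(y-c) / sum t^2 exactly."""
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 60, 25))
        y = 3.8 - 0.05 * t + rng.normal(0, 0.1, 25)
        c = 3.8
        fit = fit_line(t, y, fixed_intercept=c)
        oracle = np.sum(t * (y - c)) / np.sum(t * t)
        assert fit.slope == pytest.approx(oracle, abs=1e-10)
        assert fit.intercept == c and fit.fixed_intercept

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_line([0, 1], [1, 2])

    def test_degenerate_time(self):
        with pytest.raises(ValueError, match="variance"):
            fit_line([5, 5, 5], [1, 2, 3])


class TestFitSegmented:
    def test_noiseless_recovery(self):
        t = np.arange(0, 61, 2.0)
        y = piecewise(t, 3.8, -0.1, -0.01, 20.0)
        fit = fit_segmented(t, y)
        assert fit.intercept_mm == pytest.approx(3.8, abs=1e-6)
        assert fit.slope1_mm_per_min == pytest.approx(-0.1, abs=1e-6)
        assert fit.slope2_mm_per_min == pytest.approx(-0.01, abs=1e-6)
        assert fit.breakpoint_min == pytest.approx(20.0, abs=1e-6)
        assert fit.rss < 1e-12

    def test_pure_line_degenerates(self):
        t = np.arange(0, 30, 1.0)
        y = 3.8 - 0.05 * t
        fit = fit_segmented(t, y)
        single = fit_line(t, y)
        assert fit.rss <= single.rss + 1e-12
        assert fit.slope1_mm_per_min == pytest.approx(single.slope, abs=1e-6)
        assert fit.slope2_mm_per_min == pytest.approx(single.slope, abs=1e-6)

    def test_continuity_at_breakpoint(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 100, 30)
        y = piecewise(t, 3.8, -0.08, -0.005, 35.0) + rng.normal(0, 0.05, 30)
        fit = fit_segmented(t, y)
        psi = fit.breakpoint_min
        left = fit.intercept_mm + fit.slope1_mm_per_min * psi
        right = fit.predict(psi + 1e-12)
        assert abs(left - right) < 1e-9

    def test_rss_never_worse_than_single(self):
        rng = np.random.default_rng(4)
        for i in range(10):
            t = np.linspace(0, 60, rng.integers(10, 25))
            y = 3.0 - 0.02 * t + rng.normal(0, 0.2, t.size)
            assert fit_segmented(t, y).rss <= fit_line(t, y).rss + 1e-12

    def test_matches_brute_force_oracle(self):
        """Profiled breakpoint equals an exhaustive 1000-point grid scan."""
        rng = np.random.default_rng(7)
        for i in range(50):
            n = int(rng.integers(8, 31))
            t = np.sort(rng.uniform(0, 100, n))
            t[0] = 0.0
            psi_true = rng.uniform(t[3], t[-4])
            y = piecewise(
                t, 3.8, -rng.uniform(0.01, 0.2), -rng.uniform(0.001, 0.05), psi_true
            ) + rng.normal(0, 0.05, n)
            fit = fit_segmented(t, y)
            grid = np.linspace(t[2], t[-3], 1000)
            admissible = [
                p for p in grid if (t <= p).sum() >= 3 and (t > p).sum() >= 3
            ]
            rss_grid, psi_grid = min(
                (_solve_at_psi(t, y, p, None)[0], p) for p in admissible
            )
            step = grid[1] - grid[0]
            assert abs(fit.breakpoint_min - psi_grid) <= step
            assert fit.rss <= rss_grid + 1e-8

    def test_manual_breakpoint_override(self):
        t = np.arange(0, 61, 2.0)
        y = piecewise(t, 3.8, -0.1, -0.01, 20.0)
        fit = fit_segmented(t, y, breakpoint=25.0)
        assert fit.breakpoint_min == 25.0
        assert fit.manual_breakpoint

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_segmented(np.arange(5.0), np.arange(5.0))


class TestSelectModel:
    def test_strong_two_phase_selected(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 200, 40)
        y = piecewise(t, 3.8, -0.08, -0.008, 30.0) + rng.normal(0, 0.03, 40)
        res = SegmentedLinearModel(t, y).fit()
        assert res.model == "segmented"

    def test_minimal_perfect_line_stays_single(self):
        t = np.arange(6.0)
        y = 3.8 - 0.1 * t
        res = SegmentedLinearModel(t, y).fit()
        assert res.model == "single"

    def test_positive_second_slope_blocks_segmented(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 100, 30)
        y = piecewise(t, 3.8, -0.08, +0.01, 50.0) + rng.normal(0, 0.01, 30)
        single = fit_line(t, y)
        seg = fit_segmented(t, y)
        assert select_model(single, seg) == "single"

    def test_bic_criterion_available(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 200, 40)
        y = piecewise(t, 3.8, -0.08, -0.008, 30.0) + rng.normal(0, 0.03, 40)
        single = fit_line(t, y)
        seg = fit_segmented(t, y)
        assert select_model(single, seg, criterion="bic") == "segmented"


class TestNpqCorrection:
    def test_thirty_minute_rise_excised_and_rescaled(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 200, 81)
        y = np.where(t <= 30, 2.0 + 0.05 * t, 3.5 - 0.012 * (t - 30))
        y = y + rng.normal(0, 0.02, t.size)
        corr = correct_npq_rise(t, y, 3.8)
        assert corr.npq_corrected
        assert corr.rise_end_min == pytest.approx(30.0, abs=5.0)
        assert corr.times.min() > corr.rise_end_min
        # rescaled so the sinking line extrapolates to the culture depth
        sink = fit_line(corr.times, corr.depth_signal)
        assert sink.intercept == pytest.approx(3.8, rel=0.02)

    def test_monotone_decline_unchanged(self):
        t = np.linspace(0, 100, 25)
        y = 3.8 - 0.02 * t
        corr = correct_npq_rise(t, y, 3.8)
        assert not corr.npq_corrected
        np.testing.assert_array_equal(corr.depth_signal, y)

    def test_monotone_rise_is_an_error(self):
        t = np.linspace(0, 60, 20)
        with pytest.raises(ValueError, match="no sinking phase"):
            correct_npq_rise(t, 1.0 + 0.05 * t, 3.8)

    def test_noise_alone_not_flagged(self):
        rng = np.random.default_rng(12)
        flagged = 0
        t = np.linspace(0, 200, 40)
        for i in range(40):
            y = 3.8 - 0.012 * t + rng.normal(0, 0.03, 40)
            flagged += correct_npq_rise(t, y, 3.8).npq_corrected
        assert flagged <= 4  # about the nominal one-sided level


class TestAmplitudes:
    def test_single_fit_amplitude_one(self):
        t = np.arange(0, 30, 1.0)
        res = SegmentedLinearModel(t, 3.8 - 0.02 * t).fit()
        a1, a2 = amplitudes(res, 3.8)
        assert a1 == 1.0 and a2 is None

    def test_fractional_drop_definition(self):
        t = np.arange(0, 61, 2.0)
        y = piecewise(t, 3.8, -0.1, -0.01, 20.0)
        fit = fit_segmented(t, y)
        a1, a2 = amplitudes(fit, 3.8)
        assert a1 == pytest.approx((3.8 - 1.8) / 3.8, abs=1e-6)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-9)

    def test_conservation_across_random_fits(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            t = np.linspace(0, 150, 35)
            y = piecewise(
                t, 3.8, -rng.uniform(0.02, 0.1), -rng.uniform(0.001, 0.01),
                rng.uniform(20, 80),
            ) + rng.normal(0, 0.03, 35)
            fit = fit_segmented(t, y)
            a1, a2 = amplitudes(fit, 3.8)
            assert a1 + a2 == pytest.approx(1.0, abs=1e-9)


class TestExtractRates:
    def test_chain_former_scale(self):
        # a first-phase slope of -0.0424 mm/min is ~0.061 m/d
        t = np.arange(0, 61, 2.0)
        y = piecewise(t, 3.8, -0.0424, -0.0125, 20.0)
        rates = extract_rates(fit_segmented(t, y), 3.8)
        assert rates.rate1_m_per_day == pytest.approx(0.061, abs=0.001)
        assert rates.rate2_m_per_day == pytest.approx(0.018, abs=0.001)

    def test_single_fit_has_no_second_phase(self):
        t = np.arange(0, 30, 1.0)
        res = SegmentedLinearModel(t, 3.8 - 0.02 * t).fit()
        rates = extract_rates(res, 3.8)
        assert rates.rate2_m_per_day is None
        assert rates.amplitude1 == 1.0

    def test_zero_slope_gives_zero_rate(self):
        t = np.arange(0, 30, 1.0)
        rng = np.random.default_rng(0)
        res = SegmentedLinearModel(t, np.full(30, 3.8)).fit_single()
        assert extract_rates(res, 3.8).rate1_m_per_day == 0.0

    def test_rising_slope_rejected(self):
        t = np.arange(0, 30, 1.0)
        res = SegmentedLinearModel(t, 1.0 + 0.02 * t).fit_single()
        with pytest.raises(ValueError, match="rising"):
            extract_rates(res, 3.8)


class TestRecoveryFromGenerativeKernel:
    def test_single_population_rate_within_linearization_bias(self):
        """On a noiseless inverse-square trace with ts <= 0.2 the linear
        fit recovers depth * s * 1.44 within the 20% bias bound."""
        from sinkassay import depth_transform, forward_scaled

        s, depth = 0.002, 3.8
        t = np.linspace(0, 100, 30)  # ts <= 0.2
        y = depth_transform(forward_scaled(t, s), depth)
        fit = fit_line(t, y)
        rate = extract_rates(
            SegmentedLinearModel(t, y).fit_single(), depth
        ).rate1_m_per_day
        expected = depth * s * 1.44
        assert abs(rate - expected) / expected < 0.20
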