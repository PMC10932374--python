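"""Exponential fitting, readout rules and their independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import relaxmap as rm
from relaxmap.relaxometry import ReadoutDomainError, batch_fit

from conftest import WORKED_IS_T1, WORKED_TR_MS


def grid_search_t1(x, y, rounds=14, pts=15):
    """Independent coarse-to-fine 3D grid search over (a, b, c) for the
    saturation-recovery model; brute-force oracle, no derivative code shared
    with the implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a_lo, a_hi = 0.5 * y.max(), 2.0 * y.max()
    b_lo, b_hi = 0.05, 2.5 * y.max()
    c_lo, c_hi = 1000.0 / x[-1] / 20.0, 1000.0 / x[0] * 20.0
    best = None
    for _ in range(rounds):
        aa = np.linspace(a_lo, a_hi, pts)
        bb = np.linspace(b_lo, b_hi, pts)
        cc = np.geomspace(c_lo, c_hi, pts)
        model = (aa[:, None, None, None]
                 - bb[None, :, None, None]
                 * np.exp(-cc[None, None, :, None] * x[None, None, None, :] / 1000.0))
        cost = ((model - y[None, None, None, :]) ** 2).sum(axis=-1)
        i, j, k = np.unravel_index(np.argmin(cost), cost.shape)
        best = (aa[i], bb[j], cc[k])
        # shrink slowly (+-3 grid steps) so the correlated (a, b, c) optimum
        # cannot escape the refined box between rounds
        da, db = aa[1] - aa[0], bb[1] - bb[0]
        a_lo, a_hi = best[0] - 3 * da, best[0] + 3 * da
        b_lo, b_hi = max(best[1] - 3 * db, 1e-6), best[1] + 3 * db
        ratio = (cc[1] / cc[0]) ** 3
        c_lo, c_hi = best[2] / ratio, best[2] * ratio
    return best


class TestNormalize:
    def test_scaling(self):
        np.testing.assert_allclose(rm.normalize_signal([2, 4, 8]),
                                   [0.25, 0.5, 1.0])

    def test_idempotent_on_normalized_vector(self):
        once = rm.normalize_signal(WORKED_IS_T1)
        np.testing.assert_allclose(rm.normalize_signal(once), once)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate signal"):
            rm.normalize_signal([0.0, 0.0, 0.0])

    @given(st.lists(st.floats(0.01, 1e6), min_size=3, max_size=12),
           st.floats(0.1, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, values, scale):
        base = rm.normalize_signal(values)
        scaled = rm.normalize_signal(np.asarray(values) * scale)
        np.testing.assert_allclose(scaled, base, rtol=1e-9)
        assert base.max() == pytest.approx(1.0)


class TestT1Readout:
    def test_ideal_coefficients_give_1000_over_c(self):
        assert rm.t1_readout(1.0, 1.0, 1.0) == pytest.approx(1000.0)

    def test_worked_rate_gives_2250(self):
        assert rm.t1_readout(1.0, 1.0, 0.44444) == pytest.approx(2250.0, abs=0.1)

    def test_plateau_below_readout_fraction_is_domain_error(self):
        with pytest.raises(ReadoutDomainError):
            rm.t1_readout(0.5, 1.0, 1.0)

    def test_readout_fractions_match_printed_constants(self):
        assert rm.SR_RECOVERY_FRACTION == pytest.approx(0.6321, abs=5e-5)
        assert rm.T2_DECAY_FRACTION == pytest.approx(0.3679, abs=5e-5)


class TestFitT1:
    def test_worked_example_vector(self):
        """The printed 9-point vector fits to T1 = 2250 ms, R^2 ~ 1."""
        fit = rm.fit_t1(WORKED_TR_MS, WORKED_IS_T1)
        assert fit.valid
        assert fit.time_ms == pytest.approx(2250.0, rel=0.01)
        assert fit.r_squared > 0.9999

    def test_simulator_round_trip_800ms(self, uniform_t1_series):
        stack = uniform_t1_series.stack()
        fit = rm.fit_t1(uniform_t1_series.varied_times_ms, stack[:, 0, 0])
        assert fit.valid
        assert fit.time_ms == pytest.approx(800.0, rel=0.005)

    @pytest.mark.parametrize("t1", [200.0, 500.0, 800.0, 1100.0, 2250.0, 3000.0])
    def test_noiseless_recovery_under_half_percent(self, tr_schedule, t1):
        y = 1.0 - np.exp(-tr_schedule / t1)
        fit = rm.fit_t1(tr_schedule, y)
        assert fit.valid
        assert abs(fit.time_ms - t1) / t1 < 0.005
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_intensities_invalid(self, tr_schedule):
        fit = rm.fit_t1(tr_schedule, np.ones_like(tr_schedule))
        assert not fit.valid
        assert fit.time_ms == 0.0

    def test_noisy_recovery_median_error(self, tr_schedule):
        """Median |error| over 1000 noisy pixels at SNR 50 stays under 3%."""
        rng = np.random.default_rng(123)
        t1 = 1100.0
        clean = 1.0 - np.exp(-tr_schedule / t1)
        errors = []
        for _ in range(1000):
            # PD = 1 pixels are already on the unit scale; fitting the raw
            # magnitudes avoids compounding the noise of the per-pixel maximum
            y = np.hypot(clean + rng.normal(0, 0.02, clean.size),
                         rng.normal(0, 0.02, clean.size))
            fit = rm.fit_t1(tr_schedule, y)
            if fit.valid:
                errors.append(abs(fit.time_ms - t1) / t1)
        assert len(errors) > 950
        assert np.median(errors) < 0.03

    def test_inverse_consistency(self, tr_schedule):
        """The fitted curve evaluated at time_ms sits at the 1 - 1/e point."""
        rng = np.random.default_rng(5)
        for t1 in rng.uniform(300, 3000, 10):
            y = 1.0 - np.exp(-tr_schedule / t1)
            fit = rm.fit_t1(tr_schedule, y)
            value = fit.a - fit.b * math.exp(-fit.c * fit.time_ms / 1000.0)
            assert value == pytest.approx(rm.SR_RECOVERY_FRACTION, abs=1e-6)

    def test_r2_decreases_with_noise_in_expectation(self, tr_schedule):
        rng = np.random.default_rng(9)
        clean = 1.0 - np.exp(-tr_schedule / 1100.0)
        mean_r2 = []
        for sigma in (0.005, 0.02, 0.08):
            r2s = []
            for _ in range(40):
                y = np.hypot(clean + rng.normal(0, sigma, clean.size),
                             rng.normal(0, sigma, clean.size))
                r2s.append(rm.fit_t1(tr_schedule, rm.normalize_signal(y)).r_squared)
            mean_r2.append(np.mean(r2s))
        assert mean_r2[0] > mean_r2[1] > mean_r2[2]

    def test_grid_search_oracle_equivalence(self, tr_schedule):
        """Trust-region fits agree with a brute-force (a, b, c) grid search
        within 0.1% in the derived time on 20 random noiseless instances."""
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 20:
            t1 = rng.uniform(300, 4000)
            a = rng.uniform(0.9, 1.1)
            b = a * rng.uniform(0.9, 1.0)
            y = a - b * np.exp(-tr_schedule / t1)
            fit = rm.fit_t1(tr_schedule, y)
            if not fit.valid:
                continue
            ga, gb, gc = grid_search_t1(tr_schedule, y)
            oracle_time = rm.t1_readout(ga, gb, gc)
            assert abs(fit.time_ms - oracle_time) / oracle_time < 1e-3
            checked += 1


class TestFitT2:
    def test_noiseless_round_trip(self, te_schedule):
        y = np.exp(-te_schedule / 100.0)
        fit = rm.fit_t2(te_schedule, y)
        assert fit.valid
        assert fit.time_ms == pytest.approx(100.0, rel=0.005)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_model_points(self):
        te = np.array([1e-6, 100.0, 200.0])
        y = np.exp(-te / 100.0)
        fit = rm.fit_t2(te, y)
        assert fit.time_ms == pytest.approx(100.0, rel=1e-6)

    def test_constant_intensities_invalid(self, te_schedule):
        fit = rm.fit_t2(te_schedule, np.ones_like(te_schedule))
        assert not fit.valid

    def test_inverse_consistency(self, te_schedule):
        """The fitted curve at time_ms equals 1/e of its TE = 0 maximum."""
        for t2 in (30.0, 100.0, 250.0):
            fit = rm.fit_t2(te_schedule, 0.8 * np.exp(-te_schedule / t2))
            value = fit.a * math.exp(-fit.c * fit.time_ms / 1000.0)
            assert value == pytest.approx(fit.a * rm.T2_DECAY_FRACTION,
                                          abs=1e-6)


class TestBiexponential:
    def test_single_exponential_data_matches_mono(self, te_schedule):
        y = np.exp(-te_schedule / 100.0)
        mono = rm.fit_t2(te_schedule, y)
        bi = rm.fit_biexponential(te_schedule, y, mode="T2")
        assert bi.valid
        assert abs(bi.time_ms - mono.time_ms) / mono.time_ms < 0.02
        assert bi.components[1][0] <= 0.02 * (bi.components[0][0] + 1e-12)

    def test_two_component_mixture_recovered(self):
        """A 50/50 mixture of T2 = 30 and 300 ms sampled densely is separated
        within 10% of each true component (grid-search initialised fit)."""
        te = np.linspace(5, 600, 40)
        y = 0.5 * np.exp(-te / 30.0) + 0.5 * np.exp(-te / 300.0)
        fit = rm.fit_biexponential(te, y, mode="T2")
        assert fit.valid
        times = sorted(comp[2] for comp in fit.components)
        assert times[0] == pytest.approx(30.0, rel=0.10)
        assert times[1] == pytest.approx(300.0, rel=0.10)

    def test_t1_mixture_dominant_component(self, tr_schedule):
        y = 1.0 - 1.0 * np.exp(-tr_schedule / 900.0)
        fit = rm.fit_biexponential(tr_schedule, y, mode="T1")
        assert fit.valid
        mono = rm.fit_t1(tr_schedule, y)
        assert abs(fit.time_ms - 1000.0 / mono.c) / (1000.0 / mono.c) < 0.02

    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="insufficient points"):
            rm.fit_biexponential([10.0, 20.0, 40.0, 80.0], [1, 0.8, 0.5, 0.3],
                                 mode="T2")


class TestBatchFit:
    def test_matches_scalar_fitters_on_clean_data(self, tr_schedule, te_schedule):
        """The vectorised map solver and the scipy per-pixel solvers minimise
        the same objective: identical answers on noiseless pixels."""
        rng = np.random.default_rng(7)
        t1s = rng.uniform(200, 3000, 15)
        Y = np.array([rm.normalize_signal(1 - np.exp(-tr_schedule / t)) for t in t1s])
        out = batch_fit(tr_schedule, Y, "T1", normalize=False)
        for i, t in enumerate(t1s):
            f = rm.fit_t1(tr_schedule, Y[i])
            assert abs(out["time_ms"][i] - f.time_ms) / f.time_ms < 1e-6
        t2s = rng.uniform(20, 400, 15)
        Y = np.array([np.exp(-te_schedule / t) for t in t2s])
        out = batch_fit(te_schedule, Y, "T2", normalize=False)
        for i, t in enumerate(t2s):
            f = rm.fit_t2(te_schedule, Y[i])
            assert abs(out["time_ms"][i] - f.time_ms) / f.time_ms < 1e-6

    def test_zero_rows_are_invalid(self, tr_schedule):
        Y = np.zeros((3, tr_schedule.size))
        out = batch_fit(tr_schedule, Y, "T1")
        assert not out["valid"].any()
        assert np.all(out["time_ms"] == 0)


class TestSmoothing:
    def test_none_is_identity(self):
        stack = np.random.default_rng(0).random((3, 8, 8))
        np.testing.assert_array_equal(rm.smooth_series(stack, "none"), stack)

    def test_mean3_preserves_constant_images(self):
        stack = np.full((3, 8, 8), 4.2)
        np.testing.assert_allclose(rm.smooth_series(stack, "mean3"), stack)

    def test_mean3_spreads_impulse_over_neighborhood(self):
        stack = np.zeros((1, 9, 9))
        stack[0, 4, 4] = 9.0
        smoothed = rm.smooth_series(stack, "mean3")
        np.testing.assert_allclose(smoothed[0, 3:6, 3:6], 1.0)
        assert smoothed[0, 0, 0] == 0.0

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="unknown smoothing kernel"):
            rm.smooth_series(np.zeros((3, 4, 4)), "median5")

    def test_gaussian_kernel_parses_sigma(self):
        stack = np.random.default_rng(1).random((2, 16, 16))
        out = rm.smooth_series(stack, "gaussian:1.5")
        assert out.shape == stack.shape
        assert not np.allclose(out, stack)
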