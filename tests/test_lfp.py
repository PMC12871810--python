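"""OU fitting, simulation round trips, wavelet decomposition, ADF profiling."""

import numpy as np
import pytest

from neurostab import (
    OUFitter,
    OUParams,
    OUSpec,
    TraceRecord,
    adf_profile,
    adf_test,
    cwt,
    fit_ou,
    gen_ou,
    gen_random_walk,
    raw_power,
    simulate_fitted,
)
from neurostab.lfp import default_freq_grid, fit_acf_decay


class TestFitOU:
    def test_exact_exponential_acf_self_fit(self):
        # feeding the model its own ACF must return the planted constant
        dt, tau = 1e-3, 0.02
        lags = np.arange(500) * dt
        tau_hat, rmse, _ = fit_acf_decay(np.exp(-lags / tau), dt)
        assert tau_hat == pytest.approx(tau, rel=1e-6)
        assert rmse < 1e-9

    def test_ou_parameter_recovery_single_seed(self):
        trace = gen_ou(OUSpec(tau=0.05, sigma=1.0, dt=1e-3, n=60_000, seed=11))
        params = fit_ou(trace)
        assert params.tau == pytest.approx(0.05, rel=0.10)
        assert params.sigma == pytest.approx(1.0, rel=0.05)

    def test_white_noise_collapses_to_sampling_scale(self, rng):
        trace = TraceRecord(rng.normal(0, 1, 20_000), 1e-3)
        assert fit_ou(trace).tau <= 2e-3

    def test_offset_invariance(self):
        trace = gen_ou(OUSpec(tau=0.05, sigma=1.0, dt=1e-3, n=30_000, seed=12))
        shifted = TraceRecord(trace.samples + 123.4, trace.dt)
        a, b = fit_ou(trace), fit_ou(shifted)
        assert a.tau == pytest.approx(b.tau, rel=1e-9)
        assert a.sigma == pytest.approx(b.sigma, rel=1e-9)
        assert b.mu == pytest.approx(a.mu + 123.4)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_ou(TraceRecord(np.full(1000, 2.0), 1e-3))


class TestSimulateFitted:
    def test_round_trip_self_consistency(self):
        params = OUParams(tau=0.05, sigma=1.0, mu=0.0)
        trace = simulate_fitted(params, n=60_000, dt=1e-3, seed=13)
        refit = fit_ou(trace)
        assert refit.tau == pytest.approx(0.05, rel=0.10)
        assert refit.sigma == pytest.approx(1.0, rel=0.05)

    def test_zero_sigma_constant(self):
        trace = simulate_fitted(OUParams(tau=0.05, sigma=0.0, mu=-2.0), 1000, 1e-3, seed=0)
        np.testing.assert_allclose(trace.samples, -2.0)

    def test_seeds_differ_but_moments_agree(self):
        p = OUParams(tau=0.05, sigma=1.0, mu=0.0)
        a = simulate_fitted(p, 60_000, 1e-3, seed=1).samples
        b = simulate_fitted(p, 60_000, 1e-3, seed=2).samples
        assert not np.array_equal(a, b)
        assert np.std(a) == pytest.approx(np.std(b), rel=0.05)

    def test_estimator_fit_sample(self):
        trace = gen_ou(OUSpec(tau=0.03, sigma=0.8, dt=1e-3, n=40_000, seed=14))
        fitter = OUFitter().fit(trace)
        sim = fitter.sample(n=10_000, dt=1e-3, seed=5)
        assert sim.n_samples == 10_000


class TestCWT:
    def test_pure_tone_ridge_on_grid(self):
        dt, n = 1e-3, 20_000
        grid = np.linspace(2, 50, 25)  # contains exactly 10 Hz
        trace = TraceRecord(np.sin(2 * np.pi * 10 * np.arange(n) * dt), dt)
        dec = cwt(trace, grid)
        ridge = dec.frequencies[np.argmax(dec.time_avg_power())]
        assert ridge == pytest.approx(10.0, abs=1e-6)

    def test_ridge_within_one_grid_step_across_default_grid(self):
        dt, n = 1e-3, 60_000
        grid = default_freq_grid(0.5, 100.0, 32)
        for f0 in (1.0, 4.0, 20.0, 80.0):
            trace = TraceRecord(np.sin(2 * np.pi * f0 * np.arange(n) * dt), dt)
            dec = cwt(trace, grid)
            ridge_idx = int(np.argmax(dec.time_avg_power()))
            nearest_idx = int(np.argmin(np.abs(dec.frequencies - f0)))
            assert abs(ridge_idx - nearest_idx) <= 1

    def test_zero_signal_zero_power(self):
        dec = cwt(TraceRecord(np.zeros(5000), 1e-3), np.linspace(2, 50, 10))
        assert np.all(dec.power == 0)

    def test_two_tone_local_maxima(self):
        dt, n = 1e-3, 20_000
        t = np.arange(n) * dt
        trace = TraceRecord(np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t), dt)
        dec = cwt(trace)
        p = dec.time_avg_power()
        locmax = dec.frequencies[
            [i for i in range(1, p.size - 1) if p[i] > p[i - 1] and p[i] > p[i + 1]]
        ]
        for f0 in (5.0, 40.0):
            nearest = dec.frequencies[np.argmin(np.abs(dec.frequencies - f0))]
            assert np.min(np.abs(locmax - nearest)) == pytest.approx(0.0, abs=1e-9)

    def test_supra_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|frequencies"):
            cwt(TraceRecord(np.zeros(1000), 1e-3), [600.0])


class TestRawPower:
    def test_amplitude_doubling_quadruples_power(self):
        dt, n = 1e-3, 20_000
        grid = np.linspace(2, 50, 25)
        t = np.arange(n) * dt
        _, p1 = raw_power(TraceRecord(np.sin(2 * np.pi * 10 * t), dt), grid)
        _, p2 = raw_power(TraceRecord(2 * np.sin(2 * np.pi * 10 * t), dt), grid)
        assert p2.max() / p1.max() == pytest.approx(4.0, rel=1e-9)

    def test_white_noise_flat_band_power(self, rng):
        trace = TraceRecord(rng.normal(0, 1, 100_000), 1e-3)
        _, p = raw_power(trace)
        assert p.max() <= 3 * np.median(p)

    def test_zero_trace(self):
        _, p = raw_power(TraceRecord(np.zeros(5000), 1e-3), np.linspace(2, 50, 8))
        assert np.all(p == 0)


class TestADF:
    def test_stationary_vs_unit_root_series(self):
        ou = gen_ou(OUSpec(tau=0.02, sigma=1.0, dt=1e-3, n=2000, seed=21))
        rw = gen_random_walk(2000, 1.0, seed=21)
        assert adf_test(ou.samples)[1] < 0.05
        assert adf_test(rw.samples)[1] > 0.05

    def test_five_point_fixed_lag_matches_ols_oracle(self):
        # Dickey-Fuller with zero augmentation lags: regress diff(x) on
        # [1, x_{t-1}]; the statistic is the t-ratio of the level coefficient
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.5])
        stat, _, used = adf_test(x, lag_order=0)
        assert used == 0
        dy = np.diff(x)
        X = np.column_stack([np.ones(4), x[:-1]])
        beta, res_ss, *_ = np.linalg.lstsq(X, dy, rcond=None)
        resid = dy - X @ beta
        s2 = resid @ resid / (4 - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert stat == pytest.approx(beta[1] / se, rel=1e-9)

    def test_alternating_series_strongly_mean_reverting(self):
        # perfectly mean-reverting 5-point series: the DF regression fits it
        # exactly, driving the statistic to -inf / p to 0 (degenerate case)
        stat, p, _ = adf_test(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), lag_order=0)
        assert stat < -10 or np.isinf(stat) or p < 1e-6

    def test_constant_series_degenerate(self):
        stat, p, used = adf_test(np.full(100, 1.0))
        assert np.isnan(stat) and np.isnan(p)


class TestADFProfile:
    def test_band_profile_discriminates(self):
        grid = default_freq_grid(0.5, 100.0, 16)
        rw = gen_random_walk(60_000, 1.0, seed=31)
        ou = gen_ou(OUSpec(tau=0.02, sigma=1.0, dt=1e-3, n=60_000, seed=31))
        prof_rw = adf_profile(cwt(rw, grid), lag_order=5)
        prof_ou = adf_profile(cwt(ou, grid), lag_order=5)
        # the lowest band keeps the stochastic trend of a random walk ...
        assert prof_rw.p_value[-1] > 0.05
        # ... and is stationary for a short-memory OU
        assert prof_ou.p_value[-1] < 0.05
        assert np.all((prof_rw.p_value >= 0) & (prof_rw.p_value <= 1))

    def test_constant_bands_flagged(self):
        dec = cwt(TraceRecord(np.zeros(5000), 1e-3), np.linspace(2, 50, 4))
        prof = adf_profile(dec)
        assert prof.degenerate.all()
        assert np.isnan(prof.p_value).all()

    def test_short_bands_rejected(self):
        dec = cwt(TraceRecord(np.random.default_rng(0).normal(0, 1, 60), 1e-3),
                  [100.0, 200.0])
        with pytest.raises(ValueError, match="at least 50"):
            adf_profile(
                type(dec)(
                    coefficients=dec.coefficients[:, :40],
                    frequencies=dec.frequencies,
                    scales=dec.scales,
                    wavelet=dec.wavelet,
                    dt=dec.dt,
                )
            )
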