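import math

import numpy as np
import pytest

from pmfbind import (
    TimeSeries,
    UmbrellaWindow,
    autocorrelation,
    bootstrap_pmf,
    convergence_depths,
    tau_from_acf,
)


def _ts(values, window=None, label=""):
    return TimeSeries(values=np.asarray(values, float), save_interval_ps=1.0,
                      window=window, label=label)


def _ar1(phi, n, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    eps = rng.normal(0, scale, n)
    x = np.empty(n)
    x[0] = eps[0] / math.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestAutocorrelation:
    def test_white_noise_has_negligible_lag1(self):
        rng = np.random.default_rng(7)
        rep = autocorrelation(_ts(rng.normal(size=100_000)), max_lag=20)
        assert rep.acf[0] == pytest.approx(1.0)
        assert abs(rep.acf[1]) < 0.02  # ~1/sqrt(n) sampling bound
        assert rep.tau_e == 1

    def test_ar1_recovers_closed_form(self):
        """AR(1) with phi=0.5: rho(l) = 0.5^l, and tau_e = 2 because
        0.5 > 1/e >= 0.25."""
        rep = autocorrelation(_ts(_ar1(0.5, 100_000, seed=3)), max_lag=10)
        for lag in (1, 2, 3):
            assert rep.acf[lag] == pytest.approx(0.5**lag, abs=0.02)
        assert rep.tau_e == 2

    def test_tie_break_is_inclusive_at_one_over_e(self):
        """An ACF exactly at 1/e at lag 1 counts as decorrelated there."""
        assert tau_from_acf([1.0, 1.0 / math.e, 0.1]) == 1
        assert tau_from_acf([1.0, 1.0 / math.e + 1e-12, 0.1]) == 2
        # and the estimate from data is consistent with the same rule
        rep = autocorrelation(_ts(_ar1(1.0 / math.e, 100_000, seed=5)), max_lag=10)
        assert rep.tau_e == tau_from_acf(rep.acf)
        assert rep.tau_e in (1, 2)  # phi = 1/e sits on the threshold

    def test_alternating_sequence_has_lag1_of_minus_one(self):
        rep = autocorrelation(_ts(np.tile([1.0, -1.0], 500)), max_lag=2)
        assert rep.acf[1] == pytest.approx(-1.0, abs=1e-3)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            autocorrelation(_ts(np.ones(100)), max_lag=5)

    def test_max_lag_must_fit_series(self):
        with pytest.raises(ValueError, match="length"):
            autocorrelation(_ts(np.arange(10.0)), max_lag=10)


class TestBootstrap:
    def _degenerate_setup(self):
        # each window sits entirely in one bin -> every resample identical
        windows = [UmbrellaWindow(0.5, 5.0, "a"), UmbrellaWindow(1.5, 5.0, "b")]
        series = [_ts([0.5] * 40, windows[0], "a"), _ts([1.5] * 40, windows[1], "b")]
        edges = np.array([0.0, 1.0, 2.0])
        return series, windows, edges

    def test_degenerate_resampling_gives_zero_sigma(self):
        series, windows, edges = self._degenerate_setup()
        res = bootstrap_pmf(series, windows, edges, n_boot=10, seed=1, stride=1)
        assert np.allclose(res.sigma[np.isfinite(res.sigma)], 0.0)
        assert res.sigma_max == 0.0

    def test_replicate_count_contract(self, small_window_set, small_edges):
        series = small_window_set
        res = bootstrap_pmf(series, [ts.window for ts in series], small_edges,
                            n_boot=10, seed=4)
        assert res.n_boot == 10
        assert len(res.profiles) == 10

    def test_bitwise_reproducible_under_seed(self, small_window_set, small_edges):
        series = small_window_set
        windows = [ts.window for ts in series]
        r1 = bootstrap_pmf(series, windows, small_edges, n_boot=4, seed=9)
        r2 = bootstrap_pmf(series, windows, small_edges, n_boot=4, seed=9)
        assert np.array_equal(r1.sigma, r2.sigma, equal_nan=True)
        assert r1.sigma_max == r2.sigma_max

    def test_sigma_shrinks_with_more_data(self, binding_well):
        """Pointwise bootstrap error decays as per-window sampling grows
        (3-point ladder, monotone within noise)."""
        from pmfbind import SimConfig, generate_window_set

        sigmas = []
        for n in (400, 1600, 6400):
            cfg = SimConfig(seed=23, dt=0.005, n_steps=n * 600, s_save=600)
            series = generate_window_set(binding_well, 0.0, 10.5, 1.5, 4.0, cfg)
            windows = [ts.window for ts in series]
            edges = np.arange(-0.5, 11.3, 0.5)
            sigmas.append(bootstrap_pmf(series, windows, edges, n_boot=10,
                                        seed=2, stride=1).sigma_max)
        assert sigmas[2] < sigmas[0] / 2  # ~4x expected over a 16x n ratio
        assert sigmas[1] < sigmas[0] * 1.3
        assert sigmas[2] < sigmas[1] * 1.3

    def test_too_few_decorrelated_samples_is_an_error(self):
        series, windows, edges = self._degenerate_setup()
        short = [_ts([0.5] * 5, windows[0], "a"), _ts([1.5] * 40, windows[1], "b")]
        with pytest.raises(ValueError, match="need >= 10"):
            bootstrap_pmf(short, windows, edges, n_boot=10, seed=1, stride=1)


class TestConvergence:
    def test_full_fraction_reproduces_full_depth(self, small_window_set, small_edges):
        from pmfbind import build_histograms, solve_wham

        series = small_window_set
        windows = [ts.window for ts in series]
        rep = convergence_depths(series, [1.0], windows, small_edges)
        profile, _ = solve_wham(build_histograms(series, small_edges), windows)
        assert rep.depths[0] == pytest.approx(profile.depth(), abs=1e-9)
        assert rep.drift == 0.0

    def test_stationary_data_shows_small_drift(self, small_window_set, small_edges):
        series = small_window_set
        windows = [ts.window for ts in series]
        rep = convergence_depths(series, [0.25, 0.5, 0.75, 1.0], windows, small_edges)
        boot = bootstrap_pmf(series, windows, small_edges, n_boot=10, seed=11)
        assert rep.drift <= 4 * boot.sigma_max

    def test_injected_mean_ramp_is_detected(self, small_window_set, small_edges):
        """A nonstationary dataset (drifting coordinate) must show depth
        drift well beyond the stationary level — the diagnostic's job."""
        series = small_window_set
        windows = [ts.window for ts in series]
        stationary = convergence_depths(series, [0.25, 0.5, 0.75, 1.0],
                                        windows, small_edges)
        ramped = []
        for ts in series:
            x = ts.production().copy()
            # deepest-well window drifts 1.5 Å over the run
            if abs(ts.window.center - 1.5) < 0.1:
                x = x + np.linspace(0, 1.5, x.size)
            ramped.append(_ts(np.clip(x, -0.5, 11.2), ts.window, ts.label))
        drifted = convergence_depths(ramped, [0.25, 0.5, 0.75, 1.0],
                                     windows, small_edges)
        assert drifted.drift > 3 * stationary.drift

    def test_fraction_validation(self, small_window_set, small_edges):
        windows = [ts.window for ts in small_window_set]
        with pytest.raises(ValueError, match="1.0"):
            convergence_depths(small_window_set, [0.5], windows, small_edges)
        with pytest.raises(ValueError, match="increasing"):
            convergence_depths(small_window_set, [0.8, 0.5, 1.0], windows, small_edges)
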