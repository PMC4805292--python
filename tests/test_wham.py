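import numpy as np
import pytest

from oracles import rezero_bulk, wham_fixed_point
from pmfbind import (
    PMFProfile,
    TimeSeries,
    UmbrellaWindow,
    WhamConvergenceError,
    build_histograms,
    rezero_pmf,
    solve_wham,
)

TINY_SPRING = 1e-30  # numerically unbiased window (spring must be > 0)


def _series(values, window=None, label=""):
    return TimeSeries(values=np.asarray(values, float), save_interval_ps=1.0,
                      window=window, label=label)


class TestBuildHistograms:
    def test_identical_values_land_in_one_bin(self):
        h = build_histograms([_series([1.2] * 100)], np.array([0.0, 1.0, 2.0]))
        assert h.counts.tolist() == [[0.0, 100.0]]
        assert h.n_samples.tolist() == [100.0]

    def test_stride_subsamples(self):
        h = build_histograms([_series(np.linspace(0.1, 0.9, 100))],
                             np.array([0.0, 1.0]), stride=2)
        assert h.n_samples.tolist() == [50.0]

    def test_value_at_last_edge_is_dropped(self):
        h = build_histograms([_series([0.5, 2.0])], np.array([0.0, 1.0, 2.0]))
        assert h.counts.sum() == 1
        assert h.n_dropped.tolist() == [1]

    def test_fully_out_of_range_window_is_an_error(self):
        with pytest.raises(ValueError, match="winA"):
            build_histograms([_series([5.0, 6.0], label="winA")],
                             np.array([0.0, 1.0]))


class TestSolveWham:
    def test_single_unbiased_window_is_boltzmann_inversion(self):
        """With no bias WHAM degenerates to W_j = −ln(n_j/N) + const."""
        rng = np.random.default_rng(0)
        x = rng.normal(1.5, 0.5, size=5000)
        edges = np.linspace(0, 3, 13)
        w = UmbrellaWindow(center=0.0, spring=TINY_SPRING)
        ts = _series(x[(x >= 0) & (x < 3)], window=w)
        h = build_histograms([ts], edges)
        profile, fes = solve_wham(h, [w])
        direct = -np.log(h.counts[0] / h.n_samples[0])
        fm = profile.finite_mask
        direct = direct - direct[fm][-1]
        assert np.max(np.abs(profile.w[fm] - direct[fm])) < 1e-10

    def test_duplicated_window_equals_doubled_counts(self, small_window_set,
                                                     small_edges):
        """WHAM weights windows by sample count, so listing the same data
        twice is exactly equivalent to one window with doubled counts."""
        series = list(small_window_set[:4])
        windows = [ts.window for ts in series]
        h_dup = build_histograms(series + [series[1]], small_edges)
        p_dup, _ = solve_wham(h_dup, windows + [windows[1]], tol=1e-11)
        h_merged = build_histograms(series, small_edges)
        h_merged.counts[1] *= 2
        h_merged.n_samples[1] *= 2
        p_merged, _ = solve_wham(h_merged, windows, tol=1e-11)
        fm = p_dup.finite_mask & p_merged.finite_mask
        assert np.max(np.abs(p_dup.w[fm] - p_merged.w[fm])) < 1e-6

    def test_two_window_toy_matches_brute_force_oracle(self):
        """Hand-fixed counts on 5 bins vs the naive fixed-point solver."""
        edges = np.linspace(0, 5, 6)
        centers = 0.5 * (edges[:-1] + edges[1:])
        windows = [UmbrellaWindow(center=1.0, spring=0.5),
                   UmbrellaWindow(center=3.5, spring=0.8)]
        counts = np.array([[40.0, 80.0, 60.0, 15.0, 5.0],
                           [2.0, 20.0, 70.0, 90.0, 18.0]])
        h = build_histograms(
            [_series(np.repeat(centers, counts[i].astype(int)), window=windows[i])
             for i in range(2)],
            edges,
        )
        assert np.array_equal(h.counts, counts)
        profile, fes = solve_wham(h, windows, tol=1e-12)
        bias = [[w.bias_energy(c) for c in centers] for w in windows]
        w_ref, f_ref = wham_fixed_point(counts.tolist(), h.n_samples.tolist(), bias)
        w_ref = rezero_bulk(w_ref)
        assert np.max(np.abs(profile.w - np.asarray(w_ref))) < 1e-8
        assert fes.f == pytest.approx(f_ref, abs=1e-8)

    def test_invariant_under_window_order_shuffle(self, small_window_set, small_edges):
        series = list(small_window_set)
        windows = [ts.window for ts in series]
        p1, _ = solve_wham(build_histograms(series, small_edges), windows,
                           tol=1e-11)
        order = [3, 0, 6, 1, 7, 2, 5, 4]
        p2, _ = solve_wham(
            build_histograms([series[i] for i in order], small_edges),
            [windows[i] for i in order],
            tol=1e-11,
        )
        fm = p1.finite_mask
        assert np.max(np.abs(p1.w[fm] - p2.w[fm])) < 1e-6

    def test_invariant_under_uniform_shift(self, small_window_set, small_edges):
        """Shifting all centers and data by Δ shifts the profile rigidly."""
        delta = 7.3
        series = list(small_window_set)
        windows = [ts.window for ts in series]
        shifted_series = [
            _series(ts.production() + delta,
                    window=UmbrellaWindow(ts.window.center + delta, ts.window.spring))
            for ts in series
        ]
        p1, _ = solve_wham(build_histograms(series, small_edges), windows,
                           tol=1e-11)
        p2, _ = solve_wham(
            build_histograms(shifted_series, small_edges + delta),
            [ts.window for ts in shifted_series],
            tol=1e-11,
        )
        fm = p1.finite_mask
        assert np.allclose(p2.z[fm] - delta, p1.z[fm])
        assert np.max(np.abs(p1.w[fm] - p2.w[fm])) < 1e-6

    def test_residual_non_increasing_after_warmup(self, small_window_set, small_edges):
        """After an initial transient the fixed-point iteration contracts,
        so the residual decays monotonically to tolerance."""
        h = build_histograms(small_window_set, small_edges)
        _, fes = solve_wham(h, [ts.window for ts in small_window_set])
        hist = fes.residual_history[50:]
        assert hist.size > 100
        assert np.all(np.diff(hist) <= 1e-15)

    def test_nonconvergence_reports_residual(self, small_window_set, small_edges):
        h = build_histograms(small_window_set, small_edges)
        with pytest.raises(WhamConvergenceError, match="residual"):
            solve_wham(h, [ts.window for ts in small_window_set], max_iter=2)

    def test_window_count_mismatch(self, small_window_set, small_edges):
        h = build_histograms(small_window_set, small_edges)
        with pytest.raises(ValueError, match="windows"):
            solve_wham(h, [ts.window for ts in small_window_set[:-1]])


class TestRezero:
    def test_bulk_is_idempotent(self):
        p = PMFProfile(z=np.arange(4.0), w=np.array([-2.0, -5.0, np.inf, 0.0]),
                       convention="none")
        once = rezero_pmf(p, "bulk")
        twice = rezero_pmf(once, "bulk")
        assert np.array_equal(once.w, twice.w)
        assert once.w[3] == 0.0

    def test_constant_profile_zeroes_under_both_conventions(self):
        p = PMFProfile(z=np.arange(3.0), w=np.full(3, 4.2))
        for conv in ("bulk", "min"):
            assert np.allclose(rezero_pmf(p, conv).w, 0.0)

    def test_min_convention_puts_minimum_at_zero(self):
        p = PMFProfile(z=np.arange(4.0), w=np.array([1.0, -3.0, 2.0, np.inf]))
        out = rezero_pmf(p, "min")
        assert out.w[np.isfinite(out.w)].min() == 0.0

    def test_all_empty_profile_is_an_error(self):
        p = PMFProfile(z=np.arange(2.0), w=np.array([np.inf, np.inf]))
        with pytest.raises(ValueError):
            rezero_pmf(p, "bulk")
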