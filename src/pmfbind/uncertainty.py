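"""Decorrelation, bootstrap PMF uncertainty, and convergence diagnostics.

Three error-control procedures around the WHAM estimate:

* **Decorrelation** — the autocorrelation function of successive saved
  coordinates, and the first lag τ_e at which it falls to 1/e.  Samples
  spaced by τ_e save intervals are treated as effectively independent,
  which is the condition for unbiased resampling error estimates.
* **Bootstrap** — pseudo-datasets drawn with replacement (duplication
  allowed) independently within each window from the decorrelated samples;
  a PMF is rebuilt per pseudo-dataset, the pointwise standard deviation
  σ(z) is taken across them, and its maximum σ_max is reported as the
  single-number uncertainty of the profile.
* **Convergence** — the PMF depth recomputed on growing data fractions; a
  converged simulation shows no systematic drift of the depth with the
  amount of data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .potentials import UmbrellaWindow
from .simulate import TimeSeries
from .wham import HistogramSet, PMFProfile, build_histograms, solve_wham

__all__ = [
    "DecorrelationReport",
    "BootstrapResult",
    "ConvergenceReport",
    "autocorrelation",
    "tau_from_acf",
    "decorrelation_stride",
    "bootstrap_pmf",
    "convergence_depths",
]

logger = logging.getLogger(__name__)

ACF_THRESHOLD = 1.0 / math.e


@dataclass
class DecorrelationReport:
    """ACF by lag and the 1/e decorrelation lag τ_e (in save intervals)."""

    acf: np.ndarray  # acf[l] = rho(l), acf[0] = 1
    tau_e: int  # smallest lag with rho(lag) <= 1/e (inclusive)
    n_samples: int


@dataclass
class BootstrapResult:
    """Bootstrap spread of the PMF across resampled pseudo-datasets."""

    n_boot: int
    profiles: list[PMFProfile]  # per-replicate, bulk-anchored on a common bin
    sigma: np.ndarray  # pointwise SD σ(z), kT; NaN where < 2 finite replicates
    sigma_max: float  # max over finite bins, kT
    seed: int
    stride: int  # decorrelation stride actually used


@dataclass
class ConvergenceReport:
    """PMF depth as a function of the data fraction used."""

    fractions: np.ndarray
    depths: np.ndarray  # kT, depth = min W − bulk W per fraction
    drift: float  # max pairwise |depth difference|, kT


# -- decorrelation ----------------------------------------------------------

def tau_from_acf(rho: np.ndarray) -> int:
    """First lag l ≥ 1 with ρ(l) ≤ 1/e, inclusive at the threshold.

    The inclusive comparison is the documented tie-break: an ACF exactly at
    1/e already counts as decorrelated at that lag.
    """
    rho = np.asarray(rho, dtype=float)
    below = np.nonzero(rho[1:] <= ACF_THRESHOLD)[0]
    if below.size == 0:
        raise ValueError("ACF never falls to 1/e within the given lags")
    return int(below[0] + 1)


def autocorrelation(ts: TimeSeries, max_lag: int) -> DecorrelationReport:
    """Biased-estimator ACF ρ(l) of the production samples, l = 0..max_lag.

    τ_e is the smallest lag (≥ 1) at which ρ(l) ≤ 1/e, the threshold used
    to declare successive saved points effectively independent.  The
    inclusive comparison means a series with ρ(1) exactly 1/e has τ_e = 1.
    """
    x = ts.production()
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if x.size <= max_lag:
        raise ValueError(f"series length {x.size} must exceed max_lag {max_lag}")
    if np.var(x) == 0:
        raise ValueError("zero-variance series: autocorrelation undefined")

    rho = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    try:
        tau = tau_from_acf(rho)
    except ValueError:
        raise ValueError(
            f"ACF stays above 1/e for all lags up to {max_lag}; "
            "increase max_lag or the saving stride"
        ) from None
    return DecorrelationReport(acf=rho, tau_e=tau, n_samples=x.size)


def decorrelation_stride(ts: TimeSeries, max_lag: Optional[int] = None) -> int:
    """τ_e as an integer subsampling stride for one window's samples."""
    n = ts.production().size
    if max_lag is None:
        max_lag = max(1, min(1000, n // 2))
    return autocorrelation(ts, max_lag).tau_e


# -- bootstrap --------------------------------------------------------------

def bootstrap_pmf(series: Sequence[TimeSeries], windows: Sequence[UmbrellaWindow],
                  edges: np.ndarray, temperature: float = 298.15,
                  n_boot: int = 10, seed: int = 0,
                  stride: Optional[int] = None,
                  tol: float = 1e-7, max_iter: int = 100_000) -> BootstrapResult:
    """Bootstrap the PMF: resample decorrelated samples with duplication.

    Each of the ``n_boot`` pseudo-datasets redraws, independently within
    each window, N_i samples with replacement from that window's
    decorrelated (strided) production samples, then rebuilds the PMF by
    WHAM.  ``stride`` defaults to the maximum τ_e over windows so that the
    resampling unit is an effectively independent point — resampling raw
    correlated points would understate the variance.

    Replicate profiles are re-anchored to zero at the largest-z bin finite
    in *every* replicate before the pointwise SD (n−1 denominator) is
    taken; σ_max is the maximum SD over those common bins.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if stride is None:
        stride = max(decorrelation_stride(ts) for ts in series)

    retained = [ts.production()[::stride] for ts in series]
    for ts, x in zip(series, retained):
        if x.size < 10:
            raise ValueError(
                f"{ts.label or 'window'}: only {x.size} decorrelated samples "
                f"(stride {stride}); need >= 10 to bootstrap"
            )

    rng = np.random.default_rng(seed)
    interval = series[0].save_interval_ps
    profiles: list[PMFProfile] = []
    for r in range(n_boot):
        resampled = []
        for ts, x in zip(series, retained):
            draw = x[rng.integers(0, x.size, size=x.size)]
            resampled.append(TimeSeries(values=draw, save_interval_ps=interval,
                                        window=ts.window, label=ts.label))
        h = build_histograms(resampled, edges, stride=1)
        try:
            profile, _ = solve_wham(h, windows, temperature, tol=tol,
                                    max_iter=max_iter, convention="bulk")
        except Exception as exc:
            raise RuntimeError(f"bootstrap replicate {r} failed WHAM: {exc}") from exc
        profiles.append(profile)

    w_stack = np.vstack([p.w for p in profiles])  # (n_boot, n_bins)
    common = np.all(np.isfinite(w_stack), axis=0)
    if not common.any():
        raise RuntimeError("no bin is finite across all bootstrap replicates")
    anchor = np.nonzero(common)[0][-1]  # largest-z commonly finite bin
    w_stack = w_stack - w_stack[:, [anchor]]
    for p, row in zip(profiles, w_stack):
        p.w = np.where(np.isfinite(p.w), row, np.inf)

    finite_counts = np.isfinite(w_stack).sum(axis=0)
    sigma = np.full(w_stack.shape[1], np.nan)
    ok = finite_counts >= 2
    masked = np.where(np.isfinite(w_stack), w_stack, np.nan)
    sigma[ok] = np.nanstd(masked[:, ok], axis=0, ddof=1)
    sigma_max = float(np.nanmax(sigma[common])) if common.any() else float("nan")

    logger.info("bootstrap: n_boot=%d stride=%d sigma_max=%.3g kT",
                n_boot, stride, sigma_max)
    return BootstrapResult(n_boot=n_boot, profiles=profiles, sigma=sigma,
                           sigma_max=sigma_max, seed=seed, stride=stride)


# -- convergence ------------------------------------------------------------

def convergence_depths(series: Sequence[TimeSeries], fractions: Sequence[float],
                       windows: Sequence[UmbrellaWindow], edges: np.ndarray,
                       temperature: float = 298.15, stride: int = 1,
                       tol: float = 1e-7, max_iter: int = 100_000) -> ConvergenceReport:
    """PMF depth from the first ⌈φ·N_i⌉ retained samples, per fraction φ.

    Depth is min_j W_j minus W at the bulk (largest finite-z) bin.  The
    drift — the maximum pairwise depth difference across fractions — is the
    convergence diagnostic: for stationary, converged sampling it should be
    within a few bootstrap σ_max of zero.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0 or np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")
    if not np.all(np.diff(fractions) > 0) and fractions.size > 1:
        raise ValueError("fractions must be strictly increasing")
    if fractions[-1] != 1.0:
        raise ValueError("last fraction must be 1.0 (full data)")

    retained = [ts.production()[::stride] for ts in series]
    interval = series[0].save_interval_ps
    depths = []
    for phi in fractions:
        truncated = []
        for ts, x in zip(series, retained):
            n = math.ceil(phi * x.size)
            if n == 0:
                raise ValueError(f"{ts.label or 'window'}: empty at fraction {phi}")
            truncated.append(TimeSeries(values=x[:n], save_interval_ps=interval,
                                        window=ts.window, label=ts.label))
        h = build_histograms(truncated, edges, stride=1)
        profile, _ = solve_wham(h, windows, temperature, tol=tol,
                                max_iter=max_iter, convention="bulk")
        depths.append(profile.depth())

    depths = np.asarray(depths)
    drift = float(depths.max() - depths.min()) if depths.size > 1 else 0.0
    return ConvergenceReport(fractions=fractions, depths=depths, drift=drift)
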