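"""Weighted histogram analysis method (WHAM) for 1D umbrella sampling.

Combines per-window biased histograms into one unbiased probability
profile by the standard self-consistent iteration

    P_j = (Σ_i n_ij) / (Σ_i N_i exp[f_i − c_ij])
    exp(−f_i) = Σ_j P_j exp(−c_ij)

with all energies in kT (β = 1), c_ij the harmonic bias of window i at bin
center j, and the window free-energy constants anchored at f_0 = 0.  The
PMF is W_j = −ln P_j, re-zeroed by convention (bulk edge or minimum).

The iteration runs in linear space on precomputed exp(−c_ij) weights while
the constants stay in a safe range, falling back to a log-sum-exp path
otherwise; bins with zero total count carry a +∞ sentinel and are excluded
from downstream integration rather than smoothed over (smoothing would bias
the Kd integral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .potentials import UmbrellaWindow
from .simulate import TimeSeries

__all__ = [
    "WhamConvergenceError",
    "HistogramSet",
    "WindowFreeEnergies",
    "PMFProfile",
    "build_histograms",
    "solve_wham",
    "rezero_pmf",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.5  # Å
DEFAULT_TOL = 1e-7  # kT, on max|Δf_i|
DEFAULT_MAX_ITER = 100_000


class WhamConvergenceError(RuntimeError):
    """WHAM self-consistency failed to reach tolerance within max_iter."""


@dataclass
class HistogramSet:
    """Per-window histograms on a shared regular grid of bin edges."""

    edges: np.ndarray  # (n_bins + 1,), Å, strictly increasing
    counts: np.ndarray  # (n_windows, n_bins)
    n_samples: np.ndarray  # N_i retained per window
    n_dropped: np.ndarray  # out-of-range samples per window
    labels: list[str] = field(default_factory=list)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class WindowFreeEnergies:
    """Converged window constants f_i (kT), anchored at f_0 = 0."""

    f: np.ndarray
    iterations: int
    residual: float
    converged: bool
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class PMFProfile:
    """Binned PMF estimate W(z) in kT with an explicit zero convention.

    Bins never visited carry W = +inf and are skipped by integration and
    re-zeroing.  ``sigma`` holds optional pointwise bootstrap uncertainties.
    """

    z: np.ndarray  # bin centers, Å
    w: np.ndarray  # kT; +inf sentinel for empty bins
    sigma: Optional[np.ndarray] = None  # kT
    convention: str = "none"  # "bulk" | "min" | "none"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z.shape != self.w.shape:
            raise ValueError("z and w must have matching shapes")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.w.shape:
                raise ValueError("sigma must match w in shape")
            finite = np.isfinite(self.sigma)
            if np.any(self.sigma[finite] < 0):
                raise ValueError("sigma must be >= 0")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.w)

    def depth(self) -> float:
        """Well depth: min_j W_j minus W at the largest finite-z bin."""
        fm = self.finite_mask
        if not fm.any():
            raise ValueError("profile has no finite bins")
        w_fin = self.w[fm]
        return float(w_fin.min() - w_fin[-1])


def build_histograms(series: Sequence[TimeSeries], edges: np.ndarray,
                     stride: int = 1) -> HistogramSet:
    """Bin every stride-th production sample of each window.

    Half-open bins [lo, hi): a value exactly at the last edge is dropped.
    Samples outside the edge range are dropped and counted per window; a
    window with zero retained samples is an error (it would silently vanish
    from the WHAM equations).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be a strictly increasing 1D grid of >= 2 values")

    counts, n_samples, n_dropped, labels = [], [], [], []
    for i, ts in enumerate(series):
        x = ts.production()[::stride]
        label = ts.label or f"window {i}"
        if x.size == 0:
            raise ValueError(f"{label}: zero retained samples after stride {stride}")
        inside = (x >= edges[0]) & (x < edges[-1])
        kept = x[inside]
        if kept.size == 0:
            raise ValueError(
                f"{label}: all {x.size} samples fall outside "
                f"[{edges[0]:g}, {edges[-1]:g}) Å"
            )
        c, _ = np.histogram(kept, bins=edges)
        counts.append(c)
        n_samples.append(kept.size)
        n_dropped.append(x.size - kept.size)
        labels.append(label)

    return HistogramSet(
        edges=edges,
        counts=np.asarray(counts, dtype=float),
        n_samples=np.asarray(n_samples, dtype=float),
        n_dropped=np.asarray(n_dropped, dtype=int),
        labels=labels,
    )


def _bias_matrix(h: HistogramSet, windows: Sequence[UmbrellaWindow]) -> np.ndarray:
    """c_ij: bias energy (kT) of window i at bin center j."""
    centers = h.centers
    return np.vstack([w.bias_energy(centers) for w in windows])


def solve_wham(h: HistogramSet, windows: Sequence[UmbrellaWindow],
               temperature: float = 298.15, tol: float = DEFAULT_TOL,
               max_iter: int = DEFAULT_MAX_ITER,
               convention: str = "bulk") -> tuple[PMFProfile, WindowFreeEnergies]:
    """Self-consistent WHAM solve; returns (PMF, window free energies).

    ``temperature`` is bookkeeping (histogram energies are already in kT).
    Raises :class:`WhamConvergenceError` when max|Δf_i| is still above
    ``tol`` after ``max_iter`` sweeps.
    """
    if len(windows) != h.n_windows:
        raise ValueError(f"{len(windows)} windows vs {h.n_windows} histogram rows")
    total = h.counts.sum(axis=0)
    if not np.any(total > 0):
        raise ValueError("all histogram bins are empty")

    c = _bias_matrix(h, windows)  # (n_win, n_bins)
    N = h.n_samples
    occupied = total > 0

    log_num = np.where(occupied, np.log(np.where(occupied, total, 1.0)), -np.inf)
    # linear-space fast path: exp(-c) underflows harmlessly to 0
    with np.errstate(under="ignore"):
        exp_neg_c = np.exp(-c)

    f = np.zeros(len(windows))
    residuals = []
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        fast = np.max(np.abs(f)) < 500.0
        if fast:
            with np.errstate(under="ignore", divide="ignore"):
                denom = (N * np.exp(f)) @ exp_neg_c  # (n_bins,)
                log_p = log_num - np.log(denom)
                log_p[~occupied] = -np.inf
                fast = bool(np.all(np.isfinite(log_p[occupied])))
                if fast:
                    shift = log_p.max()
                    f_new = -(np.log(np.exp(log_p - shift) @ exp_neg_c.T) + shift)
        if not fast:  # log-sum-exp fallback for extreme constants
            denom = logsumexp(np.log(N)[:, None] + f[:, None] - c, axis=0)
            log_p = log_num - denom
            log_p[~occupied] = -np.inf
            f_new = -logsumexp(log_p[None, :] - c, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        residuals.append(residual)
        f = f_new
        if residual <= tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(final residual {residual:.3g} kT > tol {tol:g} kT)"
        )

    with np.errstate(divide="ignore"):
        w = np.where(occupied, -log_p, np.inf)
    profile = PMFProfile(z=h.centers, w=w, convention="none")
    profile = rezero_pmf(profile, convention)
    fes = WindowFreeEnergies(
        f=f, iterations=it, residual=residual, converged=True,
        residual_history=np.asarray(residuals),
    )
    logger.debug("WHAM converged in %d iterations (residual %.3g kT)", it, residual)
    return profile, fes


def rezero_pmf(p: PMFProfile, convention: str = "bulk") -> PMFProfile:
    """Anchor the PMF zero: ``bulk`` at the largest finite-z bin, ``min`` at
    the profile minimum.  Idempotent; empty (+inf) bins are untouched."""
    fm = p.finite_mask
    if not fm.any():
        raise ValueError("cannot re-zero a profile with no finite bins")
    if convention == "bulk":
        anchor = p.w[fm][-1]
    elif convention == "min":
        anchor = p.w[fm].min()
    else:
        raise ValueError(f"unknown zero convention {convention!r}")
    w = np.where(fm, p.w - anchor, np.inf)
    return PMFProfile(z=p.z.copy(), w=w,
                      sigma=None if p.sigma is None else p.sigma.copy(),
                      convention=convention)
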