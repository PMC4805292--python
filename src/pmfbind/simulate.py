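"""Synthetic umbrella-sampling data from overdamped Langevin dynamics.

Generates correlated 1D reaction-coordinate timeseries with a *known*
ground-truth free-energy profile, emulating what biased MD writes out: the
coordinate saved at a fixed stride, with a tunable correlation time set by
the diffusion coefficient and the local stiffness.  The integrator is
Euler–Maruyama on the overdamped Langevin equation

    z ← z + (D·dt) F(z)/kT + sqrt(2 D dt) ξ,   ξ ~ N(0, 1),

whose stationary distribution converges to the Boltzmann distribution of
the combined potential (truth + bias) in the small-dt limit.  Forces are
evaluated by linear interpolation on a fine precomputed grid (central
differences of W for tabulated inputs, analytic derivatives sampled on the
grid otherwise), and the hot loop is JIT-compiled; the random stream comes
from a numpy Generator, so runs are bitwise reproducible given the seed.

Trajectories reflect at the domain edges, which preserves the Boltzmann
distribution (zero-flux boundaries).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .potentials import (
    FlatBottomRestraint,
    Potential1D,
    UmbrellaWindow,
)

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "TimeSeries",
    "simulate_window",
    "generate_window_set",
    "simulate_pull",
]

logger = logging.getLogger(__name__)

# Fraction of saved samples flagged as equilibration and excluded from
# production analysis by default (configurable per TimeSeries downstream).
BURN_IN_FRACTION = 0.1

# Stability bound on dt·D·k_max (dimensionless with k in kT/Å², D in Å²/ps,
# dt in ps).  Beyond this the Euler–Maruyama chain is badly biased or divergent.
STABILITY_LIMIT = 0.1

_FORCE_GRID_POINTS = 4001
_CHUNK_STEPS = 1 << 20


class ConfigurationError(ValueError):
    """Simulation configuration violates the integrator stability bound."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one overdamped Langevin run.

    D is the diffusion coefficient along the coordinate (Å²/ps; 0.1 is a
    typical small-solute value in water), dt the integration timestep (ps),
    and s_save the saving stride in steps — the default 500-step stride at
    dt = 0.002 ps mirrors coordinates saved every 1 ps.
    """

    seed: int
    diffusion: float = 0.1  # D, Å²/ps
    dt: float = 0.002  # ps
    n_steps: int = 500_000
    s_save: int = 500  # steps between saved samples
    temperature: float = 298.15  # K; bookkeeping only (energies are in kT)
    z_init: Optional[float] = None  # default: window center, else domain midpoint

    def __post_init__(self):
        if self.diffusion <= 0:
            raise ValueError("diffusion coefficient must be > 0")
        if self.dt <= 0:
            raise ValueError("timestep must be > 0")
        if not (self.n_steps >= self.s_save >= 1):
            raise ValueError("need n_steps >= s_save >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is required and must be an integer")

    @property
    def save_interval_ps(self) -> float:
        return self.dt * self.s_save


@dataclass
class TimeSeries:
    """Saved reaction-coordinate samples from one window (or unbiased run).

    ``n_equil`` leading samples are flagged as equilibration;
    :meth:`production` returns the rest, which is what every downstream
    estimator consumes.  File-loaded series carry ``seed=None`` and
    ``n_equil=0`` (user data is assumed to be production).
    """

    values: np.ndarray
    save_interval_ps: float
    window: Optional[UmbrellaWindow] = None  # None means unbiased
    seed: Optional[int] = None
    n_equil: int = 0
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("timeseries needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries samples must all be finite")
        if not 0 <= self.n_equil < self.values.size:
            raise ValueError("n_equil must leave at least one production sample")

    def __len__(self) -> int:
        return self.values.size

    def production(self) -> np.ndarray:
        """Samples after the equilibration segment."""
        return self.values[self.n_equil:]


# -- JIT kernels ------------------------------------------------------------

@njit(cache=False)
def _run_chunk(z, noise, drift, amp, f_grid, z_lo, inv_dz, n_grid,
               k_bias, z0_bias, zmin, zmax, s_save, phase, out, n_out):
    """Advance one noise chunk; save every s_save-th state into out."""
    m = n_out
    for i in range(noise.size):
        x = (z - z_lo) * inv_dz
        j = int(x)
        if j < 0:
            j = 0
        elif j > n_grid - 2:
            j = n_grid - 2
        frac = x - j
        f = f_grid[j] + frac * (f_grid[j + 1] - f_grid[j])
        f -= k_bias * (z - z0_bias)
        z = z + drift * f + amp * noise[i]
        if z < zmin:
            z = 2.0 * zmin - z
        elif z > zmax:
            z = 2.0 * zmax - z
        phase += 1
        if phase == s_save:
            out[m] = z
            m += 1
            phase = 0
    return z, phase, m


@njit(cache=False)
def _run_pull_chunk(z, noise, drift, amp, f_grid, z_lo, inv_dz, n_grid,
                    k_fb, b_start, b_end, t_ramp, dt, step0,
                    zmin, zmax, s_save, phase, out, n_out):
    """Pull-chunk: flat-bottom restraint with a linearly shrinking bound."""
    m = n_out
    for i in range(noise.size):
        x = (z - z_lo) * inv_dz
        j = int(x)
        if j < 0:
            j = 0
        elif j > n_grid - 2:
            j = n_grid - 2
        frac = x - j
        f = f_grid[j] + frac * (f_grid[j + 1] - f_grid[j])
        t = (step0 + i) * dt
        if t >= t_ramp:
            b = b_end
        else:
            b = b_start + (b_end - b_start) * (t / t_ramp)
        if z > b:
            f -= k_fb * (z - b)
        z = z + drift * f + amp * noise[i]
        if z < zmin:
            z = 2.0 * zmin - z
        elif z > zmax:
            z = 2.0 * zmax - z
        phase += 1
        if phase == s_save:
            out[m] = z
            m += 1
            phase = 0
    return z, phase, m


# -- internals --------------------------------------------------------------

def _force_grid(truth: Potential1D):
    grid = np.linspace(truth.z_lo, truth.z_hi, _FORCE_GRID_POINTS)
    f = np.asarray(truth.force(grid), dtype=float)
    inv_dz = (_FORCE_GRID_POINTS - 1) / (truth.z_hi - truth.z_lo)
    return grid, f, inv_dz


def _check_stability(truth: Potential1D, k_extra: float, cfg: SimConfig) -> None:
    k_max = truth.max_curvature() + k_extra
    s = cfg.dt * cfg.diffusion * k_max
    if s >= STABILITY_LIMIT:
        raise ConfigurationError(
            f"dt*D*k_max = {s:.3g} >= {STABILITY_LIMIT} (k_max = {k_max:.3g} kT/Å²); "
            "reduce dt or the stiffest force constant"
        )


def _drive(kernel_args_builder, cfg: SimConfig, z0: float, rng: np.random.Generator):
    """Common chunked driver for both kernels."""
    n_saved = cfg.n_steps // cfg.s_save
    out = np.empty(n_saved, dtype=float)
    z = float(z0)
    phase = 0
    n_out = 0
    step0 = 0
    remaining = cfg.n_steps
    while remaining > 0:
        n = min(_CHUNK_STEPS, remaining)
        noise = rng.standard_normal(n)
        z, phase, n_out = kernel_args_builder(z, noise, phase, out, n_out, step0)
        step0 += n
        remaining -= n
    return out[:n_out]


def _finish(values: np.ndarray, cfg: SimConfig, window, seed, label) -> TimeSeries:
    n_equil = int(BURN_IN_FRACTION * values.size)
    if n_equil >= values.size:
        n_equil = values.size - 1
    return TimeSeries(
        values=values,
        save_interval_ps=cfg.save_interval_ps,
        window=window,
        seed=seed,
        n_equil=n_equil,
        label=label,
    )


# -- public operations ------------------------------------------------------

def simulate_window(truth: Potential1D, window: Optional[UmbrellaWindow],
                    cfg: SimConfig) -> TimeSeries:
    """Sample one (possibly biased) window of the ground-truth potential.

    ``window=None`` runs unbiased dynamics on ``truth`` alone.  The
    configuration must satisfy the stability invariant for the combined
    stiffness (truth curvature plus bias spring); violation raises
    :class:`ConfigurationError` before any stepping.
    """
    k_bias = window.spring if window is not None else 0.0
    z0_bias = window.center if window is not None else 0.0
    _check_stability(truth, k_bias, cfg)

    _, f_grid, inv_dz = _force_grid(truth)
    drift = cfg.diffusion * cfg.dt
    amp = math.sqrt(2.0 * cfg.diffusion * cfg.dt)
    z_init = cfg.z_init
    if z_init is None:
        z_init = window.center if window is not None else 0.5 * (truth.z_lo + truth.z_hi)
    if not (truth.z_lo <= z_init <= truth.z_hi):
        raise ConfigurationError(f"z_init={z_init:g} outside truth domain")

    rng = np.random.default_rng(cfg.seed)

    def run(z, noise, phase, out, n_out, step0):
        return _run_chunk(z, noise, drift, amp, f_grid, truth.z_lo, inv_dz,
                          _FORCE_GRID_POINTS, k_bias, z0_bias,
                          truth.z_lo, truth.z_hi, cfg.s_save, phase, out, n_out)

    values = _drive(run, cfg, z_init, rng)
    label = window.label if window is not None and window.label else "unbiased"
    return _finish(values, cfg, window, cfg.seed, label)


def generate_window_set(truth: Potential1D, z_first: float, z_last: float,
                        spacing: float, k_s: float, cfg: SimConfig,
                        overlap_warn_threshold: float = 0.05) -> list[TimeSeries]:
    """Simulate a regular grid of umbrella windows over [z_first, z_last].

    Window i is centered at z_first + i·spacing and simulated with seed
    ``cfg.seed + i`` (documented derivation: reproducible yet mutually
    independent streams).  Warns when the shared-bin histogram overlap of
    adjacent windows falls below ``overlap_warn_threshold`` — poor overlap
    starves WHAM of the information tying neighbouring windows together.
    """
    if spacing <= 0:
        raise ValueError("window spacing must be > 0")
    if z_first >= z_last:
        raise ValueError("need z_first < z_last")
    n_win = int(round((z_last - z_first) / spacing)) + 1
    centers = z_first + spacing * np.arange(n_win)

    series = []
    for i, c in enumerate(centers):
        w = UmbrellaWindow(center=float(c), spring=k_s, label=f"win{i:03d}")
        cfg_i = SimConfig(seed=cfg.seed + i, diffusion=cfg.diffusion, dt=cfg.dt,
                          n_steps=cfg.n_steps, s_save=cfg.s_save,
                          temperature=cfg.temperature, z_init=float(c))
        series.append(simulate_window(truth, w, cfg_i))

    _warn_poor_overlap(series, overlap_warn_threshold)
    return series


def _warn_poor_overlap(series: list[TimeSeries], threshold: float) -> None:
    """Histogram-overlap diagnostic between adjacent windows."""
    for a, b in zip(series, series[1:]):
        xa, xb = a.production(), b.production()
        lo = min(xa.min(), xb.min())
        hi = max(xa.max(), xb.max())
        if hi <= lo:
            continue
        edges = np.linspace(lo, hi, 51)
        ha, _ = np.histogram(xa, bins=edges)
        hb, _ = np.histogram(xb, bins=edges)
        shared = np.minimum(ha / xa.size, hb / xb.size).sum()
        if shared < threshold:
            warnings.warn(
                f"adjacent windows {a.label!r}/{b.label!r} overlap only "
                f"{shared:.1%} (< {threshold:.0%}); WHAM may not connect them",
                stacklevel=3,
            )


def simulate_pull(truth: Potential1D, restraint: FlatBottomRestraint,
                  cfg: SimConfig) -> TimeSeries:
    """Docking-style pull: dynamics under a shrinking flat-bottom restraint.

    The restraint's schedule (b_start → b_end over t_ramp) is required; the
    trajectory is free inside the instantaneous bound and harmonically
    confined beyond it, so after the ramp the coordinate is effectively held
    below b_end.
    """
    if restraint.schedule is None:
        raise ValueError("simulate_pull requires a restraint with a schedule")
    b_start, b_end, t_ramp = restraint.schedule
    _check_stability(truth, restraint.stiffness, cfg)

    _, f_grid, inv_dz = _force_grid(truth)
    drift = cfg.diffusion * cfg.dt
    amp = math.sqrt(2.0 * cfg.diffusion * cfg.dt)
    z_init = cfg.z_init
    if z_init is None:
        z_init = min(b_start, truth.z_hi)
    if not (truth.z_lo <= z_init <= truth.z_hi):
        raise ConfigurationError(f"z_init={z_init:g} outside truth domain")

    rng = np.random.default_rng(cfg.seed)

    def run(z, noise, phase, out, n_out, step0):
        return _run_pull_chunk(z, noise, drift, amp, f_grid, truth.z_lo, inv_dz,
                               _FORCE_GRID_POINTS, restraint.stiffness,
                               b_start, b_end, t_ramp, cfg.dt, step0,
                               truth.z_lo, truth.z_hi, cfg.s_save, phase, out, n_out)

    values = _drive(run, cfg, z_init, rng)
    ts = _finish(values, cfg, None, cfg.seed, "pull")
    # a pull trajectory is transient by construction: keep all samples
    ts.n_equil = 0
    return ts
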