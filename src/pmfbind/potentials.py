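"""One-dimensional free-energy curves and bias/restraint energies.

A :class:`Potential1D` plays two roles in this package: as a *ground-truth*
free-energy profile W(z) driving the synthetic Langevin sampler, and as the
parametric/tabulated representation of a reconstructed PMF.  All energies are
carried in units of kT at a single configured temperature; conversion to
kcal/mol happens only at the I/O boundary (see :mod:`pmfbind.io`).  Lengths
are in Å throughout.

Harmonic umbrella biases follow the half-k convention E = ½ k (z − z0)²,
the dominant dialect among umbrella-sampling tools.  Metadata files declare
their dialect explicitly so full-k inputs can be converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "Potential1D",
    "FlatPotential",
    "SquareWell",
    "HarmonicPotential",
    "DoubleWell",
    "TabulatedPotential",
    "UmbrellaWindow",
    "FlatBottomRestraint",
    "evaluate_potential",
    "harmonic_bias_energy",
    "flat_bottom_energy",
    "potential_from_dict",
]


class DomainError(ValueError):
    """Raised when a coordinate falls outside a potential's domain.

    Out-of-domain evaluation is an error, never a clamp: silently clamping
    W(z) would corrupt Boltzmann weights downstream.
    """


class Potential1D:
    """Abstract 1D free-energy curve W(z) on an explicit domain [z_lo, z_hi]."""

    kind: str = "abstract"
    z_lo: float
    z_hi: float

    # -- public API ---------------------------------------------------------
    def energy(self, z):
        """W(z) in kT.  Accepts scalars or arrays; errors outside the domain."""
        z = np.asanyarray(z, dtype=float)
        self._check_domain(z)
        out = self._energy(z)
        return float(out) if np.isscalar(z) or z.ndim == 0 else out

    def force(self, z):
        """-dW/dz in kT/Å.  Accepts scalars or arrays; errors outside the domain."""
        z = np.asanyarray(z, dtype=float)
        self._check_domain(z)
        out = self._force(z)
        return float(out) if np.isscalar(z) or z.ndim == 0 else out

    def to_tabulated(self, n: int = 1001) -> "TabulatedPotential":
        """Sample this potential on a regular n-point grid over its domain."""
        grid = np.linspace(self.z_lo, self.z_hi, n)
        return TabulatedPotential(grid, self._energy(grid))

    def max_curvature(self, n: int = 4001) -> float:
        """Numerical estimate of max |W''(z)| in kT/Å², for stability checks."""
        grid = np.linspace(self.z_lo, self.z_hi, n)
        w = self._energy(grid)
        dz = grid[1] - grid[0]
        curv = np.abs(np.diff(w, 2)) / dz**2
        return float(curv.max()) if curv.size else 0.0

    # -- hooks for subclasses ----------------------------------------------
    def _energy(self, z: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _force(self, z: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _check_domain(self, z: np.ndarray) -> None:
        if np.any(z < self.z_lo) or np.any(z > self.z_hi):
            bad = np.asarray(z)[(np.asarray(z) < self.z_lo) | (np.asarray(z) > self.z_hi)]
            first = float(np.atleast_1d(bad)[0])
            raise DomainError(
                f"z={first:g} Å outside domain [{self.z_lo:g}, {self.z_hi:g}] Å "
                f"of {self.kind} potential"
            )


@dataclass
class FlatPotential(Potential1D):
    """Constant W(z) = offset; the free-diffusion / null-truth case."""

    z_lo: float = -100.0
    z_hi: float = 100.0
    offset: float = 0.0
    kind: str = field(default="flat", init=False)

    def _energy(self, z):
        return np.full_like(z, self.offset, dtype=float)

    def _force(self, z):
        return np.zeros_like(z, dtype=float)


@dataclass
class SquareWell(Potential1D):
    """Square well: W = depth inside |z − center| ≤ width/2, else 0.

    depth is the energy *value* in the well (negative for an attractive
    well).  The profile is discontinuous, so it has no meaningful force;
    square wells are intended for closed-form Kd work, not for simulation.
    """

    depth: float = -10.0
    width: float = 2.0
    center: float = 0.0
    z_lo: float = -10.0
    z_hi: float = 10.0
    kind: str = field(default="square_well", init=False)

    def _energy(self, z):
        inside = np.abs(z - self.center) <= self.width / 2.0
        return np.where(inside, self.depth, 0.0)

    def _force(self, z):
        raise ValueError("square-well potential is discontinuous; no force defined")


@dataclass
class HarmonicPotential(Potential1D):
    """W(z) = ½ stiffness (z − center)², stiffness in kT/Å²."""

    stiffness: float = 1.0
    center: float = 0.0
    z_lo: float = -50.0
    z_hi: float = 50.0
    kind: str = field(default="harmonic", init=False)

    def __post_init__(self):
        if self.stiffness < 0:
            raise ValueError("harmonic stiffness must be >= 0")

    def _energy(self, z):
        return 0.5 * self.stiffness * (z - self.center) ** 2

    def _force(self, z):
        return -self.stiffness * (z - self.center)


@dataclass
class DoubleWell(Potential1D):
    """Smooth double well built from Gaussian components.

    W(z) = −depth1·g(z; center1, width) − depth2·g(z; center2, width)
           + barrier·g(z; midpoint, width/2)

    with g a unit-amplitude Gaussian of the given σ (``width``).  The form
    decays to zero away from the wells, which is what a binding PMF does in
    bulk, and has an analytic force everywhere.  ``depth1``/``depth2`` are
    positive well depths in kT; ``barrier`` is a positive hump height in kT
    placed midway between the wells.
    """

    depth1: float = 8.0
    center1: float = 2.0
    depth2: float = 4.0
    center2: float = 6.0
    width: float = 1.0
    barrier: float = 0.0
    z_lo: float = -2.0
    z_hi: float = 12.0
    kind: str = field(default="double_well", init=False)

    def _components(self):
        mid = 0.5 * (self.center1 + self.center2)
        return (
            (-self.depth1, self.center1, self.width),
            (-self.depth2, self.center2, self.width),
            (self.barrier, mid, self.width / 2.0),
        )

    def _energy(self, z):
        w = np.zeros_like(z, dtype=float)
        for amp, c, s in self._components():
            if amp != 0.0:
                w += amp * np.exp(-0.5 * ((z - c) / s) ** 2)
        return w

    def _force(self, z):
        f = np.zeros_like(z, dtype=float)
        for amp, c, s in self._components():
            if amp != 0.0:
                f += amp * np.exp(-0.5 * ((z - c) / s) ** 2) * (z - c) / s**2
        return f


class TabulatedPotential(Potential1D):
    """W(z) given on a strictly increasing grid; linear interpolation between
    points, central-difference forces on the grid."""

    kind = "tabulated"

    def __init__(self, z: Sequence[float], w: Sequence[float]):
        z = np.asarray(z, dtype=float)
        w = np.asarray(w, dtype=float)
        if z.ndim != 1 or z.size < 2 or z.shape != w.shape:
            raise ValueError("tabulated potential needs matching 1D z and W arrays, >= 2 points")
        if not np.all(np.diff(z) > 0):
            raise ValueError("tabulated grid must be strictly increasing in z")
        if not np.all(np.isfinite(w)):
            raise ValueError("tabulated W values must all be finite")
        self.grid_z = z
        self.grid_w = w
        self.z_lo = float(z[0])
        self.z_hi = float(z[-1])
        # central differences interior, one-sided at the ends
        self.grid_f = -np.gradient(w, z)

    def _energy(self, z):
        return np.interp(z, self.grid_z, self.grid_w)

    def _force(self, z):
        return np.interp(z, self.grid_z, self.grid_f)


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic umbrella window: E_bias(z) = ½ k_s (z − z0)²."""

    center: float  # z0, Å
    spring: float  # k_s, kT/Å²
    label: str = ""

    def __post_init__(self):
        if self.spring <= 0:
            raise ValueError(f"umbrella spring constant must be > 0, got {self.spring}")

    def bias_energy(self, z):
        z = np.asanyarray(z, dtype=float)
        return 0.5 * self.spring * (z - self.center) ** 2

    def bias_force(self, z):
        z = np.asanyarray(z, dtype=float)
        return -self.spring * (z - self.center)


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Flat-bottom distance restraint: zero inside the bound, harmonic beyond.

    E(d, t) = 0 for d ≤ b(t), else ½ k_fb (d − b(t))².  If a schedule
    (b_start, b_end, t_ramp) is present the bound b(t) shrinks linearly from
    b_start to b_end over t_ramp and stays at b_end afterwards — the pulling
    protocol used to dock a blocker into a channel filter without biasing the
    final bound geometry.
    """

    bound: float  # b, Å (static bound, or b_end once a schedule finishes)
    stiffness: float = 10.0  # k_fb, kT/Å²
    schedule: Optional[tuple[float, float, float]] = None  # (b_start, b_end, t_ramp)

    def __post_init__(self):
        if self.bound < 0:
            raise ValueError("flat-bottom bound must be >= 0")
        if self.stiffness <= 0:
            raise ValueError("flat-bottom stiffness must be > 0")
        if self.schedule is not None:
            b_start, b_end, t_ramp = self.schedule
            if not (b_start >= b_end >= 0):
                raise ValueError("schedule must decrease monotonically: b_start >= b_end >= 0")
            if t_ramp <= 0:
                raise ValueError("schedule t_ramp must be > 0")

    def bound_at(self, t: float) -> float:
        """b(t): linear ramp b_start → b_end over t_ramp, constant after."""
        if self.schedule is None:
            return self.bound
        b_start, b_end, t_ramp = self.schedule
        if t >= t_ramp:
            return b_end
        return b_start + (b_end - b_start) * (t / t_ramp)

    def energy(self, d, t: float = 0.0):
        d = np.asanyarray(d, dtype=float)
        b = self.bound_at(t)
        excess = np.maximum(d - b, 0.0)
        return 0.5 * self.stiffness * excess**2

    def force(self, d, t: float = 0.0):
        d = np.asanyarray(d, dtype=float)
        b = self.bound_at(t)
        excess = np.maximum(d - b, 0.0)
        return -self.stiffness * excess


# -- functional wrappers ----------------------------------------------------

def evaluate_potential(p: Potential1D, z) -> float:
    """W(z) in kT; DomainError outside [z_lo, z_hi]."""
    return p.energy(z)


def harmonic_bias_energy(w: UmbrellaWindow, z) -> float:
    """½ k_s (z − z0)² in kT."""
    out = w.bias_energy(z)
    return float(out) if out.ndim == 0 else out


def flat_bottom_energy(r: FlatBottomRestraint, d, t: float = 0.0) -> float:
    """Flat-bottom restraint energy in kT at distance d and time t."""
    out = r.energy(d, t)
    return float(out) if out.ndim == 0 else out


# -- config-dict factory ----------------------------------------------------

_KINDS = {
    "flat": FlatPotential,
    "square_well": SquareWell,
    "harmonic": HarmonicPotential,
    "double_well": DoubleWell,
}


def potential_from_dict(spec: dict) -> Potential1D:
    """Build a potential from a configuration mapping.

    ``{"kind": "double_well", "depth1": 8, ...}``; the ``tabulated`` kind
    takes ``z`` and ``w`` lists (or is loaded from file by the CLI layer).
    """
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "tabulated":
        return TabulatedPotential(spec["z"], spec["w"])
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown potential kind {kind!r}; expected one of "
                         f"{sorted(_KINDS) + ['tabulated']}") from None
    return cls(**spec)
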