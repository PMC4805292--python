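"""Dissociation constants from a 1D PMF with a cylindrical sampling volume.

When the ligand's center of mass is confined to a cylinder of radius R
during umbrella sampling, the association constant follows from the PMF
W(z) alone:

    Kd⁻¹ = 1000 · π R² · N_A · ∫_{z_min}^{z_max} exp[−W(z)/kT] dz

(SI lengths).  Internally lengths stay in Å, so the same quantity is
computed as Kd⁻¹ [L/mol] = π R² I [Å³] · 10⁻²⁷ [L/Å³] · N_A with
I = ∫ exp(−W/kT) dz in Å — algebraically identical to the SI form, a fact
asserted by a unit test rather than trusted.  z_min and z_max bracket the
bound state and the bulk, and W must be anchored to zero in bulk for the
integral to mean what Eq. requires.

Also provides the single-site fractional block C/(C + Kd), the relation
that links Kd to the concentration inhibiting a given fraction of the
current through the channel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.constants import Avogadro

from .wham import PMFProfile

__all__ = ["BindingResult", "compute_kd", "kd_bounds", "fraction_blocked"]

_L_PER_CUBIC_ANGSTROM = 1e-27


@dataclass
class BindingResult:
    """Kd plus the geometry and temperature that produced it."""

    kd: float  # mol/L; +inf when the integral vanishes
    ka: float  # Kd⁻¹, L/mol
    integral: float  # I = ∫ exp(−W/kT) dz, Å
    radius: float  # cylinder radius R, Å
    z_min: float
    z_max: float
    temperature: float  # K

    @property
    def kd_micromolar(self) -> float:
        return self.kd * 1e6


def compute_kd(profile: PMFProfile, radius: float, temperature: float = 298.15,
               z_min: Optional[float] = None,
               z_max: Optional[float] = None) -> BindingResult:
    """Integrate exp(−W) over [z_min, z_max] and convert to Kd.

    The trapezoidal rule runs over the profile's finite bins inside the
    range; empty (+inf) bins are excluded with a warning since they carry
    zero Boltzmann weight by construction, not by measurement.  z_min/z_max
    default to the finite extremes of the profile (bound-side edge and bulk
    edge).  An empty range gives I = 0 and Kd = +inf (no binding).
    """
    if radius <= 0:
        raise ValueError("cylinder radius must be > 0")
    if profile.convention != "bulk":
        raise ValueError(
            "profile must be re-zeroed to the bulk convention before Kd "
            "integration (use rezero_pmf(profile, 'bulk'))"
        )
    fm = profile.finite_mask
    if not fm.any():
        raise ValueError("profile has no finite bins")
    z_fin = profile.z[fm]
    if z_min is None:
        z_min = float(z_fin[0])
    if z_max is None:
        z_max = float(z_fin[-1])
    if z_min > z_max:
        raise ValueError(f"z_min ({z_min:g}) must be <= z_max ({z_max:g})")
    if z_min < z_fin[0] or z_max > z_fin[-1]:
        raise ValueError(
            f"[{z_min:g}, {z_max:g}] exceeds the profile's finite span "
            f"[{z_fin[0]:g}, {z_fin[-1]:g}]"
        )

    in_range = (profile.z >= z_min) & (profile.z <= z_max)
    if np.any(in_range & ~fm):
        warnings.warn(
            f"{int(np.sum(in_range & ~fm))} empty bin(s) inside the "
            "integration range are excluded from the Kd integral",
            stacklevel=2,
        )
    sel = in_range & fm
    z_sel = profile.z[sel]
    if z_sel.size < 2:
        integral = 0.0
    else:
        integral = float(np.trapezoid(np.exp(-profile.w[sel]), z_sel))

    ka = math.pi * radius**2 * integral * _L_PER_CUBIC_ANGSTROM * Avogadro
    kd = 1.0 / ka if ka > 0 else float("inf")
    return BindingResult(kd=kd, ka=ka, integral=integral, radius=radius,
                         z_min=z_min, z_max=z_max, temperature=temperature)


def kd_bounds(profile: PMFProfile, radius: float, sigma_max: float,
              temperature: float = 298.15, z_min: Optional[float] = None,
              z_max: Optional[float] = None) -> tuple[float, float]:
    """(Kd_low, Kd_high) from a uniform ±σ_max shift of the whole profile.

    Shifting W by a constant rescales the integral by exp(∓σ_max), so this
    is a conservative bound consistent with reporting the PMF uncertainty
    as a single worst-case number.  Returns Kd_low ≤ Kd ≤ Kd_high.
    """
    if sigma_max < 0:
        raise ValueError("sigma_max must be >= 0")
    base = compute_kd(profile, radius, temperature, z_min, z_max)
    factor = math.exp(sigma_max)
    return base.kd / factor, base.kd * factor


def fraction_blocked(concentration: float, kd: float) -> float:
    """Single-site occupancy C/(C + Kd): the blocked current fraction at
    free blocker concentration C (same units as Kd)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if not kd > 0:
        raise ValueError("Kd must be > 0")
    if math.isinf(kd):
        return 0.0
    return concentration / (concentration + kd)
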