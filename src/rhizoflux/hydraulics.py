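"""Soil hydraulic functions for unsaturated flow toward roots.

This module implements the van Genuchten water retention curve, the
Mualem unsaturated hydraulic conductivity model, the matric flux potential
(Kirchhoff transform) Phi(psi) = integral of K d(psi), the steady-state
radial water-potential profile around a single root, and the solver for the
critical bulk soil water potential below which steady radial flow can no
longer match a prescribed root-surface flux.

Conventions
-----------
* Water potential ``psi`` is expressed in kPa and is <= 0 (drier = more
  negative).  Internally, pressure head is used in cm of water with
  1 kPa = 10.197 cm H2O, the standard unit of the soil-physics literature.
* Conductivity ``K`` is in cm d-1, the matric flux potential ``Phi`` in
  cm2 d-1, fluxes in cm d-1 and radii in cm.
* ``PSI_DRY = -1e6`` kPa is the integrable dry limit: K is numerically
  negligible below it for the soils considered here, and Phi(PSI_DRY) = 0.

The sand and loam parameter sets shipped as module-level fixtures are the
Carsel & Parrish (1988) sets for those texture classes.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "KPA_TO_CM",
    "PSI_DRY_KPA",
    "SoilHydraulicParams",
    "RadialGeometry",
    "CriticalPotentialResult",
    "SupplyLimitedError",
    "UnsustainableDemandError",
    "SAND",
    "LOAM",
    "FIXTURES",
    "theta_of_psi",
    "psi_of_theta",
    "K_of_psi",
    "matric_flux_potential",
    "psi_of_phi",
    "radial_psi_profile",
    "critical_water_potential",
    "hydraulics_table",
]

#: cm of water head per kPa of suction.
KPA_TO_CM = 10.197

#: Dry integration limit for the matric flux potential (kPa).
PSI_DRY_KPA = -1.0e6


class SupplyLimitedError(ValueError):
    """Raised when the demanded root-surface flux exhausts the matric flux
    potential before the root surface is reached (the supply-limited,
    "dashed-line" regime)."""


class UnsustainableDemandError(ValueError):
    """Raised when the demanded flux cannot be met even at saturation."""


@dataclass(frozen=True)
class SoilHydraulicParams:
    """van Genuchten-Mualem parameter set for one substrate.

    Parameters
    ----------
    theta_r, theta_s : float
        Residual and saturated volumetric water content (cm3 cm-3).
    alpha : float
        Inverse air-entry scale (cm-1 of water head).
    n : float
        Retention-curve shape exponent (> 1); ``m = 1 - 1/n``.
    l : float
        Mualem tortuosity exponent (usually 0.5).
    Ks : float
        Saturated hydraulic conductivity (cm d-1).
    name : str
        Label, e.g. ``"sand"`` or ``"loam"``.
    """

    theta_r: float
    theta_s: float
    alpha: float
    n: float
    l: float
    Ks: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError(
                f"require 0 <= theta_r < theta_s <= 1, got "
                f"theta_r={self.theta_r}, theta_s={self.theta_s}"
            )
        if self.alpha <= 0.0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n <= 1.0:
            raise ValueError(f"n must be > 1, got {self.n}")
        if self.Ks <= 0.0:
            raise ValueError(f"Ks must be > 0, got {self.Ks}")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


@dataclass(frozen=True)
class RadialGeometry:
    """Single-root radial geometry: root radius ``r0``, outer (half root
    spacing) radius ``rb`` and total active root length ``L`` (all cm)."""

    r0: float
    rb: float
    L: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r0 < self.rb):
            raise ValueError(f"require 0 < r0 < rb, got r0={self.r0}, rb={self.rb}")
        if self.L <= 0.0:
            raise ValueError(f"L must be > 0, got {self.L}")


@dataclass(frozen=True)
class CriticalPotentialResult:
    """Critical bulk water potential for a given root-surface demand."""

    psi_crit: float  # kPa, <= 0
    q_demand: float  # cm d-1 at the root surface
    converged: bool


# ---------------------------------------------------------------------------
# Closed-form retention and conductivity
# ---------------------------------------------------------------------------

def _check_psi(psi) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0.0):
        raise ValueError("water potential must be <= 0 kPa")
    return psi


def _se_of_head(params: SoilHydraulicParams, head_cm) -> np.ndarray:
    """Effective saturation Se as a function of suction head magnitude (cm)."""
    ah = params.alpha * np.abs(head_cm)
    return (1.0 + ah ** params.n) ** (-params.m)


def theta_of_psi(params: SoilHydraulicParams, psi):
    """van Genuchten water retention curve theta(psi).

    ``theta = theta_r + (theta_s - theta_r) * Se`` with
    ``Se = (1 + (alpha*|h|)^n)^(-m)`` and ``h`` the head in cm.
    """
    psi = _check_psi(psi)
    se = _se_of_head(params, KPA_TO_CM * np.abs(psi))
    return params.theta_r + (params.theta_s - params.theta_r) * se


def psi_of_theta(params: SoilHydraulicParams, theta):
    """Exact analytic inverse of :func:`theta_of_psi` (kPa).

    Valid for ``theta in (theta_r, theta_s]``; saturated or dry clamping is
    the caller's decision and is deliberately not done here.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= params.theta_r):
        raise ValueError(
            f"theta <= theta_r={params.theta_r}: water potential is undefined "
            "at or below residual water content (clamp before calling if "
            "a dry floor is intended)"
        )
    if np.any(theta > params.theta_s):
        raise ValueError(
            f"theta > theta_s={params.theta_s}: supersaturated input "
            "(clamp to theta_s before calling if saturation is intended)"
        )
    se = (theta - params.theta_r) / (params.theta_s - params.theta_r)
    # |h| = ((Se^(-1/m) - 1)^(1/n)) / alpha
    head = (se ** (-1.0 / params.m) - 1.0) ** (1.0 / params.n) / params.alpha
    return -head / KPA_TO_CM


def K_of_psi(params: SoilHydraulicParams, psi):
    """Mualem unsaturated hydraulic conductivity K(psi) in cm d-1.

    ``K = Ks * Se^l * [1 - (1 - Se^(1/m))^m]^2``.
    """
    psi = _check_psi(psi)
    return _K_of_head(params, KPA_TO_CM * np.abs(psi))


def _K_of_head(params: SoilHydraulicParams, head_cm) -> np.ndarray:
    se = _se_of_head(params, head_cm)
    # Guard the 1 - Se^(1/m) bracket against cancellation at saturation.
    inner = 1.0 - np.minimum(se ** (1.0 / params.m), 1.0)
    return params.Ks * se ** params.l * (1.0 - inner ** params.m) ** 2


# ---------------------------------------------------------------------------
# Matric flux potential (Kirchhoff transform)
# ---------------------------------------------------------------------------

# Head-magnitude grid bounds for the Phi table (cm).  Below S_MIN the
# conductivity is Ks to ~1e-10 relative for any realistic alpha.
_S_MIN = 1.0e-3
_S_DRY = KPA_TO_CM * abs(PSI_DRY_KPA)
_N_NODES = 20000


@functools.lru_cache(maxsize=32)
def _phi_table(params: SoilHydraulicParams):
    """Cumulative-trapezoid table of Phi on a log-spaced head grid.

    Returns ``(log_s, phi)`` with ``phi[i] = integral_{s_i}^{s_dry} K ds``
    plus monotone interpolants for Phi(log s) and its inverse.  Phi spans
    many orders of magnitude, so both axes are interpolated in log space
    with a shape-preserving (PCHIP) interpolant.
    """
    s = np.geomspace(_S_MIN, _S_DRY, _N_NODES)
    k = _K_of_head(params, s)
    # integral from s_i to s_dry of K ds, accumulated from the dry end
    seg = 0.5 * (k[1:] + k[:-1]) * np.diff(s)
    phi = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    # Drop the exact-zero tail for log interpolation; the last retained
    # node is far below any potential of physical interest.
    keep = phi > 0.0
    log_s = np.log(s[keep])
    log_phi = np.log(phi[keep])
    fwd = PchipInterpolator(log_s, log_phi, extrapolate=False)
    inv = PchipInterpolator(log_phi[::-1], log_s[::-1], extrapolate=False)
    return {
        "log_s_min": log_s[0],
        "log_s_max": log_s[-1],
        "phi_sat": phi[0] + params.Ks * _S_MIN,  # Phi at psi = 0
        "phi_at_s_min": phi[0],
        "fwd": fwd,
        "inv": inv,
    }


def matric_flux_potential(params: SoilHydraulicParams, psi):
    """Matric flux potential Phi(psi) = int_{psi_dry}^{psi} K dpsi' (cm2 d-1).

    The integral is taken over pressure head in cm, from the dry limit
    ``PSI_DRY_KPA`` (where Phi is defined as 0) up to ``psi``.
    """
    psi = _check_psi(psi)
    tab = _phi_table(params)
    s = KPA_TO_CM * np.abs(psi)
    scalar = np.ndim(psi) == 0
    s = np.atleast_1d(s)
    out = np.empty_like(s)
    below = s <= _S_MIN  # effectively saturated: linear K ~ Ks segment
    out[below] = tab["phi_at_s_min"] + params.Ks * (_S_MIN - s[below])
    dry = s >= _S_DRY
    out[dry] = 0.0
    mid = ~below & ~dry
    if np.any(mid):
        out[mid] = np.exp(tab["fwd"](np.log(s[mid])))
    return float(out[0]) if scalar else out


def psi_of_phi(params: SoilHydraulicParams, phi):
    """Inverse of :func:`matric_flux_potential`: psi (kPa) with Phi(psi)=phi.

    Monotone bisection-free inversion via the precomputed shape-preserving
    interpolant; values above Phi(0) raise, values at or below Phi(psi_dry)
    return the dry limit.
    """
    tab = _phi_table(params)
    phi = np.asarray(phi, dtype=float)
    scalar = np.ndim(phi) == 0
    phi = np.atleast_1d(phi).copy()
    out = np.empty_like(phi)
    if np.any(phi > tab["phi_sat"] * (1.0 + 1e-12)):
        raise ValueError("phi exceeds Phi(0): no potential this wet exists")
    lo = np.exp(tab["fwd"](tab["log_s_max"]))  # Phi at the driest table node
    dry = phi <= lo
    out[dry] = PSI_DRY_KPA
    wet = phi >= tab["phi_at_s_min"]
    # Linear segment between s=0 and s=S_MIN where K ~ Ks.
    out[wet] = -(_S_MIN - (phi[wet] - tab["phi_at_s_min"]) / params.Ks) / KPA_TO_CM
    out[wet] = np.minimum(out[wet], 0.0)
    mid = ~dry & ~wet
    if np.any(mid):
        out[mid] = -np.exp(tab["inv"](np.log(phi[mid]))) / KPA_TO_CM
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Radial profile and critical potential
# ---------------------------------------------------------------------------

def radial_psi_profile(
    params: SoilHydraulicParams,
    geometry: RadialGeometry,
    psi_bulk: float,
    q0: float,
    r_values,
) -> pd.DataFrame:
    """Steady-state radial water-potential profile toward a root.

    For steady radial flow at root-surface flux ``q0`` (cm d-1), the matric
    flux potential satisfies ``Phi(r) = Phi(psi_bulk) - q0*r0*ln(rb/r)``;
    the profile is mapped back to psi through the inverse Kirchhoff
    transform.

    Returns a DataFrame with columns ``r_cm`` and ``psi_kPa``.

    Raises
    ------
    SupplyLimitedError
        If the demanded flux exhausts Phi before the root surface, i.e. the
        root surface would need to be drier than the dry limit.
    """
    if psi_bulk > 0.0:
        raise ValueError("psi_bulk must be <= 0 kPa")
    if q0 < 0.0:
        raise ValueError("q0 must be >= 0")
    r = np.asarray(r_values, dtype=float)
    if np.any((r < geometry.r0 - 1e-12) | (r > geometry.rb + 1e-12)):
        raise ValueError("r_values must lie within [r0, rb]")
    phi_bulk = matric_flux_potential(params, psi_bulk)
    phi_r0 = phi_bulk - q0 * geometry.r0 * np.log(geometry.rb / geometry.r0)
    if phi_r0 < 0.0:
        raise SupplyLimitedError(
            f"demand q0={q0} cm/d exhausts the matric flux potential before "
            f"the root surface (Phi deficit {-phi_r0:.3e} cm2/d): the bulk "
            f"soil at {psi_bulk} kPa cannot supply this flux"
        )
    phi = phi_bulk - q0 * geometry.r0 * np.log(geometry.rb / r)
    psi = np.atleast_1d(psi_of_phi(params, phi))
    # Enforce the exact outer boundary condition against interpolation noise.
    psi[np.isclose(r, geometry.rb)] = psi_bulk
    return pd.DataFrame({"r_cm": r, "psi_kPa": psi})


def critical_water_potential(
    params: SoilHydraulicParams,
    geometry: RadialGeometry,
    q_demand: float,
    rel_tol: float = 1e-4,
) -> CriticalPotentialResult:
    """Critical bulk water potential for a prescribed root-surface flux.

    Solves ``Phi(psi) = q_demand * r0 * ln(rb/r0)`` for the bulk potential
    psi: the wettest bulk state at which the root-surface potential reaches
    the dry limit, i.e. below which steady radial supply cannot match
    ``q_demand`` (cm d-1).  Bracketing bisection on psi in [PSI_DRY, 0] to
    a relative width ``rel_tol``.
    """
    if q_demand <= 0.0:
        raise ValueError("q_demand must be > 0")
    target = q_demand * geometry.r0 * np.log(geometry.rb / geometry.r0)
    phi_sat = matric_flux_potential(params, 0.0)
    if target > phi_sat:
        raise UnsustainableDemandError(
            f"demand q={q_demand} cm/d needs Phi={target:.3e} cm2/d but "
            f"Phi(0)={phi_sat:.3e}: unsustainable even at saturation"
        )
    lo, hi = PSI_DRY_KPA, 0.0  # Phi(lo)=0 <= target <= Phi(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if matric_flux_potential(params, mid) < target:
            lo = mid
        else:
            hi = mid
        if (lo - hi) > -rel_tol * max(abs(hi), 1e-12):
            break
    psi_crit = 0.5 * (lo + hi)
    return CriticalPotentialResult(
        psi_crit=psi_crit, q_demand=q_demand, converged=(lo - hi) > -rel_tol * abs(psi_crit)
    )


# ---------------------------------------------------------------------------
# Fixtures and tabulation
# ---------------------------------------------------------------------------

#: Carsel & Parrish (1988) sand.
SAND = SoilHydraulicParams(
    theta_r=0.045, theta_s=0.43, alpha=0.145, n=2.68, l=0.5, Ks=712.8, name="sand"
)

#: Carsel & Parrish (1988) loam.
LOAM = SoilHydraulicParams(
    theta_r=0.078, theta_s=0.43, alpha=0.036, n=1.56, l=0.5, Ks=24.96, name="loam"
)

FIXTURES = {"sand": SAND, "loam": LOAM}


def hydraulics_table(
    params: SoilHydraulicParams,
    psi_min: float = -1e5,
    psi_max: float = -1e-2,
    n_points: int = 200,
) -> pd.DataFrame:
    """Tabulate (psi, theta, K, Phi) on a log-|psi| grid, wet to dry."""
    psi = -np.geomspace(abs(psi_max), abs(psi_min), n_points)
    return pd.DataFrame(
        {
            "psi_kPa": psi,
            "theta": theta_of_psi(params, psi),
            "K_cm_d": K_of_psi(params, psi),
            "Phi_cm2_d": matric_flux_potential(params, psi),
        }
    )
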