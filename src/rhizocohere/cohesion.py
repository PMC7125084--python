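"""EUROSEM-style back-calculation of soil cohesion from detachment rates.

Concentrated-flow detachment in EUROSEM is proportional to a flow
detachment efficiency coefficient beta.  With the detachment rate measured,
beta is the only unknown:

    beta = ASD / (B_D * v_s * C_TC)

where ASD is the average soil detachment rate (g cm^-2 s^-1), B_D the soil
bulk density (g cm^-3), C_TC the transport-capacity term of the flow, and
v_s the particle settling velocity

    v_s = sqrt(4 * d50 * (rho_s - rho_w) * g / (3 * C_D * rho_w))

with C_D the drag coefficient at the grain Reynolds number.  Cohesion then
follows from the empirical efficiency-cohesion law

    C = -ln(beta / 0.79) / 0.85        (kPa)

so beta = 0.79 corresponds to a cohesionless bed.  Root reinforcement is
the cohesion difference between rooted and bare soil, and grows with root
length density approximately as a * ln(RLD + 1).

Internally the package is SI; the beta denominator is evaluated in the CGS
units the efficiency law was calibrated in (g, cm, s), with conversions at
that boundary only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, IterationFailureError, NegativeCohesionWarning

#: Efficiency of a cohesionless bed; beta above this implies C <= 0.
BETA_MAX = 0.79
#: Decay constant of the efficiency-cohesion law, per kPa.
COHESION_DECAY = 0.85


@dataclass(frozen=True)
class SoilParams:
    """Sediment and fluid constants (SI)."""

    d50: float = 16e-6  # m, median grain diameter of the clay-loam soil
    rho_s: float = 2650.0  # kg m^-3, detached sediment density
    rho_w: float = 1000.0  # kg m^-3
    water_viscosity: float = 1.002e-3  # Pa s at 20 C
    bulk_density: float = 1.17  # g cm^-3, mid-range dry bulk density
    gravity: float = 9.81  # m s^-2

    def __post_init__(self) -> None:
        if not (self.rho_s > self.rho_w > 0):
            raise ValueError("need rho_s > rho_w > 0")
        if self.d50 <= 0 or self.water_viscosity <= 0 or self.bulk_density <= 0:
            raise ValueError("d50, viscosity and bulk_density must be positive")


@dataclass(frozen=True)
class FlowState:
    """Per-run flow quantities entering the beta denominator."""

    transport_capacity_term: float  # C_TC, sediment-concentration units
    grain_reynolds: Optional[float] = None
    drag_coefficient: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transport_capacity_term <= 0:
            raise ValueError("transport_capacity_term must be positive")
        for v in (self.grain_reynolds, self.drag_coefficient):
            if v is not None and v <= 0:
                raise ValueError("flow quantities must be positive")


@dataclass(frozen=True)
class ReinforcementModel:
    """Origin-anchored logarithmic reinforcement model a * ln(RLD + 1), kPa."""

    a: float
    a_se: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("reinforcement coefficient a must be >= 0")


def drag_coefficient(re: float) -> float:
    """Drag coefficient at grain Reynolds number Re (intermediate-Re law).

    C_D = 24/Re + 3/sqrt(Re) + 0.34, valid from creeping flow through the
    transitional regime; tends to 0.34 at large Re.
    """
    if re <= 0:
        raise ValueError("grain Reynolds number must be positive")
    return 24.0 / re + 3.0 / math.sqrt(re) + 0.34


def grain_reynolds(velocity: float, soil: SoilParams) -> float:
    """Particle Reynolds number rho_w * v * d50 / mu."""
    return soil.rho_w * velocity * soil.d50 / soil.water_viscosity


def settling_velocity(
    soil: SoilParams,
    cd: Optional[float] = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> float:
    """Particle settling velocity, m s^-1.

    With ``cd`` given, evaluates the balance directly.  Without it, iterates
    v -> Re(v) -> C_D(Re) -> v to the self-consistent fixed point; for the
    16-um grains used here this lands within a few percent of Stokes' law.
    """
    if cd is not None:
        if cd <= 0:
            raise ValueError("drag coefficient must be positive")
        return _settling(soil, cd)
    # Stokes start, then fixed-point iteration on the drag law
    v = (
        soil.gravity * soil.d50**2 * (soil.rho_s - soil.rho_w)
        / (18.0 * soil.water_viscosity)
    )
    if v == 0.0:
        return 0.0
    for _ in range(maxiter):
        v_new = _settling(soil, drag_coefficient(grain_reynolds(v, soil)))
        if abs(v_new - v) <= tol * max(v_new, 1e-300):
            return v_new
        v = v_new
    raise IterationFailureError("settling-velocity iteration did not converge")


def _settling(soil: SoilParams, cd: float) -> float:
    return math.sqrt(
        4.0 * soil.d50 * (soil.rho_s - soil.rho_w) * soil.gravity / (3.0 * cd * soil.rho_w)
    )


def detachment_efficiency(asd: float, soil: SoilParams, flow: FlowState) -> float:
    """Flow detachment efficiency beta from a measured detachment rate.

    ``asd`` is the average soil detachment rate in SI (kg m^-2 s^-1); it is
    converted to g cm^-2 s^-1 at this boundary.  The denominator is bulk
    density (g cm^-3) x settling velocity (cm s^-1) x transport-capacity
    term, each factor independently overridable through ``soil``/``flow``.
    """
    if asd < 0:
        raise ValueError("detachment rate must be non-negative")
    cd = flow.drag_coefficient
    if cd is None and flow.grain_reynolds is not None:
        cd = drag_coefficient(flow.grain_reynolds)
    v_s = settling_velocity(soil, cd)  # m s^-1
    denom = soil.bulk_density * (v_s * 100.0) * flow.transport_capacity_term
    if denom <= 0:
        raise ValueError("beta denominator must be positive")
    asd_cgs = asd * 0.1  # kg m^-2 s^-1 -> g cm^-2 s^-1
    return asd_cgs / denom


def cohesion_from_beta(beta: float) -> float:
    """Soil cohesion in kPa from the efficiency-cohesion law.

    beta above the cohesionless ceiling 0.79 would give negative cohesion;
    such values return 0 kPa with a :class:`NegativeCohesionWarning` so
    downstream fits stay defined.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if beta > BETA_MAX:
        warnings.warn(
            f"beta = {beta:.4g} exceeds the cohesionless ceiling {BETA_MAX}; "
            "cohesion floored at 0 kPa",
            NegativeCohesionWarning,
            stacklevel=2,
        )
        return 0.0
    return -math.log(beta / BETA_MAX) / COHESION_DECAY


def beta_from_cohesion(cohesion_kpa: float) -> float:
    """Inverse map: beta = 0.79 * exp(-0.85 * C)."""
    return BETA_MAX * math.exp(-COHESION_DECAY * cohesion_kpa)


def root_reinforcement(c_rooted: float, c_bare: float) -> float:
    """Cohesion gain from roots, kPa (rooted minus bare; negative allowed)."""
    if not (np.isfinite(c_rooted) and np.isfinite(c_bare)):
        raise ValueError("cohesion values must be finite")
    delta = c_rooted - c_bare
    if delta < 0:
        warnings.warn(
            f"negative root reinforcement ({delta:.3g} kPa)", UserWarning, stacklevel=2
        )
    return delta


def fit_log_reinforcement(points: Sequence[tuple[float, float]]) -> ReinforcementModel:
    """Least-squares coefficient a of a * ln(RLD + 1) through the origin."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (rld, kPa) points")
    rld, y = pts[:, 0], pts[:, 1]
    if np.any(rld < 0):
        raise ValueError("rld must be non-negative")
    x = np.log1p(rld)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise InsufficientDataError("all points at RLD 0; coefficient undetermined")
    a = float(np.sum(x * y) / sxx)
    resid = y - a * x
    sigma2 = float(np.sum(resid**2) / max(len(y) - 1, 1))
    return ReinforcementModel(a=max(a, 0.0), a_se=math.sqrt(sigma2 / sxx))


def evaluate_log_reinforcement(model: ReinforcementModel, rld) -> np.ndarray | float:
    """Reinforcement a * ln(RLD + 1) in kPa."""
    x = np.asarray(rld, dtype=float)
    if np.any(x < 0):
        raise ValueError("rld must be non-negative")
    out = model.a * np.log1p(x)
    return float(out) if np.isscalar(rld) else out
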