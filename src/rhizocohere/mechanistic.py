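"""Mechanistic model of erosion response to root length density and root hairs.

The model couples three ingredients:

1. **Fluid flow.**  For a parabolic flow profile over a permeable bed the
   bed shear stress is ``tau = 3 g Q d50^2 sin(slope) / (2 V k W)`` with
   flow rate Q, surface velocity V, permeability k and flume width W.

2. **Root-occupied volume.**  Each root system occupies a kite-shaped
   region (vertical extent D, maximum lateral spread ``spread`` at depth d),
   idealised as two coaxial cones sharing a base: V_kite = pi*spread^2*D/12.
   The *true* root length density RLD_T is the total root length divided by
   the root-occupied volume only, so RLD_T >= box RLD.

3. **Heterogeneous Coulomb cohesion.**  Erosion occurs where the effective
   shear (tau plus any frictional term mu*N) exceeds the local cohesion.
   Root hairs enhance cohesion through a saturating rate function

       gamma(x) = M_max * tanh(M1 * x / M_max)      [mm^-1]

   whose initial slope is M1 (the initial enhancement rate) and whose
   ceiling is M_max = M1 / M2.  The tanh argument uses RLD_T on the
   m m^-3 scale (RLD_T in km m^-3 times 1000), which places saturation at
   RLD_T ~ M_max / M1 ~ 25 km m^-3 for the calibrated parameter ranges -
   exactly where hairless-line erosion stops improving.  Cohesion is
   maximal at the tap root, c_max = c_bare*(1 + gamma*R), minimal midway
   between plants, c_min = c_bare*(1 + gamma*r), with R the maximum erosion
   depth and r the reinforced depth between plants (both in mm here).

Between plants the reinforced depth is interpolated sinusoidally,
``rho(x) = (R+r)/2 + (R-r)/2 * cos(2 pi x / L)``, and the predicted
relative detachment is the fraction of one spatial period where the
effective shear exceeds the local cohesion ``c_bare*(1 + gamma*rho(x))``.
That fraction has the closed form

    F = 1 - arccos(w)/pi,  w = clamp((u - (R+r)/2) / ((R-r)/2), -1, 1),
    u = (tau_eff/c_bare - 1) / gamma

and is independent of the period length L.  Calibrating (M1, M2) against an
observed erosion-reduction curve by minimising the maximum relative error
recovers the root-hair enhancement parameters of a genotype.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import BareSoilUnerodedWarning, CalibrationError


@dataclass(frozen=True)
class FlumeConfig:
    """Flume flow conditions and bed properties (SI)."""

    Q: float = 1e-3  # m^3 s^-1
    V: float = 1.0  # m s^-1 surface velocity
    slope: float = 28.0  # degrees
    flume_width: float = 0.36  # m
    permeability: float = 0.2273e-12  # m^2 (0.2273 um^2)
    d50: float = 16e-6  # m
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if min(self.Q, self.V, self.flume_width, self.permeability, self.d50) <= 0:
            raise ValueError("flume quantities must be positive")
        if not (0.0 < self.slope < 90.0):
            raise ValueError("slope must lie in (0, 90) degrees")


@dataclass(frozen=True)
class RootGeometry:
    """Kite root geometry and erosion depths (metres), plus box layout."""

    D: float = 0.100  # vertical extent of the root system
    d: float = 0.025  # depth of maximum lateral spread
    spread: float = 0.100  # maximum lateral extent
    R: float = 0.050  # maximum erosion depth
    r: float = 0.0325  # reinforced depth midway between plants
    box_length: float = 0.25
    box_width: float = 0.25
    box_depth: float = 0.15
    plant_count: int = 49

    def __post_init__(self) -> None:
        if not (0.0 < self.d < self.D):
            raise ValueError("need 0 < d < D")
        if not (0.0 < self.r <= self.R):
            raise ValueError("need 0 < r <= R")
        if self.plant_count < 1:
            raise ValueError("plant_count must be >= 1")

    @property
    def kite_volume(self) -> float:
        """Volume of one root system: two coaxial cones sharing a base, m^3."""
        return math.pi * self.spread**2 * self.D / 12.0

    @property
    def box_area(self) -> float:
        return self.box_length * self.box_width

    @property
    def box_volume(self) -> float:
        return self.box_area * self.box_depth

    @property
    def plant_spacing(self) -> float:
        """Nominal inter-plant period, m (box width / sqrt(plant count))."""
        return self.box_width / math.sqrt(self.plant_count)


@dataclass(frozen=True)
class MechParams:
    """Root-hair enhancement and soil-strength parameters.

    ``m1`` is the initial enhancement rate (mm^-1 per m m^-3 of RLD_T) and
    ``m2 = m1 / m_max`` its ratio to the saturation value ``m_max`` (mm^-1).
    ``c_bare`` is the effective bare-soil resistance on the same stress
    scale as the bed shear stress (Pa); its default is calibrated so the
    saturated hairless curve plateaus at the observed relative detachment.
    """

    m1: float = 5.45e-3
    m2: float = 5.45e-3 / 139.0
    c_bare: float = 6.93e-3  # Pa, effective; see class docstring
    friction_mu: float = 0.0
    normal_stress: float = 0.0  # Pa

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("m1 and m2 must be positive")
        if self.c_bare <= 0:
            raise ValueError("c_bare must be positive")

    @property
    def m_max(self) -> float:
        """Saturation value of the enhancement rate, mm^-1."""
        return self.m1 / self.m2


def bed_shear_stress(cfg: FlumeConfig) -> float:
    """Bed shear stress tau = 3 g Q d50^2 sin(slope) / (2 V k W), Pa."""
    return (
        3.0 * cfg.gravity * cfg.Q * cfg.d50**2 * math.sin(math.radians(cfg.slope))
    ) / (2.0 * cfg.V * cfg.permeability * cfg.flume_width)


def true_rld(box_rld: float, geom: RootGeometry) -> float:
    """True root length density RLD_T (km m^-3): total root length over the
    root-occupied volume, capped at the full rooted slab (box area x D)."""
    if box_rld < 0:
        raise ValueError("box_rld must be non-negative")
    occupied = min(geom.plant_count * geom.kite_volume, geom.box_area * geom.D)
    return box_rld * geom.box_volume / occupied


def gamma(rld_t: float, params: MechParams) -> float:
    """Root-hair cohesion enhancement rate, mm^-1.

    ``rld_t`` is given in km m^-3 and converted to m m^-3 inside the tanh
    argument, so the small-x slope with respect to RLD_T in m m^-3 is m1.
    """
    if rld_t < 0:
        raise ValueError("rld_t must be non-negative")
    x = rld_t * 1000.0  # km m^-3 -> m m^-3
    return params.m_max * math.tanh(params.m1 * x / params.m_max)


def cohesion_extremes(
    rld_t: float, params: MechParams, geom: RootGeometry
) -> tuple[float, float]:
    """(c_min, c_max): local cohesion midway between plants and at the tap
    root, on the c_bare stress scale; gamma is per mm so R, r enter in mm."""
    g = gamma(rld_t, params)
    c_max = params.c_bare * (1.0 + g * geom.R * 1000.0)
    c_min = params.c_bare * (1.0 + g * geom.r * 1000.0)
    return c_min, c_max


def erosion_fraction(
    tau: float,
    rld_t: float,
    params: MechParams,
    geom: RootGeometry,
    spacing: Optional[float] = None,
) -> float:
    """Eroded fraction of one lateral period between plants (= relative
    detachment).

    The reinforced depth varies sinusoidally between r and R over the
    inter-plant period; erosion occurs where the effective shear
    ``tau + mu*N`` exceeds the local cohesion ``c_bare*(1 + gamma*rho)``.
    The closed form is independent of the period length, so ``spacing``
    (defaulting to the nominal inter-plant distance) does not alter the
    result; it is kept for profile-based diagnostics.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    tau_eff = tau + params.friction_mu * params.normal_stress
    g = gamma(rld_t, params)
    if g == 0.0:
        if tau_eff > params.c_bare:
            return 1.0
        warnings.warn(
            "effective shear does not exceed bare-soil cohesion; no erosion",
            BareSoilUnerodedWarning,
            stacklevel=2,
        )
        return 0.0
    u = (tau_eff / params.c_bare - 1.0) / g  # mm
    r_mm, big_r_mm = geom.r * 1000.0, geom.R * 1000.0
    if big_r_mm == r_mm:
        return 1.0 if u > big_r_mm else 0.0
    w = (u - 0.5 * (big_r_mm + r_mm)) / (0.5 * (big_r_mm - r_mm))
    w = min(1.0, max(-1.0, w))
    return 1.0 - math.acos(w) / math.pi


def erosion_curve(
    rld_grid: Sequence[float],
    params: MechParams,
    geom: RootGeometry = RootGeometry(),
    cfg: FlumeConfig = FlumeConfig(),
) -> np.ndarray:
    """Predicted relative detachment versus box RLD (km m^-3)."""
    tau = bed_shear_stress(cfg)
    return np.array(
        [
            erosion_fraction(tau, true_rld(x, geom), params, geom)
            for x in np.asarray(rld_grid, dtype=float)
        ]
    )


#: Denominator floor for relative errors against near-zero observations.
_REL_ERR_FLOOR = 0.01


def _max_rel_error(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.max(np.abs(pred - obs) / np.maximum(np.abs(obs), _REL_ERR_FLOOR)))


def calibrate_M(
    observed: Sequence[tuple[float, float]],
    geom: RootGeometry = RootGeometry(),
    cfg: FlumeConfig = FlumeConfig(),
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((5e-4, 5e-2), (20.0, 500.0)),
    base_params: MechParams = MechParams(),
    grid_size: int = 40,
    objective: str = "max_rel",
) -> tuple[MechParams, float]:
    """Calibrate (M1, M2) against an observed erosion-reduction curve.

    ``observed`` holds (box RLD in km m^-3, relative detachment) pairs.
    ``bounds`` bracket (M1, M_max).  A deterministic log-grid scan over
    (M1, M_max) is refined with Nelder-Mead; the objective is the maximum
    relative error between model and observations (the paper-style accuracy
    figure), with an RMSE alternative.  Returns the fitted parameters and
    the achieved objective value.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 4:
        raise CalibrationError("calibration needs >= 4 (rld, ratio) observations")
    rld, ratio = obs[:, 0], obs[:, 1]
    if objective == "max_rel":
        err_fn = _max_rel_error
    elif objective == "rmse":
        err_fn = lambda p, o: float(np.sqrt(np.mean((p - o) ** 2)))
    else:
        raise ValueError(f"unknown objective {objective!r}")

    (m1_lo, m1_hi), (mm_lo, mm_hi) = bounds

    def loss(logp: np.ndarray) -> float:
        m1, m_max = np.exp(logp)
        if not (m1_lo <= m1 <= m1_hi and mm_lo <= m_max <= mm_hi):
            return 1e6
        params = replace(base_params, m1=m1, m2=m1 / m_max)
        return err_fn(erosion_curve(rld, params, geom, cfg), ratio)

    m1_grid = np.log(np.geomspace(m1_lo, m1_hi, grid_size))
    mm_grid = np.log(np.geomspace(mm_lo, mm_hi, grid_size))
    cells = [
        (loss(np.array([lm1, lmm])), lm1, lmm) for lm1 in m1_grid for lmm in mm_grid
    ]
    cells.sort(key=lambda c: c[0])
    if cells[0][0] >= 1e6:
        raise CalibrationError("no feasible parameters within bounds")

    # polish from the best grid cells; the max-error surface is piecewise
    # smooth and multi-modal, so a single start can stall on a shoulder
    best, logp = cells[0][0], np.array(cells[0][1:])
    for val, lm1, lmm in cells[:8]:
        res = minimize(
            loss,
            np.array([lm1, lmm]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000, "maxfev": 4000},
        )
        if res.fun < best:
            best, logp = float(res.fun), res.x
    achieved = best
    m1, m_max = np.exp(logp)
    fitted = replace(base_params, m1=float(m1), m2=float(m1 / m_max))
    return fitted, achieved
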