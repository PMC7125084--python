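"""Flume erosion assay: detachment rates, normalisation and empirical models.

Soil boxes (0.25 x 0.25 m surface) permeated by roots are exposed to
concentrated overland flow on a 28-degree flume; run-off sediment is
captured for 5 s at regular intervals.  Per-box soil detachment rates
(kg m^-2 s^-1) are normalised by the detachment rate extrapolated to zero
root length density, giving a dimensionless "erosion reduction" ratio that
declines with RLD.

Empirical models fitted to (RLD, ratio) points:

* ``exponential``            ratio = exp(b * RLD), forced to 1 at RLD 0
* ``decay-to-plateau``       ratio = p + (1 - p) * exp(b * RLD)
* ``piecewise``              exponential below a breakpoint RLD, constant
                             (the mean ratio) above it

Parameter uncertainty is propagated with a parametric Monte Carlo: each
parameter is redrawn from a normal centred on its estimate with sd equal to
its standard error, and per-grid-point 2.5/97.5 percentiles of the redrawn
curves form the 95% band.  Two genotypes differ significantly (P < 0.05)
wherever each point curve falls outside the other's band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError

#: Soil-box surface area exposed to the flow, m^2 (0.25 m x 0.25 m).
BOX_AREA = 0.0625

FORMS = ("exponential", "decay-to-plateau", "piecewise")


@dataclass(frozen=True)
class ErosionRun:
    """One soil box run through the flume.

    ``intervals`` holds (start_s, duration_s, sediment_dry_mass_kg) capture
    records; ``rld`` is the measured root length density in km m^-3 (0 for
    bare controls).
    """

    genotype: str
    plant_count: int
    intervals: tuple[tuple[float, float, float], ...]
    flow_rate: float = 1e-3  # m^3 s^-1
    surface_velocity: float = 1.2  # m s^-1
    slope: float = 28.0  # degrees
    rld: float = 0.0  # km m^-3
    bulk_density: float = 1.17  # g cm^-3

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError("run needs at least one capture interval")
        for start, dur, mass in self.intervals:
            if dur <= 0:
                raise ValueError("capture durations must be positive")
            if mass < 0:
                raise ValueError("sediment masses must be non-negative")
            if start + dur > 120.0 + 1e-9:
                raise ValueError("run must finish within 120 s")
        if self.rld < 0:
            raise ValueError("rld must be non-negative")


@dataclass(frozen=True)
class EmpiricalErosionModel:
    """Fitted erosion-reduction model with standard errors."""

    form: str
    b: Optional[float] = None  # per km m^-3, <= 0
    b_se: Optional[float] = None
    plateau: Optional[float] = None  # dimensionless, in [0, 1]
    plateau_se: Optional[float] = None
    breakpoint: Optional[float] = None  # km m^-3

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.b is not None and self.b > 0:
            raise ValueError("decay exponent b must be <= 0")
        if self.plateau is not None and not (0.0 <= self.plateau <= 1.0):
            raise ValueError("plateau must lie in [0, 1]")


@dataclass(frozen=True)
class McBand:
    """Monte-Carlo 95% uncertainty band of a fitted model on an RLD grid."""

    grid: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        if not (
            np.all(self.lower <= self.point + 1e-12)
            and np.all(self.point <= self.upper + 1e-12)
        ):
            raise ValueError("band must bracket the point curve")


def detachment_rate(run: ErosionRun) -> float:
    """Mean soil detachment rate over the capture intervals, kg m^-2 s^-1."""
    rates = [mass / (BOX_AREA * dur) for _, dur, mass in run.intervals]
    return float(np.mean(rates))


def extrapolate_bare_rate(runs: Sequence[ErosionRun]) -> tuple[float, float]:
    """Fit rate = A0 * exp(b * RLD) to per-run rates; return (A0, b).

    Bare boxes enter the fit at RLD 0; A0 is the extrapolated bare-soil
    detachment rate used to normalise every run.
    """
    rld = np.array([r.rld for r in runs], dtype=float)
    rate = np.array([detachment_rate(r) for r in runs], dtype=float)
    has_controls = np.any(rld == 0)
    if not has_controls and np.unique(rld).size < 3:
        raise InsufficientDataError(
            "need bare-soil controls or >= 3 distinct RLD levels to extrapolate"
        )
    positive = rate > 0
    if positive.sum() < 2:
        raise InsufficientDataError("need >= 2 positive detachment rates")
    if np.unique(rld).size == 1:  # bare controls only: flat extrapolation
        return float(np.mean(rate)), 0.0
    # log-linear start values, then untransformed least squares
    slope, intercept = np.polyfit(rld[positive], np.log(rate[positive]), 1)
    try:
        popt, _ = curve_fit(
            lambda x, a0, b: a0 * np.exp(b * x),
            rld,
            rate,
            p0=[float(np.exp(intercept)), float(min(slope, -1e-9))],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise FitFailureError(f"bare-rate extrapolation failed: {exc}") from exc
    return float(popt[0]), float(popt[1])


def relative_detachment(runs: Sequence[ErosionRun]) -> np.ndarray:
    """Per-run dimensionless detachment ratios (rate / extrapolated bare rate)."""
    a0, _ = extrapolate_bare_rate(runs)
    return np.array([detachment_rate(r) / a0 for r in runs])


def fit_empirical(
    points: Sequence[tuple[float, float]],
    form: str = "exponential",
    breakpoint: Optional[float] = None,
) -> EmpiricalErosionModel:
    """Least-squares fit of an erosion-reduction model to (RLD, ratio) points.

    Standard errors are asymptotic (from the least-squares covariance); the
    piecewise plateau is the mean ratio above the breakpoint with the
    standard error of that mean.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (rld, ratio) pairs")
    x, y = pts[:, 0], pts[:, 1]

    if form == "exponential":
        b, b_se = _fit_exponential(x, y)
        return EmpiricalErosionModel(form=form, b=b, b_se=b_se)

    if form == "decay-to-plateau":
        if x.size < 4:
            raise InsufficientDataError("decay-to-plateau fit needs >= 4 points")
        try:
            popt, pcov = curve_fit(
                lambda x_, b_, p_: p_ + (1.0 - p_) * np.exp(b_ * x_),
                x,
                y,
                p0=[-0.1, float(np.clip(y.min(), 0.0, 1.0))],
                bounds=([-np.inf, 0.0], [0.0, 1.0]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitFailureError(f"decay-to-plateau fit failed: {exc}") from exc
        se = np.sqrt(np.diag(pcov))
        return EmpiricalErosionModel(
            form=form, b=float(popt[0]), b_se=float(se[0]),
            plateau=float(popt[1]), plateau_se=float(se[1]),
        )

    if form == "piecewise":
        if breakpoint is None:
            raise ValueError("piecewise form requires a breakpoint")
        below = x < breakpoint
        above = ~below
        if above.sum() < 2:
            raise InsufficientDataError("piecewise fit needs >= 2 points above breakpoint")
        b, b_se = _fit_exponential(x[below], y[below])
        plateau = float(np.mean(y[above]))
        plateau_se = (
            float(np.std(y[above], ddof=1) / np.sqrt(above.sum())) if above.sum() > 1 else 0.0
        )
        return EmpiricalErosionModel(
            form=form, b=b, b_se=b_se,
            plateau=float(np.clip(plateau, 0.0, 1.0)), plateau_se=plateau_se,
            breakpoint=float(breakpoint),
        )

    raise ValueError(f"unknown form {form!r}")


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 4:
        raise InsufficientDataError("exponential fit needs >= 4 points")
    try:
        popt, _ = curve_fit(
            lambda x_, b_: np.exp(b_ * x_), x, y, p0=[-0.1], maxfev=10000
        )
    except RuntimeError as exc:
        raise FitFailureError(f"exponential fit failed: {exc}") from exc
    b = float(min(popt[0], 0.0))
    # heteroscedasticity-robust (sandwich) asymptotic SE: detachment noise is
    # multiplicative, so the homoscedastic covariance understates the spread
    grad = x * np.exp(b * x)
    resid = y - np.exp(b * x)
    bread = float(np.sum(grad**2))
    if bread == 0.0:
        return b, 0.0
    dof = max(x.size - 1, 1)
    meat = float(np.sum(grad**2 * resid**2)) * x.size / dof
    return b, math.sqrt(meat) / bread


def evaluate_empirical(model: EmpiricalErosionModel, rld) -> np.ndarray | float:
    """Evaluate a fitted model at RLD value(s); ratios are dimensionless."""
    x = np.asarray(rld, dtype=float)
    if np.any(x < 0):
        raise ValueError("rld must be non-negative")
    if model.form == "exponential":
        out = np.exp(model.b * x)
    elif model.form == "decay-to-plateau":
        out = model.plateau + (1.0 - model.plateau) * np.exp(model.b * x)
    else:  # piecewise; not constrained continuous at the breakpoint
        out = np.where(x < model.breakpoint, np.exp(model.b * x), model.plateau)
    return float(out) if np.isscalar(rld) else out


def _perturbed(model: EmpiricalErosionModel, rng: np.random.Generator, draws: int):
    """Yield redrawn models with parameters ~ N(estimate, SE)."""
    b = model.b + (model.b_se or 0.0) * rng.standard_normal(draws) if model.b is not None else None
    if model.plateau is not None:
        p = np.clip(
            model.plateau + (model.plateau_se or 0.0) * rng.standard_normal(draws), 0.0, 1.0
        )
    else:
        p = None
    for i in range(draws):
        yield EmpiricalErosionModel(
            form=model.form,
            b=None if b is None else float(min(b[i], 0.0)),
            b_se=0.0 if b is None else model.b_se,
            plateau=None if p is None else float(p[i]),
            plateau_se=None if p is None else model.plateau_se,
            breakpoint=model.breakpoint,
        )


def monte_carlo_band(
    model: EmpiricalErosionModel,
    grid: Sequence[float],
    draws: int = 10000,
    seed: Optional[int] = None,
) -> McBand:
    """95% parametric Monte-Carlo band of the fitted curve on an RLD grid."""
    for name in ("b", "plateau"):
        est, se = getattr(model, name), getattr(model, f"{name}_se")
        if est is not None and (se is None or not np.isfinite(se)):
            raise ValueError(f"model is missing a finite standard error for {name}")
    g = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    curves = np.empty((draws, g.size))
    for i, m in enumerate(_perturbed(model, rng, draws)):
        curves[i] = evaluate_empirical(m, g)
    point = np.asarray(evaluate_empirical(model, g))
    lower = np.minimum(np.percentile(curves, 2.5, axis=0), point)
    upper = np.maximum(np.percentile(curves, 97.5, axis=0), point)
    return McBand(grid=g, point=point, lower=lower, upper=upper, draws=draws, seed=seed)


def compare_bands(a: McBand, b: McBand) -> np.ndarray:
    """Per-grid-point significance flags: True where the two fitted curves
    are mutually outside each other's 95% bands (P < 0.05)."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("bands must share the same RLD grid")
    a_out = (a.point < b.lower) | (a.point > b.upper)
    b_out = (b.point < a.lower) | (b.point > a.upper)
    return a_out & b_out
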