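"""Synthetic experiment generators.

Every assay in the pipeline can be exercised without the deposited raw data
by generating inputs with the statistical structure the analysis assumes:

* detachment cohorts whose force-scale survival follows a proportional-
  hazards construction on a Weibull baseline, scaled per genotype by the
  published hazard ratios;
* uprooting traces following the elastic/damage piecewise model (linear
  rise to the peak, linear decline to pull-out) with planted instantaneous
  force drops and additive sensor noise;
* flume erosion runs whose expected relative detachment follows the
  genotype's empirical erosion-reduction model, with multiplicative
  lognormal interval noise;
* root populations with genotype- and substrate-specific SRL distributions.

All generators are pure functions of (parameters, seed): a global seed fans
out to fixed, documented per-generator streams (1 cohorts, 2 traces,
3 erosion, 4 roots), so identical seeds give identical outputs and the
streams stay independent of one another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .centrifuge import SeedlingRecord, SpinProtocol, centrifugal_force
from .erosion import BOX_AREA, EmpiricalErosionModel, ErosionRun, evaluate_empirical
from .uprooting import ForceTrace, RootMassRecord

_STREAMS = {"cohort": 1, "traces": 2, "erosion": 3, "roots": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class GenotypeProfile:
    """Genotype-level defaults driving the generators.

    SRL means/sds are per substrate (m mg^-1); the hazard ratio is relative
    to wild type on the detachment-force scale; ``empirical_b``/``plateau``
    describe the erosion-reduction model; ``mech_m1``/``mech_m_max`` the
    root-hair enhancement function.
    """

    name: str
    srl: dict[str, tuple[float, float]]
    detach_hazard_ratio: float
    empirical_b: float
    plateau: Optional[float] = None
    breakpoint: Optional[float] = None
    rld_range: tuple[float, float] = (3.0, 56.0)
    reinforcement_a: float = 1.0
    mech_m1: float = 5e-3
    mech_m_max: float = 100.0

    def __post_init__(self) -> None:
        if self.detach_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.empirical_b > 0:
            raise ValueError("empirical_b must be <= 0")

    def erosion_model(self) -> EmpiricalErosionModel:
        """The genotype's erosion-reduction model (piecewise if a plateau is set)."""
        if self.plateau is None:
            return EmpiricalErosionModel(form="exponential", b=self.empirical_b, b_se=0.0)
        return EmpiricalErosionModel(
            form="piecewise",
            b=self.empirical_b,
            b_se=0.0,
            plateau=self.plateau,
            plateau_se=0.0,
            breakpoint=self.breakpoint,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes and the global seed shared by all generators."""

    seed: int = 0
    trace_noise_sd: float = 0.0  # N, additive on loads
    erosion_lognorm_sigma: float = 0.3  # sd of log interval multipliers
    mass_cv: float = 0.3  # lognormal sigma of masses

    def __post_init__(self) -> None:
        if min(self.trace_noise_sd, self.erosion_lognorm_sigma, self.mass_cv) < 0:
            raise ValueError("noise magnitudes must be non-negative")


def load_profiles() -> dict[str, GenotypeProfile]:
    """Genotype defaults shipped with the package (versioned JSON)."""
    raw = json.loads(
        resources.files("rhizocohere").joinpath("data/profiles.json").read_text()
    )
    out = {}
    for key, p in raw["profiles"].items():
        out[key] = GenotypeProfile(
            name=p["name"],
            srl={k: tuple(v) for k, v in p["srl"].items()},
            detach_hazard_ratio=p["detach_hazard_ratio"],
            empirical_b=p["empirical_b"],
            plateau=p["plateau"],
            breakpoint=p["breakpoint"],
            rld_range=tuple(p["rld_range"]),
            reinforcement_a=p["reinforcement_a"],
            mech_m1=p["mech_m1"],
            mech_m_max=p["mech_m_max"],
        )
    return out


PROFILES = load_profiles()

#: Weibull baseline of the detachment-force distribution: scale (N) and
#: shape, chosen so roughly a third of wild-type seedlings survive the
#: fastest spin, as in the gel assay.
BASELINE_FORCE_SCALE = 0.04
BASELINE_FORCE_SHAPE = 1.5
#: Median aerial mass of a 5-day seedling, kg (placeholder scale; the true
#: distribution is not published).
MEDIAN_AERIAL_MASS = 2.0e-5


def gen_detachment_cohort(
    n: int,
    profile: GenotypeProfile,
    protocol: SpinProtocol = SpinProtocol(),
    noise: NoiseSpec = NoiseSpec(),
) -> list[SeedlingRecord]:
    """Cohort of centrifuged seedlings under a proportional-hazards model.

    Latent detachment forces follow S(f) = exp(-HR * (f/scale)^shape) (a
    Weibull baseline with the genotype hazard ratio acting multiplicatively
    on the cumulative hazard).  Each seedling detaches at the first spin
    setting whose mass-specific centrifugal force reaches its latent force;
    seedlings surviving the fastest setting are censored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(noise.seed, "cohort")
    masses = MEDIAN_AERIAL_MASS * np.exp(noise.mass_cv * rng.standard_normal(n))
    u = rng.uniform(size=n)
    latent = BASELINE_FORCE_SCALE * (
        -np.log(u) / profile.detach_hazard_ratio
    ) ** (1.0 / BASELINE_FORCE_SHAPE)
    records = []
    for i in range(n):
        rec = None
        for setting in protocol.settings:
            probe = SeedlingRecord(
                id=f"{profile.name}-{i:04d}", genotype=profile.name,
                aerial_mass=float(masses[i]), detach_setting=setting,
            )
            if centrifugal_force(probe, setting, protocol) >= latent[i]:
                rec = probe
                break
        if rec is None:
            rec = SeedlingRecord(
                id=f"{profile.name}-{i:04d}", genotype=profile.name,
                aerial_mass=float(masses[i]), censored=True,
            )
        records.append(rec)
    return records


def gen_uprooting_trace(
    k0: float,
    x_p: float,
    h0: float,
    drops: Sequence[float] = (),
    noise: NoiseSpec = NoiseSpec(),
    drop_positions: Optional[Sequence[float]] = None,
    n_samples: int = 2000,
    genotype: str = "",
    substrate: str = "clay",
) -> ForceTrace:
    """Piecewise elastic/damage uprooting trace with planted force drops.

    The noiseless baseline rises linearly at stiffness ``k0`` to the peak
    ``k0 * x_p``, then declines at slope ``h0`` to zero at
    ``x_u = x_p * (1 + k0/h0)``; the closed-form energy is
    ``0.5 * k0 * x_p * x_u``.  Drops are instantaneous drop-and-recover
    notches of the stated magnitudes, planted on the loading branch (by
    default evenly spaced over (0.3, 0.9) * x_p) so a peak-to-trough
    detector recovers their magnitudes exactly at zero noise.
    """
    if min(k0, x_p, h0) <= 0:
        raise ValueError("k0, x_p and h0 must be positive")
    x_u = x_p * (1.0 + k0 / h0)
    x = np.union1d(np.linspace(0.0, x_u, n_samples), [x_p])  # keep the peak kink

    def baseline(xx: np.ndarray) -> np.ndarray:
        return np.where(xx <= x_p, k0 * xx, np.maximum(k0 * x_p - h0 * (xx - x_p), 0.0))

    drops = list(drops)
    if drop_positions is None:
        drop_positions = list(np.linspace(0.3 * x_p, 0.9 * x_p, len(drops))) if drops else []
    if len(drop_positions) != len(drops):
        raise ValueError("drops and drop_positions must align")
    delta = x_u / n_samples / 4.0
    extra_x, extra_f = [], []
    keep = np.ones(x.size, dtype=bool)
    for xi, di in zip(drop_positions, drops):
        base = float(baseline(np.array([xi]))[0])
        if di > base:
            raise ValueError(f"drop {di} N exceeds the instantaneous load {base:.3g} N")
        extra_x.extend([xi, xi + delta, xi + 2 * delta])
        extra_f.extend([base, base - di, float(baseline(np.array([xi + 2 * delta]))[0])])
        # regular samples inside the notch would distort its peak-to-trough size
        keep &= (x < xi) | (x > xi + 2 * delta)
    f = baseline(x)
    if extra_x:
        x = np.concatenate([x[keep], extra_x])
        f = np.concatenate([f[keep], extra_f])
        order = np.argsort(x, kind="stable")
        x, f = x[order], f[order]
    if noise.trace_noise_sd > 0:
        f = f + _rng(noise.seed, "traces").normal(0.0, noise.trace_noise_sd, f.size)
    return ForceTrace(displacement=x, load=f, genotype=genotype, substrate=substrate)


def gen_erosion_runs(
    n_boxes: int,
    profile: GenotypeProfile,
    density_levels: Sequence[int] = (9, 16, 32, 49, 81, 100),
    bare_rate: float = 0.3,
    noise: NoiseSpec = NoiseSpec(),
    n_bare: int = 3,
    flow_velocity: float = 1.2,
) -> list[ErosionRun]:
    """Flume runs whose expected relative detachment follows the genotype's
    empirical erosion-reduction model.

    Planted boxes cycle through the experimental density levels; each box's
    RLD is placed proportionally within the genotype's observed RLD range
    and jittered +/-20%.  Interval sediment masses are
    ``bare_rate * ratio * area * duration`` times a mean-one lognormal
    multiplier (sigma = ``noise.erosion_lognorm_sigma``), captured for 5 s
    every 10 s up to 115 s.  ``n_bare`` bare control boxes at RLD 0 are
    appended.
    """
    if n_boxes < 1:
        raise ValueError("n_boxes must be >= 1")
    rng = _rng(noise.seed, "erosion")
    model = profile.erosion_model()
    lo, hi = profile.rld_range
    dmin, dmax = min(density_levels), max(density_levels)
    sigma = noise.erosion_lognorm_sigma
    starts = np.arange(0.0, 111.0, 10.0)
    runs: list[ErosionRun] = []

    def make_run(count: int, rld: float) -> ErosionRun:
        ratio = 1.0 if rld == 0.0 else float(evaluate_empirical(model, rld))
        mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, starts.size)) if sigma > 0 else np.ones(starts.size)
        intervals = tuple(
            (float(s), 5.0, float(bare_rate * ratio * BOX_AREA * 5.0 * m))
            for s, m in zip(starts, mult)
        )
        return ErosionRun(
            genotype=profile.name if count > 0 else "bare",
            plant_count=count,
            intervals=intervals,
            surface_velocity=flow_velocity,
            rld=rld,
        )

    for i in range(n_boxes):
        dens = density_levels[i % len(density_levels)]
        frac = (dens - dmin) / (dmax - dmin) if dmax > dmin else 0.5
        rld = float(np.clip((lo + (hi - lo) * frac) * rng.uniform(0.8, 1.2), lo, hi))
        runs.append(make_run(dens, rld))
    for _ in range(n_bare):
        runs.append(make_run(0, 0.0))
    return runs


def gen_root_population(
    n: int,
    profile: GenotypeProfile,
    substrate: str = "clay",
    noise: NoiseSpec = NoiseSpec(),
    median_dry_mass: float = 5.0,  # mg
    container_volume: float = 3.75e-4,  # m^3
) -> list[RootMassRecord]:
    """Root dry-mass records with genotype/substrate-specific SRL.

    SRL values are normal (truncated positive); dry masses lognormal with
    the stated median.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean, sd = profile.srl[substrate]
    rng = _rng(noise.seed, "roots")
    srl = np.full(n, mean) if sd == 0 else _truncated_normal(rng, mean, sd, n)
    mass = median_dry_mass * np.exp(noise.mass_cv * rng.standard_normal(n))
    return [
        RootMassRecord(dry_mass=float(m), srl=float(s), container_volume=container_volume)
        for m, s in zip(mass, srl)
    ]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    while np.any(out <= 0):  # resample the non-physical tail
        bad = out <= 0
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out
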