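"""Centrifuge root-gel adhesion mechanics.

Seedlings grown on the surface of a gel plate are spun in a hanging-bucket
centrifuge at stepwise-increasing speed settings.  The bucket swings out so
the plate is perpendicular to the rotor plane, and each seedling experiences
a peeling force proportional to its aerial tissue mass:

    Fc = Ms * radius * omega**2

where ``omega = 2*pi/60 * base_rate * sqrt(n)`` for speed setting ``n``
(the rotor speed in RPM is ``base_rate * sqrt(n)``).  The residual bucket
inclination from the vertical is bounded by ``arctan(g / (0.07 * omega**2))``,
small enough (< 1.5 degrees at the slowest setting) that the swing-out
geometry can be treated as exact.

Detachment outcomes across a cohort form right-censored survival data on the
force scale: seedlings still attached after the fastest spin are censored at
the force they survived.  This module builds the Kaplan-Meier detachment
curves and exports analysis-ready event tables; proportional-hazards
regression on those tables is delegated to standard survival tooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


@dataclass(frozen=True)
class SpinProtocol:
    """Centrifuge configuration.

    Parameters
    ----------
    base_rate : float
        Rotor speed at setting 1, revolutions per minute.
    settings : tuple of int
        Ordered speed-setting indices used in the assay; the rotor speed at
        setting ``n`` is ``base_rate * sqrt(n)``.
    attachment_radius : float
        Distance from the rotation axis to the gel surface, metres.
    gravity : float
        Gravitational acceleration, m s^-2.
    bucket_arm : float
        Moment-arm coefficient of the bucket force balance, metres (the
        bucket pivot sits this far from the axis).
    """

    base_rate: float = 720.0
    settings: tuple[int, ...] = (1, 2, 3, 4, 5)
    attachment_radius: float = 0.07
    gravity: float = 9.81
    bucket_arm: float = 0.07

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or self.attachment_radius <= 0:
            raise ValueError("base_rate and attachment_radius must be positive")
        if self.gravity <= 0 or self.bucket_arm <= 0:
            raise ValueError("gravity and bucket_arm must be positive")
        s = self.settings
        if len(s) == 0 or any(int(n) != n or n < 1 for n in s):
            raise ValueError("settings must be positive integers")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("settings must be strictly increasing")

    @property
    def max_setting(self) -> int:
        return self.settings[-1]

    def rpm(self, setting: int) -> float:
        """Rotor speed in RPM at a given setting."""
        _check_setting(setting)
        return self.base_rate * math.sqrt(setting)


@dataclass(frozen=True)
class SeedlingRecord:
    """One centrifuged seedling.

    ``detach_setting`` is the speed index at which the seedling peeled off
    the gel, or ``None`` for seedlings still attached after the fastest spin
    (``censored`` must then be True).
    """

    id: str
    genotype: str
    aerial_mass: float  # kg
    detach_setting: Optional[int] = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.aerial_mass <= 0:
            raise ValueError(f"aerial_mass must be positive (got {self.aerial_mass})")
        if self.censored and self.detach_setting is not None:
            raise ValueError("censored seedlings cannot have a detach_setting")
        if not self.censored and self.detach_setting is None:
            raise ValueError("uncensored seedlings need a detach_setting")


@dataclass(frozen=True)
class DetachmentCurve:
    """Proportion of a cohort still attached as a function of peeling force."""

    force_grid: np.ndarray  # N, increasing, starts at 0
    proportion_attached: np.ndarray  # non-increasing, in [0, 1], starts at 1
    n_censored: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.force_grid, dtype=float)
        p = np.asarray(self.proportion_attached, dtype=float)
        if f.shape != p.shape:
            raise ValueError("force_grid and proportion_attached must align")
        if np.any(np.diff(p) > 1e-12) or np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("proportion_attached must be non-increasing in [0, 1]")


def _check_setting(setting: int) -> None:
    if setting < 1:
        raise ValueError(f"speed setting must be >= 1 (got {setting})")


def angular_velocity(setting: int, protocol: SpinProtocol = SpinProtocol()) -> float:
    """Rotor angular velocity in rad s^-1 at a speed setting."""
    _check_setting(setting)
    return 2.0 * math.pi / 60.0 * protocol.base_rate * math.sqrt(setting)


def bucket_inclination(setting: int, protocol: SpinProtocol = SpinProtocol()) -> float:
    """Upper bound on bucket inclination from perpendicular swing-out, degrees.

    Balancing moments about the bucket pivot gives
    ``tan(theta) < g / (arm * omega**2)``; theta is the largest deviation of
    the plate from perpendicular to the rotor plane.
    """
    omega = angular_velocity(setting, protocol)
    return math.degrees(math.atan(protocol.gravity / (protocol.bucket_arm * omega**2)))


def centrifugal_force(
    record: SeedlingRecord, setting: int, protocol: SpinProtocol = SpinProtocol()
) -> float:
    """Peeling force Fc = Ms * radius * omega**2 in newtons."""
    if record.aerial_mass <= 0:
        raise ValueError("aerial_mass must be positive")
    omega = angular_velocity(setting, protocol)
    return record.aerial_mass * protocol.attachment_radius * omega**2


def relative_centrifugal_force(
    setting: int, protocol: SpinProtocol = SpinProtocol()
) -> float:
    """Centripetal acceleration at the gel surface in multiples of g."""
    omega = angular_velocity(setting, protocol)
    return protocol.attachment_radius * omega**2 / protocol.gravity


def _event_force(rec: SeedlingRecord, protocol: SpinProtocol) -> float:
    setting = protocol.max_setting if rec.censored else rec.detach_setting
    return centrifugal_force(rec, setting, protocol)


def detachment_curve(
    cohort: Sequence[SeedlingRecord], protocol: SpinProtocol = SpinProtocol()
) -> DetachmentCurve:
    """Kaplan-Meier curve of the proportion of seedlings still attached.

    Event forces are seedling-specific (Fc depends on aerial mass); censored
    seedlings are carried to the force of the fastest spin and censored
    there, never counted as detachment events.  Tied event forces drop the
    curve once.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    forces = np.array([_event_force(r, protocol) for r in cohort])
    events = np.array([not r.censored for r in cohort], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(forces, event_observed=events)
    grid = np.concatenate([[0.0], np.unique(forces[events])]) if events.any() else np.array([0.0])
    surv = kmf.survival_function_at_times(grid).to_numpy()
    surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    return DetachmentCurve(
        force_grid=grid,
        proportion_attached=surv,
        n_censored=int((~events).sum()),
    )


def export_event_table(
    cohort: Sequence[SeedlingRecord],
    protocol: SpinProtocol = SpinProtocol(),
    plate_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Analysis-ready event table for external survival regression.

    One row per seedling: the force reached (event force or censoring
    force), an event flag (1 = detached), genotype, and the covariates used
    by proportional-hazards analyses (plate id when known, spin count).
    """
    rows = []
    for i, rec in enumerate(cohort):
        setting = protocol.max_setting if rec.censored else rec.detach_setting
        rows.append(
            {
                "id": rec.id,
                "genotype": rec.genotype,
                "aerial_mass_kg": rec.aerial_mass,
                "setting": setting,
                "force_N": _event_force(rec, protocol),
                "event": 0 if rec.censored else 1,
                "spin_count": setting,
                "plate_id": plate_ids[i] if plate_ids is not None else "",
            }
        )
    return pd.DataFrame(rows)


def read_cohort_csv(path) -> list[SeedlingRecord]:
    """Read a cohort CSV with columns id, genotype, aerial_mass_mg, detach_setting.

    A blank detach_setting marks a censored seedling.  Masses are given in
    mg and converted to kg here.
    """
    df = pd.read_csv(path, dtype={"id": str})
    records = []
    for _, row in df.iterrows():
        raw = row.get("detach_setting")
        censored = pd.isna(raw)
        records.append(
            SeedlingRecord(
                id=str(row["id"]),
                genotype=str(row["genotype"]),
                aerial_mass=float(row["aerial_mass_mg"]) * 1e-6,
                detach_setting=None if censored else int(raw),
                censored=bool(censored),
            )
        )
    return records
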