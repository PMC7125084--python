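"""Uprooting force-trace analysis.

A plant pulled vertically from soil at constant speed produces a
load-displacement trace f(x).  Up to the peak the root-soil system responds
elastically, f(x) = k(x)*x; past the peak accumulated damage makes the force
decline, f(x) = f(x_p) + h(x - x_p)*(x - x_p) with h < 0, reaching zero at
the uprooting displacement x_u.  Peak force and the work done (the area
under the trace up to x_u) are macroscopic summaries of root-soil cohesion;
discrete force drops along the trace mark individual root or bond failures.

Summaries are normalised per metre of root, obtained from dry root mass via
genotype- and substrate-specific specific root length (SRL, m mg^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidTraceError, NoSignalError

#: Load-cell noise floor, N. The cell is accurate above 0.05 N; alternates
#: 0.1 and 0.035 N are accepted wherever a threshold argument appears.
DEFAULT_NOISE_THRESHOLD = 0.05


@dataclass(frozen=True)
class ForceTrace:
    """Displacement (m) / load (N) series from one uprooting pull."""

    displacement: np.ndarray
    load: np.ndarray
    genotype: str = ""
    substrate: str = ""
    pull_speed: float = 0.005  # m min^-1

    def __post_init__(self) -> None:
        x = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "displacement", x)
        object.__setattr__(self, "load", f)
        if x.ndim != 1 or x.shape != f.shape or x.size < 2:
            raise InvalidTraceError("trace needs >= 2 aligned samples")
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(x)):
            raise InvalidTraceError("trace contains non-finite values")
        if np.any(np.diff(x) < 0):
            raise InvalidTraceError("displacement must be non-decreasing")


@dataclass(frozen=True)
class RootMassRecord:
    """Dry root mass with the SRL conversion to root length."""

    dry_mass: float  # mg
    srl: float  # m mg^-1
    container_volume: float = 3.75e-4  # m^3 (375 cm^3 pot)

    def __post_init__(self) -> None:
        if min(self.dry_mass, self.srl, self.container_volume) <= 0:
            raise ValueError("dry_mass, srl and container_volume must be positive")

    @property
    def root_length(self) -> float:
        """Total root length in metres."""
        return self.dry_mass * self.srl


@dataclass(frozen=True)
class UprootSummary:
    peak_force: float  # N
    total_energy: float  # J
    drops: tuple[float, ...]  # N
    rld: float  # km m^-3
    root_length: float  # m
    peak_per_root_length: float  # N m^-1 root
    energy_per_root_length: float  # J m^-1 root


def read_trace_csv(path, genotype: str = "", substrate: str = "") -> ForceTrace:
    """Read one pull from a CSV with columns displacement_mm, load_N."""
    df = pd.read_csv(path)
    return ForceTrace(
        displacement=df["displacement_mm"].to_numpy() * 1e-3,
        load=df["load_N"].to_numpy(),
        genotype=genotype,
        substrate=substrate,
    )


def peak_force(trace: ForceTrace, threshold: float = DEFAULT_NOISE_THRESHOLD) -> float:
    """Maximum load over samples above the noise threshold, N."""
    above = trace.load[trace.load >= threshold]
    if above.size == 0:
        raise NoSignalError(f"no sample reaches the {threshold} N noise threshold")
    return float(above.max())


def _uprooting_index(load: np.ndarray, threshold: float) -> int:
    """Index of the uprooting endpoint: last downward crossing of the threshold."""
    below = load < threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    return int(crossings[-1]) if crossings.size else load.size - 1


def total_energy(trace: ForceTrace, threshold: float = DEFAULT_NOISE_THRESHOLD) -> float:
    """Work done uprooting: trapezoidal area under the trace up to x_u, J.

    x_u is the last sample where the load falls back below the threshold
    (the pull-out); if the load never returns below it, the whole trace is
    integrated.
    """
    end = _uprooting_index(trace.load, threshold)
    return float(np.trapezoid(trace.load[: end + 1], trace.displacement[: end + 1]))


def _smooth(load: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(load).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def detect_force_drops(
    trace: ForceTrace,
    min_drop: float = 0.05,
    smooth_window: Optional[int] = None,
    threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> list[float]:
    """Incremental force drops: declines from a local maximum to the next
    local minimum, in displacement order, keeping only drops >= min_drop.

    The terminal decline is excluded when it ends below the noise threshold:
    that decline is the pull-out itself, not an incremental failure.  An
    optional centred moving-median prefilter (``smooth_window`` samples,
    default off) suppresses sensor jitter.
    """
    f = trace.load if smooth_window is None else _smooth(trace.load, smooth_window)
    # collapse runs of equal values so plateaus yield single extrema
    keep = np.concatenate([[True], np.diff(f) != 0.0])
    comp = f[keep]
    if comp.size < 2:
        return []
    d = np.sign(np.diff(comp))
    drops: list[float] = []
    i = 0
    n = comp.size
    while i < n - 1:
        if d[i] > 0:
            i += 1
            continue
        # d[i] < 0: comp[i] is a local max (or the first sample); find trough
        j = i
        while j < n - 1 and comp[j + 1] < comp[j]:
            j += 1
        is_terminal_pullout = j == n - 1 and comp[j] < threshold
        drop = comp[i] - comp[j]
        if drop >= min_drop and not is_terminal_pullout:
            drops.append(float(drop))
        i = j
    return drops


def root_length_density(rec: RootMassRecord) -> float:
    """RLD in km m^-3: dry mass * SRL / container volume."""
    return rec.root_length / rec.container_volume / 1000.0


def summarize_uproot(
    trace: ForceTrace,
    rec: RootMassRecord,
    min_drop: float = 0.05,
    threshold: float = DEFAULT_NOISE_THRESHOLD,
    smooth_window: Optional[int] = None,
) -> UprootSummary:
    """Aggregate peak, energy and drops, normalised per metre of root."""
    pk = peak_force(trace, threshold)
    en = total_energy(trace, threshold)
    drops = tuple(detect_force_drops(trace, min_drop, smooth_window, threshold))
    length = rec.root_length
    return UprootSummary(
        peak_force=pk,
        total_energy=en,
        drops=drops,
        rld=root_length_density(rec),
        root_length=length,
        peak_per_root_length=pk / length,
        energy_per_root_length=en / length,
    )
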