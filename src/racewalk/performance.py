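"""Performance parameters: step cadence, step-length ratio and smoothness.

Cadence (SC) is the reciprocal of the heel-strike-to-heel-strike interval.
The step-length ratio (SLR) normalizes step length by stature — elite race
walkers trade cadence against relative step length at a given speed.
Smoothness (S) is a dimensionless jerk cost of the anteroposterior
acceleration over one step: the squared jerk integral scaled by step duration
and step length so that the value is invariant to time and length units
(1 = ideally smooth, 10 = worst in the adopted normalization band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .signals import AccelerationTrace

__all__ = [
    "TrialMeta",
    "PerformanceStep",
    "step_cadence",
    "step_length_ratio",
    "smoothness",
    "sequence_performance",
]


@dataclass(frozen=True)
class TrialMeta:
    """Trial-level metadata: mean speed (m/s) and athlete stature (m)."""

    v_mean: float
    h: float
    speed_label_kmh: float | None = None

    def __post_init__(self) -> None:
        if self.v_mean <= 0:
            raise DomainError("mean speed must be positive")
        if not (1.2 <= self.h <= 2.2):
            raise DomainError("stature must lie in [1.2, 2.2] m")


@dataclass(frozen=True)
class PerformanceStep:
    SC: float     # steps/s
    SLR: float    # percent
    S: float      # dimensionless jerk cost


def step_cadence(tmax_i: float, tmax_next: float) -> float:
    """SC = 1 / (tmax_{i+1} − tmax_i), in steps/s."""
    dt = tmax_next - tmax_i
    if dt <= 0:
        raise DomainError("heel-strike interval must be positive")
    return 1.0 / dt


def step_length_ratio(v_mean: float, SC: float, h: float) -> float:
    """SLR = 100 · v / (SC · h): step length as a percentage of stature."""
    if v_mean <= 0 or SC <= 0 or h <= 0:
        raise DomainError("speed, cadence and stature must be positive")
    return 100.0 * v_mean / (SC * h)


def smoothness(
    trace: AccelerationTrace,
    window: tuple[float, float],
    SC: float,
    v_mean: float,
    *,
    length_normalized: bool = True,
) -> float:
    """Dimensionless jerk cost of the AP acceleration over one step.

    S = T⁵ · (SC/v)² · ∫ j²(t) dt over ``window = (tmax_i, tmax_{i+1})``,
    with T the window duration and j the time derivative of ``a_ap`` (central
    differences, one-sided at the edges; trapezoidal integration).  The
    (SC/v)² factor divides by the squared step length, which is what renders
    S dimensionless; ``length_normalized=False`` swaps in the alternative
    1/(SC·v)² scaling for sensitivity analyses.
    """
    lo, hi = window
    if SC <= 0 or v_mean <= 0:
        raise DomainError("cadence and speed must be positive")
    if lo < trace.t[0] - 1e-12 or hi > trace.t[-1] + 1e-12 or hi <= lo:
        raise DomainError("window must lie inside the trace")
    sel = (trace.t >= lo - 1e-12) & (trace.t <= hi + 1e-12)
    t = trace.t[sel]
    a = trace.a_ap[sel]
    if len(t) < 8:
        raise DomainError(f"window too short for jerk estimation: {len(t)} samples")
    j = np.gradient(a, t)
    integral = np.trapezoid(j**2, t)
    T = hi - lo
    scale = (SC / v_mean) ** 2 if length_normalized else 1.0 / (SC * v_mean) ** 2
    return float(T**5 * scale * integral)


def sequence_performance(sc, slr, s, NS: int = 30) -> tuple[float, float, float]:
    """Arithmetic sequence means (SCS, SLRS, SS) over exactly NS step values."""
    arrs = [np.asarray(v, dtype=float) for v in (sc, slr, s)]
    if any(len(a) != NS for a in arrs):
        raise DomainError(f"each per-step series must have exactly NS={NS} values")
    return tuple(float(a.mean()) for a in arrs)
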