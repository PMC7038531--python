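"""Step segmentation and per-step gait-event detection.

Two inertial landmarks drive the whole analysis (see :mod:`racewalk.logc`):

* **MAPA** — the maximum of the anteroposterior acceleration within a step,
  used as the heel-strike proxy; consecutive MAPA instants delimit one step
  and their spacing gives the step cadence.
* **NPVA** — the negative peak (minimum) of the vertical acceleration inside
  the step, the landmark that precedes toe-off by the cadence-dependent
  threshold.

The detector parameters (minimum peak separation, prominence rule) are not
dictated by the physiology alone; the defaults below derive from the valid
elite cadence range of 2.8–4.0 steps/s and are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import NoStepsError
from .signals import AccelerationTrace, InertialConfig

__all__ = [
    "StepEvents",
    "detect_mapa",
    "detect_npva",
    "segment_steps",
    "SC_MIN",
    "SC_MAX",
]

#: valid elite race-walking cadence range (steps/s)
SC_MIN = 2.8
SC_MAX = 4.0

#: default minimum separation between heel-strike peaks (s); 1/4 s = 4 steps/s
MIN_PEAK_SEPARATION = 0.25

#: default peak-height rule: median + IQR_FACTOR * IQR of the AP channel
IQR_FACTOR = 1.0

#: default minimum peak prominence (m/s²); heel-strike transients at the
#: trunk reach several m/s², sensor noise stays well below this
MIN_PROMINENCE = 2.0


@dataclass(frozen=True)
class StepEvents:
    """Per-step event times, with cadence gating applied.

    ``tmax`` has length ``N + 1`` for ``N`` raw steps: step ``i`` spans
    ``[tmax[i], tmax[i+1])`` and contains one vertical minimum ``tmin[i]``.
    ``kept[i]`` is False for steps whose cadence fell outside
    ``[SC_MIN, SC_MAX]``; they are flagged rather than silently dropped.
    """

    tmax: np.ndarray          # MAPA times (s), length N+1
    tmin: np.ndarray          # NPVA times (s), length N
    i_max: np.ndarray         # sample indices of tmax
    i_min: np.ndarray         # sample indices of tmin
    kept: np.ndarray          # bool, length N

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "i_max", "i_min", "kept"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.tmin)
        if len(self.tmax) != n + 1:
            raise NoStepsError("tmax must have one more entry than tmin")
        if np.any(np.diff(self.tmax) <= 0):
            raise NoStepsError("tmax must be strictly increasing")
        if n and not (
            np.all(self.tmax[:-1] < self.tmin) and np.all(self.tmin < self.tmax[1:])
        ):
            raise NoStepsError("interleaving tmax[i] < tmin[i] < tmax[i+1] violated")

    @property
    def n_steps(self) -> int:
        return len(self.tmin)

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.kept))

    def to_frame(self, kept_only: bool = True) -> pd.DataFrame:
        """One row per step: ``step, tmax_s, tmin_s, tmax_next_s``."""
        df = pd.DataFrame(
            {
                "step": np.arange(self.n_steps),
                "tmax_s": self.tmax[:-1],
                "tmin_s": self.tmin,
                "tmax_next_s": self.tmax[1:],
                "kept": self.kept,
            }
        )
        if kept_only:
            df = df[df["kept"]].drop(columns="kept").reset_index(drop=True)
        return df


def detect_mapa(
    trace: AccelerationTrace,
    cfg: InertialConfig,
    *,
    min_separation: float = MIN_PEAK_SEPARATION,
    iqr_factor: float = IQR_FACTOR,
    min_prominence: float = MIN_PROMINENCE,
) -> np.ndarray:
    """Detect heel-strike proxies: local maxima of the AP acceleration.

    The first ``cfg.warmup`` seconds are discarded.  Peaks must be separated
    by at least ``min_separation`` seconds, exceed
    ``median + iqr_factor * IQR`` of the post-warmup AP signal, and have a
    prominence of at least ``min_prominence``.

    Returns the peak times (s).  Raises :class:`NoStepsError` when fewer than
    two peaks are found.
    """
    if not trace.filtered:
        raise NoStepsError("trace must be filtered before event detection")
    start = int(np.searchsorted(trace.t, trace.t[0] + cfg.warmup))
    a = trace.a_ap[start:]
    if len(a) < 3:
        raise NoStepsError("trace shorter than the warmup interval")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    height = med + iqr_factor * (q3 - q1)
    idx, _ = find_peaks(
        a,
        height=height,
        prominence=min_prominence,
        distance=max(1, round(min_separation * trace.f)),
    )
    if len(idx) < 2:
        raise NoStepsError(f"only {len(idx)} anteroposterior peaks found; need at least 2")
    return trace.t[start + idx]


def detect_npva(trace: AccelerationTrace, mapa_times: np.ndarray) -> np.ndarray:
    """Vertical-acceleration minimum strictly inside each MAPA interval.

    Ties (a flat minimum spanning several samples) resolve to the earliest
    sample.  With fewer than two MAPA times there is no interval and the
    result is empty.
    """
    mapa_times = np.asarray(mapa_times, dtype=float)
    if len(mapa_times) < 2:
        return np.empty(0)
    out = np.empty(len(mapa_times) - 1)
    for i, (lo, hi) in enumerate(zip(mapa_times[:-1], mapa_times[1:])):
        sel = np.flatnonzero((trace.t > lo) & (trace.t < hi))
        if len(sel) == 0:
            raise NoStepsError(f"no samples strictly inside step interval {i}")
        out[i] = trace.t[sel[np.argmin(trace.a_vert[sel])]]  # argmin → earliest tie
    return out


def segment_steps(
    trace: AccelerationTrace,
    cfg: InertialConfig,
    *,
    min_separation: float = MIN_PEAK_SEPARATION,
    iqr_factor: float = IQR_FACTOR,
    min_prominence: float = MIN_PROMINENCE,
    sc_range: tuple[float, float] = (SC_MIN, SC_MAX),
) -> StepEvents:
    """Compose the two detectors and gate steps on cadence.

    Steps whose cadence ``1 / (tmax[i+1] − tmax[i])`` falls outside
    ``sc_range`` are flagged (``kept = False``) but retained in the event
    arrays, mirroring step-level (not trial-level) exclusion.
    """
    tmax = detect_mapa(
        trace, cfg,
        min_separation=min_separation,
        iqr_factor=iqr_factor,
        min_prominence=min_prominence,
    )
    tmin = detect_npva(trace, tmax)
    sc = 1.0 / np.diff(tmax)
    kept = (sc >= sc_range[0]) & (sc <= sc_range[1])
    if not kept.any():
        raise NoStepsError("no steps survive cadence gating")
    t_idx = np.searchsorted(trace.t, tmax)
    t_idx = np.clip(t_idx, 0, len(trace.t) - 1)
    n_idx = np.searchsorted(trace.t, tmin)
    n_idx = np.clip(n_idx, 0, len(trace.t) - 1)
    return StepEvents(tmax=tmax, tmin=tmin, i_max=t_idx, i_min=n_idx, kept=kept)
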