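"""Synthetic race-walking trunk accelerations with known ground truth.

The generator emulates the waveform morphology a trunk sensor sees: a
pronounced anteroposterior maximum at each heel strike and a vertical
minimum preceding each toe-off.  Both landmarks are raised-cosine pulses, so
their extrema sit exactly at the prescribed instants.  Crucially, the
vertical minimum is placed at ``TOE − E(SC)`` with the same cadence-dependent
threshold the estimator uses: the inertial timing model is then exactly
invertible and end-to-end recovery tests isolate detector and sampling
quantization error from model error.

Matched 240-fps video annotations are derived by quantizing the true toe-off
and heel-strike instants onto the camera frame grid, guaranteeing that the
benchmark interval brackets the true flight time.

Defaults emulate the study conditions of the elite cohort: 200 Hz sampling,
a 14.0 km/h trial (3.89 m/s) at 3.29 steps/s with 45 ms flight time, stature
1.745 m, and 0.3 m/s² sensor noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .events import StepEvents
from .logc import ThresholdModel, variable_threshold
from .performance import TrialMeta
from .signals import GRAVITY, AccelerationTrace
from .benchmark import VideoStepAnnotation

__all__ = ["SimSpec", "SimResult", "generate_trial", "generate_video_annotations"]


@dataclass(frozen=True)
class SimSpec:
    """Trial recipe: timing profile, waveform shape, noise and rates."""

    duration: float = 70.0          # s
    cadence: float | tuple = 3.29   # steps/s, constant or per-step
    flight_time: float | tuple = 0.045  # s, constant or per-step; 0 = double support
    v_mean: float = 3.89            # m/s (14.0 km/h)
    stature: float = 1.745          # m
    ap_amplitude: float = 8.0       # m/s², heel-strike pulse
    ap_halfwidth: float = 0.025     # s
    vert_amplitude: float = 12.0    # m/s², toe-off-related pulse (subtracted)
    vert_halfwidth: float = 0.030   # s
    noise_sd: float = 0.3           # m/s²
    seed: int = 0
    f: float = 200.0                # Hz
    FR: float = 240.0               # frames/s
    start: float = 0.5              # s, first heel strike

    def to_json(self, path) -> None:
        d = asdict(self)
        d["cadence"] = list(np.atleast_1d(self.cadence).astype(float))
        d["flight_time"] = list(np.atleast_1d(self.flight_time).astype(float))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)


@dataclass(frozen=True)
class SimResult:
    """A generated trial bundled with its ground truth."""

    trace: AccelerationTrace            # raw (noisy, unfiltered)
    events: StepEvents                  # true MAPA/NPVA times
    flight_times: np.ndarray            # true FT per step (s)
    toe_times: np.ndarray               # true TOE per step (s)
    heel_times: np.ndarray              # true HSE times (length n_steps + 1)
    meta: TrialMeta
    spec: SimSpec

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(len(self.flight_times)),
                "heel_s": self.heel_times[:-1],
                "toe_s": self.toe_times,
                "heel_next_s": self.heel_times[1:],
                "flight_time_s": self.flight_times,
            }
        )


def _per_step(value, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if len(arr) == 1:
        arr = np.full(n, arr[0])
    if len(arr) < n:
        raise DomainError(f"{name}: need {n} per-step values, got {len(arr)}")
    return arr[:n]


def _add_pulses(t: np.ndarray, centers: np.ndarray, amp: float, w: float) -> np.ndarray:
    """Sum of raised-cosine pulses amp/2·(1 + cos(π(t−c)/w)) on |t−c| ≤ w."""
    out = np.zeros_like(t)
    f = 1.0 / (t[1] - t[0])
    n_half = int(math.ceil(w * f)) + 1
    for c in centers:
        k = int(round((c - t[0]) * f))
        lo, hi = max(0, k - n_half), min(len(t), k + n_half + 1)
        x = t[lo:hi] - c
        mask = np.abs(x) <= w
        out[lo:hi][mask] += 0.5 * amp * (1.0 + np.cos(np.pi * x[mask] / w))
    return out


def generate_trial(spec: SimSpec, model: ThresholdModel = ThresholdModel()) -> SimResult:
    """Generate one synthetic trial with ground-truth events and flight times.

    Heel strikes follow the cadence profile from ``spec.start``; toe-off of
    step *i* precedes the next heel strike by the flight time, and the
    vertical-minimum pulse is centred at ``TOE − E(SC)``.  Gaussian noise
    (seeded) is added to both channels; the same spec and seed reproduce the
    trial bit for bit.
    """
    if spec.duration <= spec.start:
        raise DomainError("duration must exceed the start offset")
    # heel-strike schedule from the cadence profile
    heels = [spec.start]
    cad = np.atleast_1d(np.asarray(spec.cadence, dtype=float))
    k = 0
    while True:
        sc = cad[min(k, len(cad) - 1)]
        if sc <= 0:
            raise DomainError("cadence must be positive")
        nxt = heels[-1] + 1.0 / sc
        if nxt > spec.duration - 0.05:
            break
        heels.append(nxt)
        k += 1
    heels = np.asarray(heels)
    n = len(heels) - 1
    if n < 2:
        raise DomainError("duration too short for two steps at this cadence")

    ft = _per_step(spec.flight_time, n, "flight_time")
    if np.any(ft < 0):
        raise DomainError("flight time must be non-negative")
    step_time = np.diff(heels)
    if np.any(ft >= step_time):
        raise DomainError("flight time must be shorter than the step time")
    sc_true = 1.0 / step_time
    toe = heels[1:] - ft
    e_true = np.asarray(variable_threshold(sc_true, model))
    vmin_centers = toe - e_true  # NPVA instants

    # pulses must stay inside their own step: NPVA strictly after the
    # previous heel strike, clear of the pulse supports
    margin = spec.vert_halfwidth + spec.ap_halfwidth
    if np.any(vmin_centers - heels[:-1] <= margin):
        raise DomainError(
            "vertical-minimum pulse overlaps the heel-strike pulse; "
            "flight time too close to the step time for this cadence"
        )

    t = np.arange(int(round(spec.duration * spec.f))) / spec.f
    a_ap = _add_pulses(t, heels, spec.ap_amplitude, spec.ap_halfwidth)
    a_vert = GRAVITY - _add_pulses(t, vmin_centers, spec.vert_amplitude, spec.vert_halfwidth)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a_vert = a_vert + rng.normal(0.0, spec.noise_sd, len(t))
        a_ap = a_ap + rng.normal(0.0, spec.noise_sd, len(t))

    trace = AccelerationTrace(t=t, a_vert=a_vert, a_ap=a_ap, f=spec.f)
    events = StepEvents(
        tmax=heels,
        tmin=vmin_centers,
        i_max=np.round(heels * spec.f).astype(int),
        i_min=np.round(vmin_centers * spec.f).astype(int),
        kept=np.ones(n, dtype=bool),
    )
    meta = TrialMeta(v_mean=spec.v_mean, h=spec.stature, speed_label_kmh=spec.v_mean * 3.6)
    return SimResult(
        trace=trace,
        events=events,
        flight_times=ft,
        toe_times=toe,
        heel_times=heels,
        meta=meta,
        spec=spec,
    )


def _floor_frame(x: float, tol: float = 1e-9) -> int:
    r = round(x)
    return int(r) if abs(x - r) <= tol else int(math.floor(x))


def _ceil_frame_exclusive(x: float, tol: float = 1e-9) -> int:
    """Smallest integer strictly greater than x when x is exact."""
    r = round(x)
    return int(r) + 1 if abs(x - r) <= tol else int(math.ceil(x))


def generate_video_annotations(
    toe_times, heel_next_times, flight_times, FR: float = 240.0
) -> list[VideoStepAnnotation]:
    """Frame-quantized annotations consistent with the true events.

    Frame k falls at time k/FR; contact is visible up to toe-off and again
    from heel-strike, so ``FNA = ⌊TOE·FR⌋`` and ``FND = ⌈HSE·FR⌉`` (next
    frame when HSE falls exactly on the grid).  The resulting interval
    ``[(FNC − FNB)/FR, (FND − FNA)/FR]`` always brackets the true flight
    time.  Zero flight yields the no-flight flag.
    """
    if FR <= 0:
        raise DomainError("frame rate must be positive")
    out = []
    for i, (o, h, ftime) in enumerate(zip(toe_times, heel_next_times, flight_times)):
        if ftime <= 0:
            fna = _floor_frame(o * FR)
            out.append(
                VideoStepAnnotation(
                    FNA=fna, FNB=fna + 1, FNC=fna, FND=fna + 1,
                    FR=FR, no_flight=True, step=i,
                )
            )
            continue
        fna = _floor_frame(o * FR)
        fnd = _ceil_frame_exclusive(h * FR)
        if fnd < fna + 2:
            # flight entirely inside one inter-frame gap: no airborne frame
            # exists, so the annotator's best call is FNC = FNB (zero lower
            # bound) with the flight bracketed by two contact frames
            fnd = fna + 2
        out.append(
            VideoStepAnnotation(
                FNA=fna, FNB=fna + 1, FNC=fnd - 1, FND=fnd, FR=FR, step=i
            )
        )
    return out


def annotations_to_frame(annotations: list[VideoStepAnnotation]) -> pd.DataFrame:
    """Annotation CSV layout: ``step,FR,FNA,FNB,FNC,FND,no_flight``."""
    return pd.DataFrame(
        {
            "step": [a.step for a in annotations],
            "FR": [a.FR for a in annotations],
            "FNA": [a.FNA for a in annotations],
            "FNB": [a.FNB for a in annotations],
            "FNC": [a.FNC for a in annotations],
            "FND": [a.FND for a in annotations],
            "no_flight": [a.no_flight for a in annotations],
        }
    )
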