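"""Loss-of-ground-contact (LOGC) timing from trunk-acceleration events.

The flight phase of a race-walking step runs from toe-off (TOE) to the next
heel-strike (HSE).  A trunk sensor observes neither event directly; instead,
the vertical-acceleration minimum (NPVA) precedes TOE by a duration *E*, and
the anteroposterior maximum (MAPA) marks HSE.  The per-step LOGC timing is
therefore

    LOGCT_i = tmax_{i+1} − tmin_i − E_i

where the threshold *E* depends on step cadence SC through a two-parameter
quadratic with no intercept,

    E(SC) = SC²/a + SC/b,      a = −40.921,  b = 11.242,

fitted to optimal-threshold data from elite athletes over the valid cadence
range 2.8–4.0 steps/s.  *E* decreases with cadence and crosses zero at
SC = −a/b ≈ 3.64 steps/s; negative values are clamped to zero (a threshold is
a non-negative duration).  ``LOGCT ≤ 0`` means no flight occurred (double
support).

Each detected event carries one sample of timing uncertainty, so the step
bounds are ``LOGCT ± 2/f``.  Judging operates on sequences of ``NS`` steps
(the judge's field of view): sequence values are plain arithmetic means over
consecutive non-overlapping windows of exactly ``NS`` steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, FitError, InsufficientStepsError
from .events import SC_MAX, SC_MIN, StepEvents
from .signals import InertialConfig

__all__ = [
    "ThresholdModel",
    "ThresholdFitResult",
    "LOGCStep",
    "SequenceMetrics",
    "variable_threshold",
    "logc_timing",
    "aggregate_sequences",
    "fit_threshold_model",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Cadence-dependent threshold E(SC) = SC²/a + SC/b, clamped at zero."""

    a: float = -40.921
    b: float = 11.242
    sc_range: tuple[float, float] = (SC_MIN, SC_MAX)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"a": self.a, "b": self.b, "sc_range": list(self.sc_range)}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThresholdModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(a=d["a"], b=d["b"], sc_range=tuple(d.get("sc_range", (SC_MIN, SC_MAX))))


def variable_threshold(SC, model: ThresholdModel = ThresholdModel()) -> np.ndarray | float:
    """Evaluate the threshold E at cadence ``SC`` (steps/s).

    Cadences outside the model's valid range are clamped to the range
    endpoints with a warning; a negative raw threshold (cadence above the
    zero crossing −a/b) is clamped to 0.  ``SC ≤ 0`` is a domain error.
    """
    sc = np.asarray(SC, dtype=float)
    scalar = sc.ndim == 0
    sc = np.atleast_1d(sc)
    if np.any(sc <= 0):
        raise DomainError("step cadence must be positive")
    lo, hi = model.sc_range
    if np.any((sc < lo) | (sc > hi)):
        warnings.warn(
            f"cadence outside valid range [{lo}, {hi}] steps/s; clamping", stacklevel=2
        )
        sc = np.clip(sc, lo, hi)
    e = np.maximum(sc**2 / model.a + sc / model.b, 0.0)
    return float(e[0]) if scalar else e


@dataclass(frozen=True)
class LOGCStep:
    """Per-step LOGC timing with one-sample-per-event uncertainty bounds."""

    step: int
    SC: float
    E: float
    LOGCT: float
    LOGCT_min: float
    LOGCT_max: float

    @property
    def double_support(self) -> bool:
        """True when no flight occurred (``LOGCT ≤ 0``)."""
        return self.LOGCT <= 0.0


@dataclass(frozen=True)
class SequenceMetrics:
    """Aggregates over one judged sequence of NS steps.

    Timing fields are filled by :func:`aggregate_sequences`; classification
    (``LOGCC_S``, labels, ``eta``) and performance fields (``SCS``, ``SLRS``,
    ``SS``) are attached by the downstream modules.
    """

    sequence: int
    LOGCT_S: float
    LOGCT_S_min: float
    LOGCT_S_max: float
    LOGCC_S: float | None = None
    SCS: float | None = None
    SLRS: float | None = None
    SS: float | None = None
    eta: float | None = None
    label_binary: str | None = None
    label_threelevel: str | None = None
    steps: tuple[LOGCStep, ...] = field(default=(), repr=False)


def logc_timing(
    events: StepEvents,
    model: ThresholdModel = ThresholdModel(),
    cfg: InertialConfig = InertialConfig(),
) -> list[LOGCStep]:
    """Per-step LOGC timing for the cadence-gated steps of ``events``.

    ``LOGCT_i = tmax_{i+1} − tmin_i − E(SC_i)`` with bounds ``LOGCT ± 2/f``
    (one sample of uncertainty on each of the two detected events).
    """
    out: list[LOGCStep] = []
    half_band = 2.0 / cfg.f
    for i in range(events.n_steps):
        if not events.kept[i]:
            continue
        sc = 1.0 / (events.tmax[i + 1] - events.tmax[i])
        e = variable_threshold(sc, model)
        logct = events.tmax[i + 1] - events.tmin[i] - e
        out.append(
            LOGCStep(
                step=i,
                SC=float(sc),
                E=float(e),
                LOGCT=float(logct),
                LOGCT_min=float(logct - half_band),
                LOGCT_max=float(logct + half_band),
            )
        )
    return out


def steps_to_frame(steps: list[LOGCStep]) -> pd.DataFrame:
    """Per-step export: ``step,SC,E_s,LOGCT_s,LOGCT_min_s,LOGCT_max_s,double_support``."""
    return pd.DataFrame(
        {
            "step": [s.step for s in steps],
            "SC": [s.SC for s in steps],
            "E_s": [s.E for s in steps],
            "LOGCT_s": [s.LOGCT for s in steps],
            "LOGCT_min_s": [s.LOGCT_min for s in steps],
            "LOGCT_max_s": [s.LOGCT_max for s in steps],
            "double_support": [s.double_support for s in steps],
        }
    )


def aggregate_sequences(
    steps: list[LOGCStep], cfg: InertialConfig = InertialConfig()
) -> list[SequenceMetrics]:
    """Mean LOGC timing over consecutive non-overlapping NS-step windows.

    The trailing remainder (fewer than NS steps) is dropped with a warning.
    Double-support steps contribute their actual (≤ 0) timing to the mean —
    the sequence mean is a plain arithmetic mean, unweighted and uncensored.
    """
    ns = cfg.NS
    if len(steps) < ns:
        raise InsufficientStepsError(f"need at least NS={ns} steps, got {len(steps)}")
    n_seq = len(steps) // ns
    if len(steps) % ns:
        warnings.warn(f"dropping trailing {len(steps) % ns} steps (< NS)", stacklevel=2)
    out = []
    for s in range(n_seq):
        window = steps[s * ns : (s + 1) * ns]
        out.append(
            SequenceMetrics(
                sequence=s,
                LOGCT_S=float(np.mean([w.LOGCT for w in window])),
                LOGCT_S_min=float(np.mean([w.LOGCT_min for w in window])),
                LOGCT_S_max=float(np.mean([w.LOGCT_max for w in window])),
                steps=tuple(window),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Threshold-model refitting from optimal-threshold (OT) data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdFitResult:
    """Outcome of refitting E(SC) from per-step optimal thresholds."""

    a: float
    b: float
    r_squared: float                    # percent, ordinary least squares
    r_squared_robust: float             # percent, least-absolute-residual fit
    a_robust: float
    b_robust: float
    residuals: np.ndarray
    included: np.ndarray                # indices into the input arrays
    excluded: pd.DataFrame              # columns: index, reason, SC, OT
    OT: np.ndarray
    SC: np.ndarray

    def model(self, robust: bool = False) -> ThresholdModel:
        if robust:
            return ThresholdModel(a=self.a_robust, b=self.b_robust)
        return ThresholdModel(a=self.a, b=self.b)


def _basis(sc: np.ndarray) -> np.ndarray:
    return np.column_stack([sc**2, sc])


def _r2_percent(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - yhat) ** 2))
    if sst == 0:
        return 100.0 if ssr == 0 else 0.0
    return float(np.clip(100.0 * (1.0 - ssr / sst), 0.0, 100.0))


def fit_threshold_model(
    OT, SC, *, sc_range: tuple[float, float] = (SC_MIN, SC_MAX), max_iter: int = 20
) -> ThresholdFitResult:
    """Refit the no-intercept quadratic ``OT = SC²/a + SC/b`` from data.

    The optimal threshold OT of a step is the *E* value that makes the
    inertial timing match the benchmark exactly.  Point exclusions mirror the
    original calibration: (i) cadence outside ``sc_range``; (ii) ``OT < 0``
    (toe-off cannot precede the vertical minimum); (iii) outside the 99%
    prediction bounds of the fitted model, applied iteratively until the
    included set is stable.  Both an ordinary least-squares fit and a
    least-absolute-residual (median regression) fit are reported.
    """
    ot = np.asarray(OT, dtype=float)
    sc = np.asarray(SC, dtype=float)
    if ot.shape != sc.shape or ot.ndim != 1:
        raise DomainError("OT and SC must be 1-D arrays of equal length")

    reasons = np.full(len(ot), "", dtype=object)
    reasons[(sc < sc_range[0]) | (sc > sc_range[1])] = "cadence-range"
    neg = (ot < 0) & (reasons == "")
    reasons[neg] = "negative-OT"
    include = reasons == ""
    if np.count_nonzero(include) < 10:
        raise FitError("fewer than 10 points remain after cadence/negative-OT exclusions")
    if np.ptp(sc[include]) == 0:
        raise FitError("degenerate design: all cadences equal")

    # iterate the 99%-prediction-bounds exclusion until the set stabilizes
    for _ in range(max_iter):
        x, y = _basis(sc[include]), ot[include]
        res = sm.OLS(y, x).fit()
        pred = res.get_prediction(_basis(sc))
        band = pred.conf_int(obs=True, alpha=0.01)
        outside = (ot < band[:, 0]) | (ot > band[:, 1])
        new_out = outside & include
        if not new_out.any():
            break
        reasons[new_out] = "99%-bounds"
        include = include & ~outside
        if np.count_nonzero(include) < 3:
            raise FitError("99%-bounds exclusion removed nearly all points")

    x, y = _basis(sc[include]), ot[include]
    ols = sm.OLS(y, x).fit()
    c1, c2 = ols.params
    if c1 == 0 or c2 == 0:
        raise FitError("fitted coefficient is zero; cannot invert to (a, b)")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg convergence chatter on clean data
        lad = sm.QuantReg(y, x).fit(q=0.5)
    d1, d2 = lad.params
    if d1 == 0 or d2 == 0:
        d1, d2 = c1, c2

    fitted = x @ ols.params
    excluded = pd.DataFrame(
        {
            "index": np.flatnonzero(~include),
            "reason": reasons[~include],
            "SC": sc[~include],
            "OT": ot[~include],
        }
    )
    return ThresholdFitResult(
        a=float(1.0 / c1),
        b=float(1.0 / c2),
        r_squared=_r2_percent(y, fitted),
        r_squared_robust=_r2_percent(y, x @ lad.params),
        a_robust=float(1.0 / d1),
        b_robust=float(1.0 / d2),
        residuals=y - fitted,
        included=np.flatnonzero(include),
        excluded=excluded,
        OT=ot,
        SC=sc,
    )
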