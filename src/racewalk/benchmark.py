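"""High-speed-camera benchmark and inertial-vs-benchmark agreement statistics.

A 240-fps camera provides the reference flight time for each step via four
frame numbers: FNA (last frame with ground contact of the trailing foot),
FNB = FNA + 1, FNC (last airborne frame before the leading foot lands) and
FND = FNC + 1.  Frame quantization makes the reference an interval of width
exactly 2/FR; the central benchmark value is the interval midpoint.

Agreement is measured at three levels: binary/three-level confusion
statistics (positive class = "legal"), a precision–recall construction with
its AUC, and a fuzzy comparison where the acceptable-classification fraction
τ counts steps whose membership difference |η − λ| stays below one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import StepLabel, fuzzy_membership
from .errors import DomainError, InputError

__all__ = [
    "VideoStepAnnotation",
    "BenchmarkStep",
    "benchmark_timing",
    "benchmark_membership",
    "fuzzy_agreement",
    "agreement_stats",
    "pr_auc",
    "detection_comparison",
    "effect_sizes",
    "EffectSize",
    "load_annotations",
]


@dataclass(frozen=True)
class VideoStepAnnotation:
    """Four frame numbers bounding toe-off and heel-strike for one step."""

    FNA: int
    FNB: int
    FNC: int
    FND: int
    FR: float = 240.0
    no_flight: bool = False
    step: int | None = None

    def __post_init__(self) -> None:
        if self.FR <= 0:
            raise InputError("frame rate must be positive")
        if self.no_flight:
            return
        tag = f"step {self.step}" if self.step is not None else "annotation"
        if self.FNB != self.FNA + 1:
            raise InputError(f"{tag}: FNB must equal FNA + 1")
        if self.FND != self.FNC + 1:
            raise InputError(f"{tag}: FND must equal FNC + 1")
        if self.FNC < self.FNB:
            raise InputError(f"{tag}: FNC must be >= FNB when flight exists")


@dataclass(frozen=True)
class BenchmarkStep:
    """Camera-based flight time with its frame-quantization interval."""

    LOGCB: float
    LOGCB_min: float
    LOGCB_max: float
    step: int | None = None

    @property
    def no_flight(self) -> bool:
        return self.LOGCB <= 0.0


def load_annotations(path) -> list[VideoStepAnnotation]:
    """Read the annotation CSV: ``step,FR,FNA,FNB,FNC,FND,no_flight``."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"{path}: {exc}") from exc
    if df.empty:
        raise InputError(f"{path}: no annotations")
    required = {"FNA", "FNB", "FNC", "FND"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for i, row in df.iterrows():
        out.append(
            VideoStepAnnotation(
                FNA=int(row["FNA"]),
                FNB=int(row["FNB"]),
                FNC=int(row["FNC"]),
                FND=int(row["FND"]),
                FR=float(row.get("FR", 240.0)),
                no_flight=bool(row.get("no_flight", False)),
                step=int(row["step"]) if "step" in df.columns else int(i),
            )
        )
    return out


def benchmark_timing(
    annotations: list[VideoStepAnnotation], NS: int = 30
) -> tuple[list[BenchmarkStep], pd.DataFrame]:
    """Per-step benchmark intervals and NS-window sequence means.

    ``LOGCB_max = (FND − FNA)/FR`` brackets the flight from outside,
    ``LOGCB_min = (FNC − FNB)/FR`` from inside; the central value is their
    midpoint.  No-flight steps contribute zeros.  Sequence means follow the
    same consecutive non-overlapping NS-step windows as the inertial side
    (trailing remainder dropped).
    """
    steps = []
    for ann in annotations:
        if ann.no_flight:
            steps.append(BenchmarkStep(0.0, 0.0, 0.0, step=ann.step))
            continue
        hi = (ann.FND - ann.FNA) / ann.FR
        lo = (ann.FNC - ann.FNB) / ann.FR
        steps.append(BenchmarkStep(0.5 * (lo + hi), lo, hi, step=ann.step))
    n_seq = len(steps) // NS
    rows = []
    for s in range(n_seq):
        w = steps[s * NS : (s + 1) * NS]
        rows.append(
            {
                "sequence": s,
                "LOGCB_S": float(np.mean([b.LOGCB for b in w])),
                "LOGCB_S_min": float(np.mean([b.LOGCB_min for b in w])),
                "LOGCB_S_max": float(np.mean([b.LOGCB_max for b in w])),
            }
        )
    return steps, pd.DataFrame(rows)


def benchmark_membership(logcb, LHE: float = 0.040, f: float = 200.0):
    """Fuzzy membership λ of the benchmark timing.

    Same trapezoidal form and the same ``2/f`` band as the inertial η (the
    band uses the inertial sample frequency so that η and λ share a scale).
    """
    return fuzzy_membership(logcb, LHE, f)


def fuzzy_agreement(eta, lam) -> tuple[np.ndarray, int, int, float]:
    """σ = η − λ per item; acceptable iff −0.5 < σ < 0.5; τ = AC/(AC+WC).

    The boundary |σ| = 0.5 counts as a wrong classification.
    Returns ``(sigma, AC, WC, tau)``.
    """
    e = np.asarray(eta, dtype=float)
    l = np.asarray(lam, dtype=float)
    if e.shape != l.shape:
        raise DomainError("membership lists must have equal length")
    sigma = e - l
    ac = int(np.count_nonzero(np.abs(sigma) < 0.5))
    wc = len(sigma) - ac
    return sigma, ac, wc, ac / len(sigma) if len(sigma) else float("nan")


def _rate(num: int, den: int) -> float:
    return num / den if den else float("nan")


def agreement_stats(pred, truth, mode: str = "binary") -> dict:
    """Confusion statistics of predicted vs benchmark labels.

    The positive class is "legal" (the overwhelmingly common call): the false
    alarm rate is the probability of calling a truly legal step illegal, and
    the miss alarm rate the probability of calling a truly illegal step
    legal — so false alarm = 1 − TPR and miss alarm = FPR.  Rates over an
    empty truth class are reported as NaN, never zero.  In ``three_level``
    mode per-class TPR and PPV are returned together with the accuracy and
    the 3×3 confusion matrix.
    """
    pred = [StepLabel(p) for p in pred]
    truth = [StepLabel(t) for t in truth]
    if len(pred) != len(truth):
        raise DomainError("pred and truth must have equal length")
    if not pred:
        raise DomainError("empty label lists")

    if mode == "binary":
        classes = [StepLabel.LEGAL, StepLabel.ILLEGAL]
    elif mode == "three_level":
        classes = [StepLabel.LEGAL, StepLabel.DOUBT, StepLabel.ILLEGAL]
    else:
        raise DomainError(f"unknown mode: {mode}")
    if any(l not in classes for l in pred + truth):
        raise DomainError(f"labels do not match mode {mode!r}")

    k = len(classes)
    cm = np.zeros((k, k), dtype=int)  # rows: truth, cols: pred
    ci = {c: i for i, c in enumerate(classes)}
    for p, t in zip(pred, truth):
        cm[ci[t], ci[p]] += 1
    accuracy = float(np.trace(cm)) / len(pred)

    report: dict = {"confusion_matrix": cm, "classes": [c.value for c in classes],
                    "accuracy": accuracy, "n": len(pred)}
    if mode == "binary":
        il, ii = ci[StepLabel.LEGAL], ci[StepLabel.ILLEGAL]
        n_legal, n_illegal = int(cm[il].sum()), int(cm[ii].sum())
        report.update(
            TPR=_rate(int(cm[il, il]), n_legal),
            FPR=_rate(int(cm[ii, il]), n_illegal),
            false_alarm=_rate(int(cm[il, ii]), n_legal),
            miss_alarm=_rate(int(cm[ii, il]), n_illegal),
        )
        # distance of the (FPR, TPR) point to the ideal classifier (0, 1)
        if np.isfinite(report["TPR"]) and np.isfinite(report["FPR"]):
            report["roc_distance"] = float(
                np.hypot(report["FPR"], 1.0 - report["TPR"])
            )
    else:
        per_class = {}
        for c in classes:
            i = ci[c]
            per_class[c.value] = {
                "TPR": _rate(int(cm[i, i]), int(cm[i].sum())),
                "PPV": _rate(int(cm[i, i]), int(cm[:, i].sum())),
            }
        report["per_class"] = per_class
    return report


def pr_auc(points) -> float:
    """Area under a precision–recall curve by trapezoidal integration.

    ``points`` are (recall, precision) pairs; the anchor (0, 1) is prepended,
    points are sorted by ascending recall (ties broken by descending
    precision) and the trapezoid rule integrates precision over recall.
    """
    pts = [(float(r), float(p)) for r, p in points]
    for r, p in pts:
        if not (0.0 <= r <= 1.0 and 0.0 <= p <= 1.0):
            raise DomainError(f"recall/precision outside [0, 1]: ({r}, {p})")
    pts.append((0.0, 1.0))
    pts.sort(key=lambda rp: (rp[0], -rp[1]))
    r = np.array([p[0] for p in pts])
    p = np.array([p[1] for p in pts])
    return float(np.trapezoid(p, r))


def detection_comparison(
    inertial_logct, benchmark_logcb
) -> dict:
    """Flight-event detection agreement and paired timing differences.

    An inertial flight event is declared when ``LOGCT > 0``, a benchmark
    event when ``LOGCB > 0``.  Returns agreement counts (including false and
    missed flight detections) and the paired differences
    (inertial − benchmark) as mean ± SD over all paired steps.
    """
    est = np.asarray(inertial_logct, dtype=float)
    ref = np.asarray(benchmark_logcb, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise DomainError("paired step lists must be 1-D and of equal length")
    ev_i, ev_b = est > 0, ref > 0
    diff = est - ref
    return {
        "n": len(est),
        "events_inertial": int(ev_i.sum()),
        "events_benchmark": int(ev_b.sum()),
        "agreements": int(np.count_nonzero(ev_i == ev_b)),
        "false_logc": int(np.count_nonzero(ev_i & ~ev_b)),
        "missed_logc": int(np.count_nonzero(~ev_i & ev_b)),
        "detection_rate": float(np.count_nonzero(ev_i == ev_b)) / len(est),
        "MD_mean": float(diff.mean()),
        "MD_sd": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# Effect sizes and index weights
# ---------------------------------------------------------------------------

#: qualitative effect-size scale for highly trained participants
_ES_SCALE = ((0.25, "trivial"), (0.5, "small"), (1.0, "moderate"))


@dataclass(frozen=True)
class EffectSize:
    name: str
    g: float
    label: str


@dataclass(frozen=True)
class EffectSizeReport:
    effects: tuple[EffectSize, ...]
    kappa: dict[str, float] = field(default_factory=dict)


def hedges_g(x, y) -> float:
    """Bias-corrected standardized mean difference between two groups.

    g = J · (mean(x) − mean(y)) / s_pooled with the small-sample correction
    J = 1 − 3 / (4(n₁ + n₂) − 9).  A zero pooled SD yields NaN (undefined),
    reported explicitly rather than as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs at least 2 values")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if x.mean() == y.mean() else float("nan")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (x.mean() - y.mean()) / np.sqrt(sp2))


def es_label(g: float) -> str:
    if not np.isfinite(g):
        return "undefined"
    mag = abs(g)
    for cut, name in _ES_SCALE:
        if (name == "trivial" and mag <= cut) or (name != "trivial" and mag < cut):
            return name
    return "large"


def effect_sizes(groups_m: dict, groups_n: dict) -> EffectSizeReport:
    """Hedges' g per index between two speed groups, plus κ weights.

    ``groups_m`` and ``groups_n`` map index names to per-sequence value
    arrays for the minimum- and maximum-speed groups.  κ_i = |H_i| / Σ|H_i|
    so that the weights are non-negative and sum to 1 when all g are defined.
    """
    if set(groups_m) != set(groups_n):
        raise DomainError("the two groups must cover the same indices")
    effects = tuple(
        EffectSize(name=k, g=(g := hedges_g(groups_m[k], groups_n[k])), label=es_label(g))
        for k in groups_m
    )
    mags = {e.name: abs(e.g) for e in effects}
    total = sum(v for v in mags.values() if np.isfinite(v))
    kappa = {}
    if total > 0 and all(np.isfinite(v) for v in mags.values()):
        kappa = {k: v / total for k, v in mags.items()}
    return EffectSizeReport(effects=effects, kappa=kappa)
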