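"""Normalized biomechanical indices and the radar-chart synthesis.

Five indices on [0, 1] (0 best, 1 worst) summarize one judged step sequence:

* δ — normalized sequence LOGC timing (ramp from invisibility to certainty),
* α — infringement fraction (already on [0, 1]),
* γ — cadence shortfall relative to elite-competition correlations,
* ρ — step-length-ratio shortfall, likewise,
* μ — smoothness on the [1, 10] normalization band.

The γ/ρ anchors come from linear speed correlations observed in elite
competition: the "sufficient" anchor (index = 0.4) is the correlation
evaluated at the qualifying-standard speed vE, the "optimal" anchor
(index = 0) at the world-record speed vR.  On the radar chart each axis plots
``1 − index`` so a wider pentagon means a better gesture; the synthetic score
ε is the polygon area divided by the area of the regular unit pentagon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError
from .logc import SequenceMetrics
from .signals import InertialConfig

__all__ = [
    "CalibrationConstants",
    "IndexProfile",
    "calibrate_boundaries",
    "compute_indices",
    "radar_epsilon",
    "plot_radar",
    "best_admissible",
    "AXIS_ORDER",
]

#: fixed radar axis order: infringement axes (α, δ) grouped on the right,
#: performance axes (μ, ρ, γ) on the left
AXIS_ORDER = ("alpha", "delta", "mu", "rho", "gamma")

#: area of the regular pentagon with unit circumradius
A_MAX = 2.5 * np.sin(2.0 * np.pi / 5.0)

#: elite-competition correlations: cadence vs speed (v in m/s) and
#: step-length ratio vs speed (v in km/h)
_SC_SLOPE, _SC_INTERCEPT = 0.259, 2.253
_SLR_SLOPE, _SLR_INTERCEPT = 2.47, 32.73


@dataclass(frozen=True)
class CalibrationConstants:
    """Anchors for the γ and ρ normalizations, plus the smoothness band.

    Defaults are the published anchor values; :func:`calibrate_boundaries`
    recomputes them from the two reference speeds (the published anchors and
    the published vR disagree slightly — see docs/methods.md).
    """

    sc_at_04: float = 3.130   # cadence mapped to γ = 0.4 (steps/s)
    sc_at_0: float = 3.380    # cadence mapped to γ = 0 (steps/s)
    slr_at_04: float = 62.8   # SLR mapped to ρ = 0.4 (%)
    slr_at_0: float = 71.4    # SLR mapped to ρ = 0 (%)
    s_min: float = 1.0
    s_max: float = 10.0

    def __post_init__(self) -> None:
        if not (self.sc_at_04 < self.sc_at_0 and self.slr_at_04 < self.slr_at_0):
            raise DomainError("the index-0.4 anchor must lie below the index-0 anchor")
        if not self.s_min < self.s_max:
            raise DomainError("s_min must be below s_max")


def calibrate_boundaries(
    vE_kmh: float = 12.20,
    vR_kmh: float = 15.76,
    vE_ms: float | None = 3.39,
    vR_ms: float | None = 4.38,
) -> CalibrationConstants:
    """Anchors from the two reference speeds via the elite correlations.

    The cadence correlation takes the speed in m/s and the SLR correlation in
    km/h.  Explicit m/s values may be given (the published rounded figures);
    otherwise they are derived as ``v_kmh / 3.6``.
    """
    if vE_kmh <= 0 or vR_kmh <= 0:
        raise DomainError("reference speeds must be positive")
    ve_ms = vE_ms if vE_ms is not None else vE_kmh / 3.6
    vr_ms = vR_ms if vR_ms is not None else vR_kmh / 3.6
    return CalibrationConstants(
        sc_at_04=_SC_SLOPE * ve_ms + _SC_INTERCEPT,
        sc_at_0=_SC_SLOPE * vr_ms + _SC_INTERCEPT,
        slr_at_04=_SLR_SLOPE * vE_kmh + _SLR_INTERCEPT,
        slr_at_0=_SLR_SLOPE * vR_kmh + _SLR_INTERCEPT,
    )


@dataclass(frozen=True)
class IndexProfile:
    """The five indices, the radar score ε, and the axis order used for ε."""

    delta: float
    alpha: float
    gamma: float
    rho: float
    mu: float
    epsilon: float | None = None
    axis_order: tuple[str, ...] = AXIS_ORDER
    sequence: int | None = None

    def __post_init__(self) -> None:
        for name in ("delta", "alpha", "gamma", "rho", "mu"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"index {name}={v} outside [0, 1]")

    def values(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.axis_order}

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("delta", "alpha", "gamma", "rho", "mu", "epsilon")}
        d["axis_order"] = list(self.axis_order)
        return d


def delta_index(logct_s: float, LHE: float = 0.040, f: float = 200.0) -> float:
    """δ ramp through (LHE − 2/f, 0), (LHE, 0.4) and (LHE + 3/f, 1).

    The three published anchor points are collinear with slope f/5, so a
    single clamped line realizes the whole piecewise definition.
    """
    return float(np.clip((logct_s - (LHE - 2.0 / f)) * f / 5.0, 0.0, 1.0))


def _shortfall(value: float, at_04: float, at_0: float) -> float:
    # linear through (at_04, 0.4) and (at_0, 0); the published γ = 1 cutoff
    # (−1.5·at_0 + 2.5·at_04) is exactly where this line reaches 1
    return float(np.clip(0.4 - 0.4 * (value - at_04) / (at_0 - at_04), 0.0, 1.0))


def compute_indices(
    seq: SequenceMetrics,
    calib: CalibrationConstants = CalibrationConstants(),
    cfg: InertialConfig = InertialConfig(),
) -> IndexProfile:
    """Normalize one sequence's metrics into an :class:`IndexProfile` (no ε)."""
    for name in ("LOGCC_S", "SCS", "SLRS", "SS"):
        if getattr(seq, name) is None:
            raise DomainError(f"sequence metrics incomplete: {name} missing")
    return IndexProfile(
        delta=delta_index(seq.LOGCT_S, cfg.LHE, cfg.f),
        alpha=float(seq.LOGCC_S),
        gamma=_shortfall(seq.SCS, calib.sc_at_04, calib.sc_at_0),
        rho=_shortfall(seq.SLRS, calib.slr_at_04, calib.slr_at_0),
        mu=float(np.clip((seq.SS - calib.s_min) / (calib.s_max - calib.s_min), 0.0, 1.0)),
        sequence=seq.sequence,
    )


def radar_epsilon(profile: IndexProfile) -> tuple[IndexProfile, np.ndarray]:
    """Radar polygon area ratio ε and the polygon vertices.

    Axis k (in ``profile.axis_order``) points at angle 90° + k·72° and plots
    the radius ``1 − index``; the pentagon area A follows from the shoelace
    formula and ε = A / A_max with A_max the regular unit pentagon's area.
    Returns the profile with ε attached, plus the (5, 2) vertex array.
    """
    radii = np.array([1.0 - v for v in profile.values().values()])
    angles = np.pi / 2.0 + 2.0 * np.pi / 5.0 * np.arange(5)
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return replace(profile, epsilon=float(area / A_MAX)), verts


def plot_radar(profiles, path, labels=None) -> None:
    """Render one or more index profiles as a radar chart (SVG-friendly).

    Each axis plots ``1 − index`` at angles 90° + k·72° in the profile's
    axis order; the filled polygon area over the unit pentagon is ε.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(profiles, IndexProfile):
        profiles = [profiles]
    fig, ax = plt.subplots(figsize=(5, 5))
    angles = np.pi / 2.0 + 2.0 * np.pi / 5.0 * np.arange(5)
    ring = np.append(angles, angles[0])
    ax.plot(np.cos(ring), np.sin(ring), color="0.6", lw=0.8)
    for k, name in enumerate(AXIS_ORDER):
        ax.plot([0, np.cos(angles[k])], [0, np.sin(angles[k])], color="0.8", lw=0.6)
        greek = {"alpha": "α", "delta": "δ", "mu": "μ", "rho": "ρ", "gamma": "γ"}[name]
        ax.annotate(greek, (1.12 * np.cos(angles[k]), 1.12 * np.sin(angles[k])),
                    ha="center", va="center")
    for i, prof in enumerate(profiles):
        prof, verts = radar_epsilon(prof) if prof.epsilon is None else (prof, None)
        if verts is None:
            _, verts = radar_epsilon(prof)
        closed = np.vstack([verts, verts[:1]])
        lab = labels[i] if labels else f"ε = {prof.epsilon:.2f}"
        ax.fill(closed[:, 0], closed[:, 1], alpha=0.25)
        ax.plot(closed[:, 0], closed[:, 1], lw=1.2, label=lab)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="lower right", frameon=False, fontsize=8)
    fig.savefig(path, format="svg" if str(path).endswith(".svg") else None,
                bbox_inches="tight")
    plt.close(fig)


def best_admissible(
    profiles: list[IndexProfile], *, delta_max: float = 0.4, alpha_max: float = 0.4
) -> IndexProfile | None:
    """ε_opt: the largest ε among profiles with δ ≤ 0.4 and α ≤ 0.4.

    Profiles lacking ε get it computed on the fly.  Returns ``None`` when no
    profile satisfies the admissibility constraints.
    """
    if not profiles:
        raise DomainError("profile list is empty")
    best: IndexProfile | None = None
    for p in profiles:
        if p.delta > delta_max or p.alpha > alpha_max:
            continue
        if p.epsilon is None:
            p, _ = radar_epsilon(p)
        if best is None or p.epsilon > best.epsilon:
            best = p
    return best
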