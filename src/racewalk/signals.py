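"""Acceleration trace model, CSV ingestion and zero-phase low-pass filtering.

A single trunk-mounted inertial sensor (lower lumbar spine, L5–S1) provides a
proxy for the centre-of-mass acceleration of a race walker.  Two channels are
used downstream: the vertical axis (``a_vert``) and the anteroposterior axis
(``a_ap``).  Both are low-pass filtered with a fourth-order Butterworth filter
run forward and then backward, which doubles the magnitude attenuation and
cancels the phase shift — event *timing* is the quantity of interest, so zero
phase distortion is essential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DomainError, ParseError, SamplingError

__all__ = ["InertialConfig", "AccelerationTrace", "load_trace", "lowpass_zero_phase"]

#: gravitational acceleration used as the vertical-channel baseline (m/s²)
GRAVITY = 9.81


@dataclass(frozen=True)
class InertialConfig:
    """Acquisition and judging constants.

    Parameters
    ----------
    f : float
        Sample frequency of the inertial sensor (Hz).
    cutoff_vertical, cutoff_ap : float
        Low-pass cut-off frequencies (Hz) for the vertical and anteroposterior
        channels.  The anteroposterior channel keeps more bandwidth because the
        heel-strike transient it carries is sharper.
    filter_order : int
        Order of the Butterworth filter applied in each pass (even, positive).
    LHE : float
        Limit of the human eye (s): flight times at or below this duration are
        invisible to a judge and deemed legal.
    NS : int
        Number of steps in one judged step sequence (the judging window).
    warmup : float
        Leading interval (s) excluded from analysis while the athlete
        accelerates to the target pace.
    """

    f: float = 200.0
    cutoff_vertical: float = 20.0
    cutoff_ap: float = 30.0
    filter_order: int = 4
    LHE: float = 0.040
    NS: int = 30
    warmup: float = 10.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise DomainError("sample frequency must be positive")
        nyquist = self.f / 2.0
        if not (0 < self.cutoff_vertical < nyquist and 0 < self.cutoff_ap < nyquist):
            raise DomainError("cut-off frequencies must lie in (0, f/2)")
        if self.filter_order <= 0 or self.filter_order % 2:
            raise DomainError("filter order must be a positive even integer")
        if self.LHE <= 0:
            raise DomainError("LHE must be positive")
        if self.NS < 1:
            raise DomainError("NS must be at least 1")
        if self.warmup < 0:
            raise DomainError("warmup must be non-negative")


@dataclass(frozen=True)
class AccelerationTrace:
    """Uniformly sampled two-channel CoM acceleration proxy."""

    t: np.ndarray
    a_vert: np.ndarray
    a_ap: np.ndarray
    f: float
    filtered: bool = False

    #: |Δt − 1/f| tolerance; real loggers jitter slightly
    _dt_tol: float = field(default=0.0, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        av = np.asarray(self.a_vert, dtype=float)
        aa = np.asarray(self.a_ap, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "a_vert", av)
        object.__setattr__(self, "a_ap", aa)
        if not (len(t) == len(av) == len(aa)):
            raise DomainError("t, a_vert and a_ap must have equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(av)) and np.all(np.isfinite(aa))):
            raise DomainError("trace contains non-finite values")
        if self.f <= 0:
            raise DomainError("sample frequency must be positive")
        tol = self._dt_tol or max(1e-6, 0.01 / self.f)
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / self.f) > tol)):
            k = int(np.argmax(np.abs(dt - 1.0 / self.f)))
            raise SamplingError(
                f"non-uniform sampling at sample {k}: dt={dt[k]:.6g} s, expected {1.0 / self.f:.6g} s"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ax": self.a_vert, "az": self.a_ap})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


# recognized header aliases for the input CSV dialect
_TIME_COLS = ("t", "time", "time_s")
_VERT_COLS = ("ax", "a_vert", "vertical")
_AP_COLS = ("az", "a_ap", "anteroposterior")


def _pick(columns, aliases, what: str, path) -> str:
    lower = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    raise ParseError(f"{path}: no {what} column (expected one of {aliases})")


def load_trace(path, f: float = 200.0) -> AccelerationTrace:
    """Read a two-channel acceleration CSV into an :class:`AccelerationTrace`.

    The dialect is UTF-8, comma-separated with a header row.  Recognized
    columns: ``t`` (seconds, optional), ``ax`` (vertical, m/s²) and ``az``
    (anteroposterior, m/s²); extra columns are ignored.  A missing time column
    is synthesized as ``k / f``.

    Raises
    ------
    ParseError
        Missing columns or a non-numeric/NaN cell (the row is named).
    SamplingError
        Timestamps deviate from uniform ``1/f`` spacing beyond tolerance.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    vcol = _pick(df.columns, _VERT_COLS, "vertical acceleration", path)
    acol = _pick(df.columns, _AP_COLS, "anteroposterior acceleration", path)
    try:
        tcol = _pick(df.columns, _TIME_COLS, "time", path)
    except ParseError:
        tcol = None

    cols = [c for c in (tcol, vcol, acol) if c is not None]
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: non-numeric or missing value in data row {row}")

    t = numeric[tcol].to_numpy() if tcol else np.arange(len(df)) / f
    return AccelerationTrace(
        t=t, a_vert=numeric[vcol].to_numpy(), a_ap=numeric[acol].to_numpy(), f=f
    )


def lowpass_zero_phase(trace: AccelerationTrace, cfg: InertialConfig) -> AccelerationTrace:
    """Zero-phase Butterworth low-pass filtering of both channels.

    The configured filter (default fourth order) is applied forward and then
    backward per channel, which squares the magnitude response (an effective
    eighth-order roll-off) and cancels the phase shift.  Reflective padding of
    length ``3 * filter_order`` suppresses startup transients.

    Raises
    ------
    DomainError
        Trace already filtered, or too short for stable edge handling.
    """
    if trace.filtered:
        raise DomainError("trace is already filtered")
    pad = 3 * cfg.filter_order
    if len(trace) <= pad:
        raise DomainError(f"trace too short to filter: need > {pad} samples, got {len(trace)}")

    out = {}
    for name, cutoff in (("a_vert", cfg.cutoff_vertical), ("a_ap", cfg.cutoff_ap)):
        sos = sps.butter(cfg.filter_order, cutoff, btype="low", fs=trace.f, output="sos")
        out[name] = sps.sosfiltfilt(sos, getattr(trace, name), padtype="even", padlen=pad)
    return replace(trace, a_vert=out["a_vert"], a_ap=out["a_ap"], filtered=True)
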