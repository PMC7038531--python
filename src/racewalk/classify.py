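"""Step and step-sequence infringement classification.

Three strategies mirror the judge's repertoire: a binary legal/illegal call,
a three-level call with an explicit "doubt" grade (the yellow paddle), and a
fuzzy membership that grades how illegal a timing is.  All hinge on the limit
of the human eye, LHE = 40 ms: flight shorter than LHE is invisible to a
judge and therefore legal.  Equality cases resolve toward the lenient
(athlete-favourable) side throughout.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .errors import DomainError

__all__ = [
    "StepLabel",
    "classify_binary",
    "classify_three_level",
    "fuzzy_membership",
    "infringement_fraction",
]


class StepLabel(str, Enum):
    LEGAL = "legal"
    DOUBT = "doubt"
    ILLEGAL = "illegal"


def classify_binary(logct: float, LHE: float = 0.040) -> StepLabel:
    """Legal iff the timing (step or sequence) is at most LHE.

    A non-positive timing (double support) is trivially legal.
    """
    if not np.isfinite(logct):
        raise DomainError("LOGC timing must be finite")
    return StepLabel.LEGAL if logct <= LHE else StepLabel.ILLEGAL


def classify_three_level(
    logct_min: float, logct_max: float, LHE: float = 0.040
) -> StepLabel:
    """Three-level call from the timing confidence interval.

    Legal when the whole interval sits at or below LHE, illegal when it sits
    strictly above, doubt when it straddles the limit.
    """
    if logct_min > logct_max:
        raise DomainError("inverted bounds: logct_min > logct_max")
    if logct_max <= LHE:
        return StepLabel.LEGAL
    if logct_min > LHE:
        return StepLabel.ILLEGAL
    return StepLabel.DOUBT


def fuzzy_membership(logct, LHE: float = 0.040, f: float = 200.0):
    """Fuzzy illegality membership η ∈ [0, 1].

    η = 0 at or below ``LHE − 2/f``, η = 1 at or above ``LHE + 2/f``, with a
    linear ramp between (η = 0.5 exactly at LHE).  At f = 200 Hz the doubt
    band is (30 ms, 50 ms).  Accepts scalars or arrays.
    """
    if f <= 0:
        raise DomainError("sample frequency must be positive")
    x = np.asarray(logct, dtype=float)
    band = 2.0 / f
    eta = np.clip((x - (LHE - band)) / (2.0 * band), 0.0, 1.0)
    return float(eta) if x.ndim == 0 else eta


def infringement_fraction(step_labels, NS: int = 30) -> float:
    """Fraction of illegal steps in one judged sequence (exactly NS labels).

    Consumes binary labels: the count of "illegal" calls divided by NS.
    """
    labels = list(step_labels)
    if len(labels) != NS:
        raise DomainError(f"expected exactly NS={NS} labels, got {len(labels)}")
    if any(l == StepLabel.DOUBT for l in labels):
        raise DomainError("infringement fraction consumes binary labels only")
    return sum(1 for l in labels if l == StepLabel.ILLEGAL) / NS
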