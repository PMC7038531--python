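"""Exception hierarchy shared across the package.

Two broad families matter to callers (and to the CLI exit codes): problems
with the *inputs* (malformed files, bad parameter values) and problems that
arise while *processing* otherwise valid inputs (no steps found, degenerate
fits).
"""


class RaceWalkError(Exception):
    """Base class for all package errors."""


class InputError(RaceWalkError):
    """Invalid input data or parameters (CLI exit code 2)."""


class ParseError(InputError):
    """A file could not be parsed (names the offending row where possible)."""


class SamplingError(InputError):
    """Timestamps are not uniformly sampled within tolerance."""


class DomainError(InputError):
    """A value lies outside the operation's domain."""


class ProcessingError(RaceWalkError):
    """Computation failed on valid inputs (CLI exit code 3)."""


class NoStepsError(ProcessingError):
    """No (or too few) steps could be detected in the trace."""


class InsufficientStepsError(ProcessingError):
    """Fewer steps than one judged sequence requires."""


class FitError(ProcessingError):
    """Regression could not be carried out (degenerate design)."""
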