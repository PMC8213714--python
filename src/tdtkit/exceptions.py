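"""Exception and warning hierarchy.

All validation failures raise :class:`TDTValidationError` (a ``ValueError``),
solver failures raise :class:`ConvergenceError`, and soft diagnostics are
emitted as warnings so callers can promote them with ``warnings.simplefilter``.
"""


class TDTError(Exception):
    """Base class for all package errors."""


class TDTValidationError(TDTError, ValueError):
    """Invalid input: broken invariant, malformed file, bad parameter."""


class InsufficientDataError(TDTValidationError):
    """Too few observations (or too few distinct conditions) to fit."""


class FitInvalidError(TDTError):
    """A fit succeeded numerically but is physically impossible.

    The canonical case is a non-negative slope of log10(time) on
    temperature: tolerance time cannot increase with heat stress.
    """


class ConvergenceError(TDTError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateRampError(TDTError):
    """Ramp closed form undefined (logarithm argument not positive)."""


class InconsistentInputError(TDTValidationError):
    """Inputs that contradict each other (e.g. ramp ending below baseline)."""


class DoseNotReached(TDTError):
    """A dose target was never reached; carries the final accumulated dose."""

    def __init__(self, target: float, final_dose: float):
        super().__init__(
            f"dose never reached target {target:g}; final dose {final_dose:.6g}"
        )
        self.target = target
        self.final_dose = final_dose


class ParseError(TDTValidationError):
    """File parsing failure, naming the offending row/column where known."""


class ExtrapolationWarning(UserWarning):
    """Prediction outside the time-temperature span the curve was fitted on."""


class RefinementWarning(UserWarning):
    """Integration step coarser than the finest profile interval."""


class BelowRangeWarning(UserWarning):
    """Profile temperature far below the curve's tolerated range.

    Injury rates there are formally tiny but the linear TDT relation is
    unvalidated that far below ct_ref; results should be treated with care.
    """
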