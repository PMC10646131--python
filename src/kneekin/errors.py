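"""Exception hierarchy.

All package-specific failures derive from :class:`KneeKinError` so callers
can catch one base class; the subclasses distinguish bad parameters,
degenerate geometry, non-terminating searches and file-format problems.
"""


class KneeKinError(Exception):
    """Base class for all kneekin errors."""


class ParameterError(KneeKinError, ValueError):
    """An input value violates a documented precondition."""


class GeometryError(KneeKinError):
    """A geometric construction is degenerate or undefined for this input."""


class ConvergenceError(KneeKinError):
    """An iterative search terminated without meeting its tolerance."""

    def __init__(self, message: str, best_imbalance_mm: float | None = None):
        super().__init__(message)
        self.best_imbalance_mm = best_imbalance_mm


class FormatError(KneeKinError):
    """A file could not be parsed or failed validation."""


class ContractError(KneeKinError):
    """An operation was applied to data it is documented never to accept
    (e.g. computing rotation from a standardized track)."""
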