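"""Exception hierarchy.

Validation failures (bad input data or configuration) and estimation
failures (a statistic that cannot be computed from otherwise valid data)
are kept distinct so the command-line layer can map them to exit codes
2 and 3 respectively.
"""


class StanceMCIDError(Exception):
    """Base class for all package errors."""


class ValidationError(StanceMCIDError):
    """Input data or configuration violates a documented contract."""


class InsufficientDataError(ValidationError):
    """Fewer measurement trials than the required minimum."""


class PairingError(ValidationError):
    """A unit is missing one of its two timepoints."""


class JoinError(ValidationError):
    """A unit with change scores has no anchor record (or vice versa)."""


class EstimationError(StanceMCIDError):
    """An estimator's preconditions are not met (e.g. an empty group)."""


class DegenerateDataError(EstimationError):
    """Data carry no usable signal (e.g. all paired differences zero)."""


class UndefinedSymmetryIndexError(EstimationError):
    """Symmetry index is undefined because both limb loads are zero."""
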