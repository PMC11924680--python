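"""Exception hierarchy shared across the package.

``ValidationError`` (and subclasses) map to CLI exit code 2; anything else
raised during a run maps to exit code 3.
"""


class StaturePgsError(Exception):
    """Base class for all package errors."""


class ValidationError(StaturePgsError, ValueError):
    """Invalid user input: bad values, malformed tables, unknown codes."""


class ParseError(ValidationError):
    """A file could not be parsed into a valid domain object."""


class OutOfRangeError(ValidationError):
    """A query fell outside the range covered by a reference table."""


class AlignmentError(ValidationError):
    """Weight table and dosage matrix share no usable variants."""


class ConvergenceError(StaturePgsError):
    """A model fit failed to converge (e.g. complete separation)."""


class SimulationError(StaturePgsError):
    """The generative model produced an unusable cohort (e.g. empty after referral filtering)."""
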