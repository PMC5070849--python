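"""Exception hierarchy shared across the package."""


class SSXError(Exception):
    """Base class for all package errors."""


class ParseError(SSXError):
    """A delimited-text input could not be parsed."""


class ValidationError(SSXError):
    """Input data violates a structural invariant."""


class AlignmentError(ValidationError):
    """Internal and external matrices do not share a time grid."""


class DimensionError(SSXError):
    """A requested dimension is incompatible with the data."""


class EstimabilityError(SSXError):
    """Model cannot be estimated: too many metagenes for the sample count."""


class NotDiagonalizableError(SSXError):
    """Effective system matrix is numerically defective."""
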