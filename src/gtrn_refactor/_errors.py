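"""Exception hierarchy shared across the package."""


class GtrnError(Exception):
    """Base class for all package errors."""


class ValidationError(GtrnError):
    """A genome, table or argument violates a structural contract."""


class NumericalError(GtrnError):
    """A linear solve or integration failed or is untrustworthy."""


class MoveError(GtrnError):
    """A mutation move is illegal on the given genome (rejected)."""


class NoLegalMoveError(MoveError):
    """No mutation move at all can be applied to the genome."""


class GenomeParseError(ValidationError):
    """An annotated genome file cannot be parsed back into a GTRN."""


class StabilityWarning(UserWarning):
    """The linear system has a non-negative eigenvalue (unstable dynamics)."""
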