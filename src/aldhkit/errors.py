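"""Exception hierarchy for aldhkit."""


class AldhkitError(Exception):
    """Base class for all aldhkit errors."""


class FixtureError(AldhkitError):
    """A packaged fixture is missing or corrupt."""


class ParameterError(AldhkitError):
    """A generator or analysis parameter is out of range or contradictory."""


class InputError(AldhkitError):
    """User-supplied data violates a precondition."""


class PatternSyntaxError(InputError):
    """A PROSITE-style pattern string could not be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SplicedAlignmentError(AldhkitError):
    """No spliced alignment of the CDS onto the genomic sequence was found."""
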