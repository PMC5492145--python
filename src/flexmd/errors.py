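"""Exception hierarchy for flexmd."""


class FlexmdError(Exception):
    """Base class for all flexmd errors."""


class ParseError(FlexmdError):
    """A structure or trajectory file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UnsupportedFormatError(FlexmdError):
    """Input uses a feature outside the supported subset (e.g. triclinic box)."""


class AtomCountMismatchError(FlexmdError):
    """Trajectory frame atom count disagrees with the topology."""


class SelectionError(FlexmdError):
    """An atom/residue selection resolved to nothing or to invalid atoms."""


class ConfigError(FlexmdError):
    """A configuration value violates its contract; names the field."""
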