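"""Exception hierarchy shared across the package."""


class EpifitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EpifitError):
    """A file is structurally invalid (e.g. a required column is missing)."""


class ParseError(EpifitError):
    """A row could not be parsed; carries the offending 1-based row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DecompositionError(EpifitError):
    """A double-mutant label does not decompose into two known singles."""


class InfeasibleFitnessError(EpifitError):
    """A fitness value lies outside the range of the fitted curve."""


class InsufficientDataError(EpifitError):
    """Not enough observations for the requested statistic."""


class ConfigurationError(EpifitError):
    """A simulation or generator configuration is self-inconsistent."""
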