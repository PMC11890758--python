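"""Exception taxonomy.

Two broad families matter for the CLI exit codes: configuration/format
problems (the user's files are wrong) and analysis problems (the data
cannot support the requested computation).
"""


class ScreenError(Exception):
    """Base class for all oncoscreen errors."""


class ConfigError(ScreenError):
    """Invalid configuration file or generator specification."""


class FormatError(ScreenError):
    """Tabular input does not match the declared dialect/schema."""


class LayoutError(ScreenError):
    """Well identifier outside the declared plate geometry."""


class JoinError(ScreenError):
    """Measurements could not be matched to the plate map.

    ``wells`` lists the offending (plate_id, well) pairs.
    """

    def __init__(self, message, wells=None):
        super().__init__(message)
        self.wells = list(wells) if wells is not None else []


class DegenerateSignalError(ScreenError):
    """A ratio denominator channel is zero or negative."""


class DegenerateControlError(ScreenError):
    """Positive and blank controls coincide; percent-of-control undefined."""


class InsufficientDataError(ScreenError):
    """Too few usable points (or too narrow a dose span) to fit a curve."""


class InsufficientReplicatesError(ScreenError):
    """Fewer than two usable replicate AUCs in a condition."""
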