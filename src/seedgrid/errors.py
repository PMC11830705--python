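"""Exception hierarchy shared across the toolkit."""


class SeedgridError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(SeedgridError):
    """Invalid configuration or parameter values (CLI exit code 2)."""


class DataError(SeedgridError):
    """Malformed or missing input data (CLI exit code 3)."""


class NoFeasiblePlanError(ConfigError):
    """No longitudinal gear yields a mean seeds-per-grid in the target range."""

    def __init__(self, message, per_gear_means=None):
        super().__init__(message)
        self.per_gear_means = dict(per_gear_means or {})


class TrayFrameNotFoundError(DataError):
    """No dominant rectangular tray contour in the binary image."""


class BordersNotFoundError(DataError):
    """Projection profile has no resolvable border bands."""


class LabelParseError(DataError):
    """Malformed row in a YOLO-style label file."""

    def __init__(self, message, path=None, line_no=None):
        super().__init__(message)
        self.path = path
        self.line_no = line_no
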