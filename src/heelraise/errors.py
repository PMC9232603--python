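"""Error taxonomy shared across the pipeline.

Each category maps to one kind of user-facing failure so the CLI can
report a stable error class and exit code.
"""


class HeelRaiseError(Exception):
    """Base class for all toolkit errors."""

    category = "error"


class FormatError(HeelRaiseError):
    """A file does not match the expected delimited-text layout."""

    category = "format"


class DataError(HeelRaiseError):
    """Values violate a stream or feature invariant (e.g. non-monotone time)."""

    category = "data"


class ParameterError(HeelRaiseError):
    """A configuration or function parameter is out of range."""

    category = "parameter"


class AlignmentError(HeelRaiseError):
    """Streams cannot be placed on a common clock (no temporal overlap)."""

    category = "alignment"


class ConfigurationError(HeelRaiseError):
    """A required stream or setting is missing for the requested operation."""

    category = "configuration"


class CalibrationError(HeelRaiseError):
    """A classifier boundary cannot be fitted from the provided points."""

    category = "calibration"


class FitError(HeelRaiseError):
    """A regression fit is impossible (e.g. zero variance in the regressor)."""

    category = "fit"
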