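"""Exception hierarchy shared by all pipeline stages."""


class WpbMorphError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(WpbMorphError):
    """A measurement violates its physical invariants (e.g. short axis <= 0)."""


class SchemaError(WpbMorphError):
    """A table does not match its declared schema (missing column, bad cell, duplicate id)."""


class ConfigError(WpbMorphError):
    """A configuration value is out of its admissible range."""


class OutOfRangeError(WpbMorphError):
    """A derived quantity falls outside its admissible open interval."""


class WindowingError(WpbMorphError):
    """A time-series analysis window contains no samples."""


class OnsetNotFoundError(WpbMorphError):
    """No stimulus onset crossing was found in a trace."""
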