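"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError and SchemaError -> 2,
NumericalError -> 3; everything else is a bug.
"""


class SignalCapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SignalCapError):
    """Invalid scientific or run configuration (bad parameter, unknown key)."""


class SchemaError(SignalCapError):
    """Malformed input file: missing column, ragged grid, non-numeric field."""


class LayoutError(SignalCapError):
    """Synthetic image layout is geometrically invalid (overlapping nuclei)."""


class MeasurementError(SignalCapError):
    """A pixel-level measurement cannot be taken (e.g. centroid at border)."""


class NumericalError(SignalCapError):
    """An estimator or optimizer failed to produce a valid result."""
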