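"""Exception hierarchy for the soilsom pipeline.

All errors derive from :class:`SoilSomError` so callers can catch the
package's failures with one clause; the CLI maps subclasses to exit codes.
"""


class SoilSomError(Exception):
    """Base class for all soilsom errors."""


class ConfigError(SoilSomError):
    """Invalid configuration: unknown keys, bad parameter values, shares not summing to 1."""


class DataError(SoilSomError):
    """Invalid input data: schema problems, NaNs, empty inputs, geometry errors."""


class PanelError(ConfigError):
    """Invalid metal panel: missing metals, nonpositive factors or references."""


class SchemaError(DataError):
    """A table is missing a required column or contains an unparsable cell."""


class GeometryError(DataError):
    """A unit polygon is invalid or degenerate."""


class NumericalError(SoilSomError):
    """A numerical procedure failed: singular kriging system, undefined index."""
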