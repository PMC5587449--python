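"""Exception hierarchy shared across the pipeline.

Every error a caller may want to catch programmatically derives from
:class:`ThermonicheError`; specific subclasses mark the failure mode
(empty input, degenerate distribution, raster extent, ...).
"""


class ThermonicheError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ThermonicheError):
    """A required column, option, or file layout could not be resolved."""


class EmptyInputError(ThermonicheError):
    """An operation received no usable records."""


class InsufficientDataError(ThermonicheError):
    """Too few observations for the requested estimate."""


class DegenerateDistributionError(ThermonicheError):
    """A sample with fewer than two distinct values, where spread is required."""


class NoInflectionError(ThermonicheError):
    """Chord deviations never change sign: the curve has no detectable inflection."""


class FormatError(ThermonicheError):
    """A raster or table file violates its declared format."""


class ExtentError(ThermonicheError):
    """A point falls outside the raster grid."""


class MissingDataError(ThermonicheError):
    """The raster cell under a point is nodata in at least one band."""


class GeometryError(ThermonicheError):
    """Range polygons are invalid or unusable."""


class ScenarioError(ThermonicheError):
    """A synthetic-data scenario is internally infeasible."""


class DegeneratePredictorError(ThermonicheError):
    """Regression predictor (or correlate) is constant."""


class ParameterError(ThermonicheError):
    """An option value is outside its admissible range."""
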