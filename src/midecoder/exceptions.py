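"""Exception hierarchy for configuration, geometry and pipeline errors."""


class MidecoderError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MidecoderError, ValueError):
    """An invalid field in a user-supplied configuration or spec."""


class ValidationError(MidecoderError, ValueError):
    """A data container violating its invariants (shape/label/NaN checks)."""


class GeometryError(MidecoderError, ValueError):
    """Window or layer geometry that does not fit the data it is applied to."""


class MappingError(MidecoderError, KeyError):
    """Event codes present in a recording but absent from the event map."""


class AggregationError(MidecoderError, ValueError):
    """Invalid input to window-prediction aggregation (e.g. empty batch)."""


class AssemblyError(MidecoderError, ValueError):
    """Inconsistent component widths when assembling the full classifier."""


class SplitError(MidecoderError, ValueError):
    """Too few trials (or classes) to build the requested cross-validation split."""


class DivergenceError(MidecoderError, RuntimeError):
    """Non-finite loss encountered during optimisation."""
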