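"""Exception types shared across the package."""


class NicheGridError(Exception):
    """Base class for package errors."""


class ConfigurationError(NicheGridError, ValueError):
    """Invalid parameter set (axis spec, world config, light params ...)."""


class GridFormatError(NicheGridError, ValueError):
    """A gridded file does not honor the climatology contract (12 monthly layers,
    regular spacing)."""


class DimensionError(NicheGridError, ValueError):
    """Mismatched geometries or axis counts between objects."""


class DegenerateInputError(NicheGridError, ValueError):
    """An operation received input with no usable information (empty valid
    region, constant field where variation is required)."""


class InsufficientDataError(NicheGridError, ValueError):
    """Fewer data points than the statistic requires."""
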