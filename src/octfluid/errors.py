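"""Exception hierarchy for octfluid."""


class OctFluidError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OctFluidError):
    """Invalid parameter value or malformed configuration."""


class ShapeError(OctFluidError):
    """Operands with incompatible shapes."""


class PlacementError(OctFluidError):
    """A requested phantom fluid pocket could not be placed."""


class DivergenceError(OctFluidError):
    """Training produced a non-finite loss."""
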