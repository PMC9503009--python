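"""Exception types shared across the package."""


class ScamfluxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ScamfluxError, ValueError):
    """An assay condition, parameter set, or config file is invalid."""


class PlacementError(ScamfluxError, RuntimeError):
    """Cells could not be placed in the frame without overlap."""


class FormatError(ScamfluxError, ValueError):
    """An input file is not in the expected format."""


class IntensityOverflowError(ScamfluxError, ValueError):
    """Rendered intensities exceed the output dtype range."""
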