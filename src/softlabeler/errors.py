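"""Exception hierarchy shared across the pipeline stages."""


class SoftLabelerError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SoftLabelerError, ValueError):
    """A parameter violates its documented constraint."""


class FormatError(SoftLabelerError, ValueError):
    """An input array or file has the wrong layout (e.g. not 3-channel RGB)."""


class DimensionError(SoftLabelerError, ValueError):
    """Two rasters that must share a spatial shape do not."""


class DegenerateMaskError(SoftLabelerError, ValueError):
    """A mask is constant, so it has no lesion contour to work with."""


class MissingInputError(SoftLabelerError, FileNotFoundError):
    """A pipeline stage input (file or precomputed array) is absent."""


class ConfigError(SoftLabelerError, ValueError):
    """A configuration file failed to parse or validate."""
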