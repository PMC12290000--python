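"""Exception hierarchy shared across the package."""


class OvasegError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(OvasegError):
    """Grid shape / dimensionality does not match what the operation needs."""


class AlignmentError(OvasegError):
    """Two grids that must share a shape (or pairing) do not."""


class DomainError(OvasegError):
    """Input values fall outside the documented domain (e.g. not in [0, 1])."""


class DegenerateInputError(OvasegError):
    """Input is technically valid but carries no usable signal."""


class MetadataError(OvasegError):
    """Required grid metadata (spacing, axis order) is missing or invalid."""


class PlacementError(OvasegError):
    """Phantom organs could not be placed without overlap."""


class ConfigurationError(OvasegError):
    """Pipeline / run configuration is incomplete or inconsistent."""
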