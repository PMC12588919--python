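"""Exception hierarchy shared across the pipeline."""


class AmpelqtlError(Exception):
    """Base class for all package errors."""


class InvalidCoordinateError(AmpelqtlError):
    """A landmark coordinate is missing or non-finite."""


class GeometryError(AmpelqtlError):
    """Degenerate landmark geometry (e.g. all points coincident)."""


class InconsistentGeometryError(GeometryError):
    """Vein polygons exceed the leaf boundary (blade area <= 0)."""


class UndefinedRatioError(AmpelqtlError):
    """A shape ratio has a zero denominator; carries the trait name."""


class DuplicateRecordError(AmpelqtlError):
    """Conflicting duplicate rows for the same design cell."""


class ZeroVarianceError(AmpelqtlError):
    """A z-transform group has no spread."""


class TooSparseError(AmpelqtlError):
    """Too many missing cells for PCA."""


class AliasingError(AmpelqtlError):
    """Singular factorial design in variance partitioning."""


class FormatError(AmpelqtlError):
    """Malformed input file contents."""


class ReconciliationError(AmpelqtlError):
    """Identifiers do not match across inputs (markers or genotypes)."""


class ConfigError(AmpelqtlError):
    """Invalid pipeline or simulation configuration."""
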