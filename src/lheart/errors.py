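"""Exception hierarchy for the reconstruction pipeline."""


class LheartError(Exception):
    """Base class for all package-specific errors."""


class InvalidMetadataError(LheartError):
    """Plane metadata violates its invariants (non-unit / non-orthogonal
    direction cosines, non-positive pixel spacing)."""


class MissingMetadataError(LheartError):
    """A required DICOM attribute is absent from the header map."""


class StudyFormatError(LheartError):
    """Study file is malformed or referentially inconsistent."""


class NonManifoldSurfaceError(LheartError):
    """Surface is not a closed 2-manifold; carries the offending edges."""

    def __init__(self, message, edges=()):
        super().__init__(message)
        self.edges = list(edges)


class DegenerateGeometryError(LheartError):
    """Point set is collinear/coplanar/coincident where full rank is needed."""


class EpsilonTooSmallError(LheartError):
    """Mutual-subset filtering emptied one of the clouds."""

    def __init__(self, message, last_sizes=None):
        super().__init__(message)
        self.last_sizes = last_sizes


class DegenerateContourError(LheartError):
    """Contour has too few vertices or zero area."""


class AmbiguousStackError(LheartError):
    """Two parallel contours share the same level position."""


class ResolutionCapError(LheartError):
    """Requested auxiliary-grid resolution exceeds the configured node cap."""


class SeedConflictError(LheartError):
    """An interior anchor point landed in (or next to) a sink tetrahedron."""


class InvalidSpecError(LheartError):
    """Phantom specification is geometrically inconsistent."""


class InvalidRegionError(LheartError):
    """Polygon handed to a region metric is self-intersecting."""


class UndefinedDistanceError(LheartError):
    """Hausdorff distance requested for an empty set."""


class OpenIntersectionError(LheartError):
    """Mesh/plane intersection produced an open polyline chain."""
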