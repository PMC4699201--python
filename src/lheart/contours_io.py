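"""Study-file I/O and the 2D-pixel to 3D-patient coordinate transform.

Contours are delineated as ordered ``(u, v)`` pixel-coordinate loops on
individual imaging planes.  Each plane carries the DICOM geometry triplet —
image position ``P`` (0020,0032), image orientation ``U, V`` (0020,0037) and
pixel spacing ``(Δu, Δv)`` (0028,0030) — from which a contour point maps into
the patient-based coordinate system (LPS, mm) as::

    p(u, v) = P + u * Δu * U + v * Δv * V

Conventions fixed here: ``(u, v)`` are 0-based pixel indices, ``u`` advances
along ``row_dir`` with spacing ``Δu = PixelSpacing[1]`` and ``v`` along
``col_dir`` with ``Δv = PixelSpacing[0]``.

The study interchange format is a small versioned JSON dialect (see
``docs/study_format.md``); meshes are written as PLY / OFF / STL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from lheart.errors import (
    InvalidMetadataError,
    MissingMetadataError,
    NonManifoldSurfaceError,
    StudyFormatError,
)

VIEWS = ("sax", "2ch", "3ch", "4ch")
LABELS = ("LV", "LA", "AO", "MERGED")

_DIRCOS_TOL = 1e-6
STUDY_FORMAT_VERSION = 1


@dataclass
class PlaneMeta:
    """Geometry of one imaging plane in the patient coordinate system.

    Parameters
    ----------
    position : (3,) array_like
        Patient coordinates (mm) of the center of the (0, 0) pixel.
    row_dir, col_dir : (3,) array_like
        Unit direction cosines of increasing ``u`` and ``v`` respectively.
    spacing : (2,) array_like
        Physical pixel pitch ``(Δu, Δv)`` in mm/pixel.
    plane_id : str
    view : str
        One of ``sax``, ``2ch``, ``3ch``, ``4ch``.
    """

    position: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    spacing: np.ndarray
    plane_id: str
    view: str

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.row_dir = _unitize(np.asarray(self.row_dir, dtype=float).reshape(3), "row_dir")
        self.col_dir = _unitize(np.asarray(self.col_dir, dtype=float).reshape(3), "col_dir")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(2)
        if abs(float(self.row_dir @ self.col_dir)) > _DIRCOS_TOL:
            raise InvalidMetadataError(
                f"plane {self.plane_id!r}: row_dir and col_dir are not orthogonal "
                f"(dot = {float(self.row_dir @ self.col_dir):.3e})"
            )
        if np.any(self.spacing <= 0):
            raise InvalidMetadataError(
                f"plane {self.plane_id!r}: pixel spacing must be positive, got {self.spacing}"
            )
        if self.view not in VIEWS:
            raise InvalidMetadataError(
                f"plane {self.plane_id!r}: unknown view {self.view!r} (expected one of {VIEWS})"
            )

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal ``row_dir × col_dir``."""
        n = np.cross(self.row_dir, self.col_dir)
        return n / np.linalg.norm(n)

    def to_plane_coords(self, points_3d) -> np.ndarray:
        """Project 3D points onto the plane axes, returning in-plane mm
        coordinates ``(s, t) = ((p - P)·U, (p - P)·V)``."""
        d = np.asarray(points_3d, dtype=float) - self.position
        return np.column_stack([d @ self.row_dir, d @ self.col_dir])

    def as_dict(self) -> dict:
        return {
            "plane_id": self.plane_id,
            "view": self.view,
            "position": self.position.tolist(),
            "row_dir": self.row_dir.tolist(),
            "col_dir": self.col_dir.tolist(),
            "spacing": self.spacing.tolist(),
        }


def _unitize(vec: np.ndarray, name: str) -> np.ndarray:
    norm = float(np.linalg.norm(vec))
    if abs(norm - 1.0) > _DIRCOS_TOL:
        raise InvalidMetadataError(
            f"{name} is not a unit vector (|{name}| = {norm:.8f}, tolerance {_DIRCOS_TOL})"
        )
    return vec / norm


@dataclass
class LabeledContour2D:
    """Ordered planar contour in pixel coordinates with an anatomical label."""

    points: np.ndarray  # (n, 2) float, (u, v)
    label: str
    plane_id: str
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.label not in LABELS:
            raise StudyFormatError(f"unknown contour label {self.label!r} (expected one of {LABELS})")
        if self.closed and len(self.points) < 3:
            raise StudyFormatError(
                f"closed contour on plane {self.plane_id!r} needs >= 3 points, got {len(self.points)}"
            )
        if len(self.points) > 1:
            same = np.all(self.points[1:] == self.points[:-1], axis=1)
            if np.any(same):
                raise StudyFormatError(
                    f"contour on plane {self.plane_id!r} has identical consecutive points"
                )

    def __len__(self):
        return len(self.points)

    def as_dict(self) -> dict:
        return {
            "plane_id": self.plane_id,
            "label": self.label,
            "closed": self.closed,
            "points": np.round(self.points, 9).tolist(),
        }


@dataclass
class LabeledCloud3D:
    """3D point set with per-point label and source-plane bookkeeping."""

    points: np.ndarray  # (n, 3) mm
    labels: list = field(default_factory=list)
    source_plane: list = field(default_factory=list)
    source_view: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = len(self.points)
        if not (len(self.labels) == len(self.source_plane) == len(self.source_view) == n):
            raise ValueError(
                "points, labels, source_plane and source_view must have equal length"
            )

    def __len__(self):
        return len(self.points)

    def select(self, mask) -> "LabeledCloud3D":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return LabeledCloud3D(
            self.points[idx],
            [self.labels[i] for i in idx],
            [self.source_plane[i] for i in idx],
            [self.source_view[i] for i in idx],
        )

    @staticmethod
    def concatenate(clouds) -> "LabeledCloud3D":
        clouds = [c for c in clouds if len(c)]
        if not clouds:
            return LabeledCloud3D(np.empty((0, 3)))
        return LabeledCloud3D(
            np.vstack([c.points for c in clouds]),
            sum((c.labels for c in clouds), []),
            sum((c.source_plane for c in clouds), []),
            sum((c.source_view for c in clouds), []),
        )


@dataclass
class TriSurface:
    """Triangulated surface: ``vertices`` (n, 3) mm, ``triangles`` (m, 3) int."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    # -- topology ---------------------------------------------------------
    def edge_counts(self) -> dict:
        """Map undirected edge -> number of incident triangles."""
        counts: dict = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (int(a), int(b)) if a < b else (int(b), int(a))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def boundary_edges(self) -> list:
        return [e for e, c in self.edge_counts().items() if c != 2]

    def is_watertight(self) -> bool:
        return len(self.triangles) > 0 and not self.boundary_edges()

    def check_watertight(self) -> None:
        bad = self.boundary_edges()
        if len(self.triangles) == 0 or bad:
            raise NonManifoldSurfaceError(
                f"surface is not watertight: {len(bad)} edge(s) not shared by exactly "
                f"2 triangles, e.g. {bad[:5]}",
                edges=bad,
            )

    def euler_characteristic(self) -> int:
        used = np.unique(self.triangles)
        return int(len(used) - len(self.edge_counts()) + len(self.triangles))

    # -- geometry ---------------------------------------------------------
    def signed_volume(self) -> float:
        """Enclosed volume (mm^3) by the divergence theorem; positive for
        outward-oriented watertight surfaces."""
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def area(self) -> float:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)

    def edge_lengths(self) -> np.ndarray:
        v, t = self.vertices, self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        return np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    @staticmethod
    def from_trimesh(mesh: trimesh.Trimesh) -> "TriSurface":
        return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


# ---------------------------------------------------------------------------
# 2D -> 3D projection
# ---------------------------------------------------------------------------

def projection_matrix(meta: PlaneMeta) -> np.ndarray:
    """Homogeneous 4x4 matrix mapping ``(u, v, 0, 1)`` to patient coordinates."""
    m = np.eye(4)
    m[:3, 0] = meta.row_dir * meta.spacing[0]
    m[:3, 1] = meta.col_dir * meta.spacing[1]
    m[:3, 2] = 0.0
    m[:3, 3] = meta.position
    return m


def project_contour_to_3d(contour: LabeledContour2D, meta: PlaneMeta) -> np.ndarray:
    """Project a planar pixel-coordinate contour into patient coordinates.

    Returns an ``(n, 3)`` array; point ``k`` is
    ``position + u_k * Δu * row_dir + v_k * Δv * col_dir``.
    """
    uv = contour.points
    return (
        meta.position
        + np.outer(uv[:, 0] * meta.spacing[0], meta.row_dir)
        + np.outer(uv[:, 1] * meta.spacing[1], meta.col_dir)
    )


def project_study_to_clouds(contours, metas) -> dict:
    """Project every contour and bucket the points per view.

    Returns ``{"sax": LabeledCloud3D, "2ch": ..., "3ch": ..., "4ch": ...}``
    (views with no contours map to empty clouds).
    """
    buckets = {v: [] for v in VIEWS}
    for c in contours:
        meta = metas[c.plane_id]
        pts = project_contour_to_3d(c, meta)
        buckets[meta.view].append(
            LabeledCloud3D(pts, [c.label] * len(pts), [c.plane_id] * len(pts), [meta.view] * len(pts))
        )
    return {v: LabeledCloud3D.concatenate(b) for v, b in buckets.items()}


# ---------------------------------------------------------------------------
# DICOM header ingestion
# ---------------------------------------------------------------------------

_TAGS = {
    "ImagePositionPatient": "(0020,0032)",
    "ImageOrientationPatient": "(0020,0037)",
    "PixelSpacing": "(0028,0030)",
}


def extract_plane_meta(header: dict, plane_id: str = "plane", view: str = "sax") -> PlaneMeta:
    """Build a :class:`PlaneMeta` from a DICOM-style attribute map.

    ``header`` must provide ``ImagePositionPatient`` (3 floats),
    ``ImageOrientationPatient`` (6 floats: row cosines then column cosines)
    and ``PixelSpacing`` (2 floats, DICOM order row-spacing then
    column-spacing).  Per the package convention ``Δu = PixelSpacing[1]``
    (column pitch, along the row direction) and ``Δv = PixelSpacing[0]``.
    """
    for key, tag in _TAGS.items():
        if key not in header:
            raise MissingMetadataError(f"missing DICOM attribute {key} {tag}")
    pos = np.asarray(header["ImagePositionPatient"], dtype=float)
    orient = np.asarray(header["ImageOrientationPatient"], dtype=float)
    spacing = np.asarray(header["PixelSpacing"], dtype=float)
    if pos.shape != (3,):
        raise InvalidMetadataError("ImagePositionPatient must have 3 components")
    if orient.shape != (6,):
        raise InvalidMetadataError("ImageOrientationPatient must have 6 components")
    if spacing.shape != (2,):
        raise InvalidMetadataError("PixelSpacing must have 2 components")
    return PlaneMeta(
        position=pos,
        row_dir=orient[:3],
        col_dir=orient[3:],
        spacing=(spacing[1], spacing[0]),
        plane_id=plane_id,
        view=view,
    )


# ---------------------------------------------------------------------------
# Study file (versioned JSON)
# ---------------------------------------------------------------------------

def write_study(path, contours, metas) -> None:
    """Serialize contours + plane metadata to the JSON study format."""
    metas = dict(metas)
    for c in contours:
        if c.plane_id not in metas:
            raise StudyFormatError(f"contour references unknown plane_id {c.plane_id!r}")
    doc = {
        "format": "lheart-study",
        "version": STUDY_FORMAT_VERSION,
        "planes": [metas[k].as_dict() for k in sorted(metas)],
        "contours": [c.as_dict() for c in contours],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_study(path):
    """Read a study file; returns ``(contours, {plane_id: PlaneMeta})``."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise StudyFormatError(f"{path}: not valid JSON (line {exc.lineno}: {exc.msg})") from exc
    if not isinstance(doc, dict) or doc.get("format") != "lheart-study":
        raise StudyFormatError(f"{path}: not an lheart study file")
    if doc.get("version") != STUDY_FORMAT_VERSION:
        raise StudyFormatError(
            f"{path}: unsupported study version {doc.get('version')!r}"
        )
    metas = {}
    for i, rec in enumerate(doc.get("planes", [])):
        try:
            meta = PlaneMeta(
                position=rec["position"],
                row_dir=rec["row_dir"],
                col_dir=rec["col_dir"],
                spacing=rec["spacing"],
                plane_id=rec["plane_id"],
                view=rec["view"],
            )
        except KeyError as exc:
            raise StudyFormatError(f"{path}: planes[{i}] missing field {exc}") from exc
        if meta.plane_id in metas:
            raise StudyFormatError(f"{path}: duplicate plane_id {meta.plane_id!r}")
        metas[meta.plane_id] = meta
    contours = []
    for i, rec in enumerate(doc.get("contours", [])):
        try:
            c = LabeledContour2D(
                points=rec["points"],
                label=rec["label"],
                plane_id=rec["plane_id"],
                closed=rec.get("closed", True),
            )
        except KeyError as exc:
            raise StudyFormatError(f"{path}: contours[{i}] missing field {exc}") from exc
        if c.plane_id not in metas:
            raise StudyFormatError(
                f"{path}: contours[{i}] references undefined plane_id {c.plane_id!r}"
            )
        contours.append(c)
    return contours, metas


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

_MESH_FORMATS = {"PLY": ".ply", "OFF": ".off", "STL": ".stl"}


def write_mesh(surface: TriSurface, path, fmt: str | None = None) -> None:
    """Write a watertight surface as PLY, OFF or STL (inferred from the
    extension when ``fmt`` is None).  Refuses non-manifold input."""
    surface.check_watertight()
    path = Path(path)
    if fmt is None:
        fmt = {v: k for k, v in _MESH_FORMATS.items()}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}")
    fmt = fmt.upper()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; choose from {sorted(_MESH_FORMATS)}")
    mesh = surface.to_trimesh()
    mesh.export(str(path), file_type=fmt.lower())


def read_mesh(path) -> TriSurface:
    """Read a PLY/OFF/STL mesh back into a :class:`TriSurface`."""
    mesh = trimesh.load(str(path), process=False, force="mesh")
    surf = TriSurface.from_trimesh(mesh)
    if surf.vertices.size and surf.triangles.size:
        # STL stores loose triangles; re-weld coincident vertices.
        if surf.boundary_edges():
            mesh.merge_vertices()
            surf = TriSurface.from_trimesh(mesh)
    return surf
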