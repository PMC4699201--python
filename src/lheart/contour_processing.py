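"""Densification of parallel short-axis contour groups.

Each anatomical group (LV, LA, AO) is a stack of roughly parallel closed
contours spaced one slice apart (8 mm in routine CMR).  The stack is turned
into a dense point sheet in four steps:

(a) re-orientation — every contour is made counter-clockwise about the
    short-axis normal (positive signed area);
(b) intra-contour interpolation — each contour is resampled to a common
    point count ``N`` on a periodic PCHIP curve through its vertices;
(c) contour matching — neighbouring contours are brought into point-to-point
    correspondence by the circular shift minimizing the mean point-wise
    distance, giving an ``L × N`` matrix of points whose columns are
    correspondence tracks across slices;
(d) inter-contour interpolation — each column track is interpolated
    coordinate-wise with PCHIP against physical slice position, enlarging
    the matrix to ``M × N`` levels.

PCHIP is shape-preserving and C¹; for the near-circular endocardial
contours a C² spline gives no practical benefit.  The bifurcation region
(merged LV/LA/AO contours) is deliberately left uninterpolated — point
correspondence is ill-defined there and the variational reconstruction
handles that region from the raw points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from lheart.errors import AmbiguousStackError, DegenerateContourError

_WRAP_PAD = 3  # wrap-around knots on each side for periodic PCHIP


@dataclass
class ContourMatrix:
    """``M × N`` grid of 3D points: row = slice level, column = track."""

    points: np.ndarray  # (M, N, 3)
    levels: np.ndarray  # (M,) position along the stack normal, mm
    label: str

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (M, N, 3)")
        if len(self.levels) != self.points.shape[0]:
            raise ValueError("levels must have one entry per row")
        d = np.diff(self.levels)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("levels must be strictly monotone")

    @property
    def shape(self):
        return self.points.shape[:2]

    def flat_points(self) -> np.ndarray:
        return self.points.reshape(-1, 3)

    def row_centroids(self) -> np.ndarray:
        """Per-level contour centroids — guaranteed-inside anchors for
        star-shaped endocardial contours."""
        return self.points.mean(axis=1)


# ---------------------------------------------------------------------------
# (a) orientation
# ---------------------------------------------------------------------------

def _plane_basis(points: np.ndarray, normal) -> tuple:
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # any in-plane orthonormal pair (e1, e2) with e1 × e2 = normal
    seed = np.array([1.0, 0.0, 0.0])
    if abs(normal @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _to_plane_2d(points: np.ndarray, normal) -> np.ndarray:
    e1, e2 = _plane_basis(points, normal)
    c = points.mean(axis=0)
    d = points - c
    return np.column_stack([d @ e1, d @ e2])


def signed_area(contour, normal=None) -> float:
    """Shoelace signed area of a closed polygon (mm²).

    2D input uses the standard orientation (CCW positive).  3D input must be
    planar and requires ``normal``; the sign is taken counter-clockwise
    about that normal.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise DegenerateContourError(f"polygon needs >= 3 vertices, got {len(pts)}")
    if pts.shape[1] == 3:
        if normal is None:
            raise ValueError("signed_area of a 3D contour requires the reference normal")
        pts = _to_plane_2d(pts, normal)
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def reorient_ccw(contour, normal=None) -> np.ndarray:
    """Return the contour ordered counter-clockwise (positive signed area).

    Idempotent; the point set is unchanged up to order reversal.
    """
    pts = np.asarray(contour, dtype=float)
    area = signed_area(pts, normal=normal)
    if area == 0.0:
        raise DegenerateContourError("zero-area polygon has no orientation")
    return pts.copy() if area > 0 else pts[::-1].copy()


# ---------------------------------------------------------------------------
# (b) intra-contour resampling
# ---------------------------------------------------------------------------

def resample_contour(contour, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` points on a periodic PCHIP curve.

    The curve passes through every original vertex and is parameterized by
    cumulative chord length.  Plain PCHIP is not periodic, so the knot
    sequence is padded with three wrap-around vertices on each side and only
    the central period is sampled — C¹ across the seam in practice.  The
    first output sample coincides with the original first vertex.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 4:
        raise DegenerateContourError(f"resampling needs >= 4 points, got {len(pts)}")
    if n < 4:
        raise ValueError(f"target point count must be >= 4, got {n}")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(seg == 0):
        raise DegenerateContourError("contour has coincident consecutive points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    k = _WRAP_PAD
    t_ext = np.concatenate([t[-1 - k:-1] - total, t, t[1:1 + k] + total])
    p_ext = np.vstack([pts[-k:], closed, pts[1:1 + k]])
    interp = PchipInterpolator(t_ext, p_ext, axis=0, extrapolate=False)
    s = np.arange(n) * (total / n)
    return np.asarray(interp(s))


# ---------------------------------------------------------------------------
# (c) matching
# ---------------------------------------------------------------------------

def match_contours(reference, other) -> int:
    """Circular shift aligning ``other`` with ``reference``.

    Returns the ``k`` in ``[0, N)`` minimizing the mean point-wise distance
    between ``reference`` and ``np.roll(other, -k, axis=0)``; ties break to
    the smallest ``k``.  Both contours must have equal point counts and the
    same orientation.
    """
    ref = np.asarray(reference, dtype=float)
    oth = np.asarray(other, dtype=float)
    if ref.shape != oth.shape:
        raise ValueError(f"point counts differ: {ref.shape} vs {oth.shape}")
    n = len(ref)
    # mean ||ref_j - oth_{j+k}||: expand via FFT-free direct scan (n is small)
    costs = np.empty(n)
    for k in range(n):
        costs[k] = np.mean(np.linalg.norm(ref - np.roll(oth, -k, axis=0), axis=1))
    return int(np.argmin(costs))


def apply_shift(contour, k: int) -> np.ndarray:
    """Apply the circular shift found by :func:`match_contours`."""
    return np.roll(np.asarray(contour, dtype=float), -k, axis=0)


# ---------------------------------------------------------------------------
# (c)+(d) matrix construction and inter-contour interpolation
# ---------------------------------------------------------------------------

def build_matrix(group, n: int, normal, label: str = "LV") -> ContourMatrix:
    """Reformulate a stack of parallel contours into an ``L × N`` matrix.

    ``group`` is a sequence of ``(points (m, 3), level)`` pairs.  Contours
    are sorted by level, re-oriented counter-clockwise about ``normal``,
    resampled to ``n`` points, and matched sequentially (each row to its
    predecessor) so that every column is a correspondence track.
    """
    if len(group) < 2:
        raise ValueError("a contour stack needs >= 2 contours")
    levels = np.array([float(lv) for _, lv in group])
    if len(np.unique(levels)) != len(levels):
        raise AmbiguousStackError(f"duplicate stack levels: {sorted(levels)}")
    order = np.argsort(levels)
    rows = []
    for i in order:
        pts = reorient_ccw(np.asarray(group[i][0], dtype=float), normal=normal)
        rows.append(resample_contour(pts, n))
    for i in range(1, len(rows)):
        k = match_contours(rows[i - 1], rows[i])
        rows[i] = apply_shift(rows[i], k)
    return ContourMatrix(np.stack(rows), levels[order], label)


def interpolate_levels(matrix: ContourMatrix, m: int) -> ContourMatrix:
    """Densify a contour matrix from ``L`` to ``m`` levels.

    Every column track is interpolated coordinate-wise with PCHIP against
    the physical level position; the ``m`` output levels are uniformly
    spaced over ``[levels[0], levels[-1]]`` (no extrapolation), so original
    rows are reproduced whenever an output level hits an input level.
    """
    l = matrix.points.shape[0]
    if m < l:
        raise ValueError(f"target level count {m} < input level count {l}")
    levels = matrix.levels
    new_levels = np.linspace(levels[0], levels[-1], m)
    if levels[0] > levels[-1]:
        interp = PchipInterpolator(levels[::-1], matrix.points[::-1], axis=0)
    else:
        interp = PchipInterpolator(levels, matrix.points, axis=0)
    return ContourMatrix(np.asarray(interp(new_levels)), new_levels, matrix.label)


# ---------------------------------------------------------------------------
# group driver
# ---------------------------------------------------------------------------

def choose_level_count(levels, target_spacing_mm: float) -> int:
    """Level count giving inter-level spacing ≈ ``target_spacing_mm``."""
    span = float(abs(levels[-1] - levels[0]))
    return max(len(levels), int(round(span / target_spacing_mm)) + 1)


def densify_groups(contours3d, normal, n: int = 64,
                   target_spacing_mm: float | None = None, m: int | None = None):
    """Densify the short-axis LV / LA / AO contour groups.

    Parameters
    ----------
    contours3d : sequence of (label, points (k, 3))
        Projected short-axis contours.  ``MERGED`` contours (the bifurcation
        region) are excluded from every group and must be carried through to
        the reconstruction as raw points by the caller.
    normal : (3,) array_like
        Short-axis stack normal (apex-to-base); levels are positions along
        it and "counter-clockwise" is defined about it.
    n : int
        Points per resampled contour.
    target_spacing_mm : float, optional
        Desired inter-level spacing; the per-group level count ``M`` follows
        from the stack span.  Ignored when ``m`` is given.
    m : int, optional
        Explicit output level count for every group.

    Returns
    -------
    (dict, list)
        ``{label: ContourMatrix}`` for the groups with >= 2 contours, and a
        list of warning strings for groups passed through uninterpolated.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    groups: dict = {"LV": [], "LA": [], "AO": []}
    for label, pts in contours3d:
        if label == "MERGED":
            continue
        pts = np.asarray(pts, dtype=float)
        groups[label].append((pts, float(pts.mean(axis=0) @ normal)))
    matrices, warnings = {}, []
    for label, stack in groups.items():
        if not stack:
            warnings.append(f"group {label}: no contours, skipped")
            continue
        if len(stack) < 2:
            warnings.append(f"group {label}: only 1 contour, passed through uninterpolated")
            continue
        mat = build_matrix(stack, n, normal, label=label)
        if m is not None:
            m_g = max(m, mat.points.shape[0])
        elif target_spacing_mm is not None:
            m_g = choose_level_count(mat.levels, target_spacing_mm)
        else:
            m_g = mat.points.shape[0]
        matrices[label] = interpolate_levels(mat, m_g)
    return matrices, warnings
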