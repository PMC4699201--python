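"""Validation of a reconstruction against reference planar contours.

The watertight surface is cut with each imaging plane; the resulting closed
sectional polygons (``Re``) are compared with the reference contours drawn
on that plane (``Tr``) using three standard criteria:

* Hausdorff distance ``H`` between the two boundary curves (mm),
* Dice ``D = 2·Area(Re ∩ Tr) / (Area(Re) + Area(Tr))``,
* Jaccard ``J = Area(Re ∩ Tr) / Area(Re ∪ Tr)``.

``D`` and ``J`` are algebraically linked by ``J = D / (2 − D)``; an overlap
of 0.7 or more is conventionally considered adequate.  Region areas are
computed by exact polygon clipping (shapely), not rasterization, so results
are deterministic and resolution-free.  All in-plane coordinates are mm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import reduce
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from lheart.contours_io import PlaneMeta, TriSurface, project_contour_to_3d
from lheart.errors import (
    InvalidRegionError,
    OpenIntersectionError,
    UndefinedDistanceError,
)

ADEQUATE_OVERLAP = 0.7  # conventional adequacy bar for Dice/Jaccard


@dataclass
class ValidationRecord:
    """Per-plane comparison scores."""

    plane_id: str
    view: str
    hausdorff_mm: float
    dice: float
    jaccard: float

    def __post_init__(self):
        if not (0.0 <= self.dice <= 1.0) or not (0.0 <= self.jaccard <= 1.0):
            raise ValueError("Dice/Jaccard must lie in [0, 1]")

    @property
    def adequate(self) -> bool:
        return self.dice >= ADEQUATE_OVERLAP

    def as_dict(self) -> dict:
        return {
            "plane_id": self.plane_id,
            "view": self.view,
            "H_mm": self.hausdorff_mm,
            "D": self.dice,
            "J": self.jaccard,
            "adequate": self.adequate,
        }


# ---------------------------------------------------------------------------
# mesh / plane intersection
# ---------------------------------------------------------------------------

def intersect_mesh_plane(surface: TriSurface, meta: PlaneMeta) -> list:
    """Cut a watertight surface with an imaging plane.

    Returns a list of closed polygons as ``(k, 2)`` arrays in the plane's
    in-plane mm coordinates ``(s, t)`` (axes ``row_dir``/``col_dir`` about
    ``position``).  A plane that misses the surface yields an empty list; an
    open chain (possible only for non-watertight input) raises
    :class:`OpenIntersectionError`.
    """
    normal = meta.normal
    offset = float(meta.position @ normal)
    sd = surface.vertices @ normal - offset
    # nudge vertices lying exactly on the plane so every crossing is a clean
    # edge crossing
    sd = np.where(sd == 0.0, 1e-12, sd)
    tris = surface.triangles
    tsd = sd[tris]
    crossing = np.flatnonzero(~(np.all(tsd > 0, axis=1) | np.all(tsd < 0, axis=1)))
    if len(crossing) == 0:
        return []

    def edge_point(i, j):
        t = sd[i] / (sd[i] - sd[j])
        return surface.vertices[i] + t * (surface.vertices[j] - surface.vertices[i])

    # Each crossing triangle contributes one segment whose endpoints live on
    # its two crossed edges; chaining via shared (undirected) edge keys links
    # the segments into loops.
    segments = []  # (edge_key_a, edge_key_b)
    points: dict = {}
    for ti in crossing:
        a, b, c = (int(v) for v in tris[ti])
        keys = []
        for i, j in ((a, b), (b, c), (c, a)):
            if (sd[i] > 0) != (sd[j] > 0):
                key = (i, j) if i < j else (j, i)
                if key not in points:
                    points[key] = edge_point(i, j)
                keys.append(key)
        if len(keys) == 2:
            segments.append(tuple(keys))

    adjacency: dict = {}
    for ka, kb in segments:
        adjacency.setdefault(ka, []).append(kb)
        adjacency.setdefault(kb, []).append(ka)

    loops = []
    visited: set = set()
    for start in adjacency:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        closed = False
        while True:
            nxts = [k for k in adjacency[cur] if k != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                closed = True
                break
            if nxt in visited:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if not closed:
            raise OpenIntersectionError(
                f"plane {meta.plane_id!r}: open intersection chain of {len(loop)} points "
                "(surface is not watertight along the cut)"
            )
        loops.append(loop)

    out = []
    for loop in loops:
        pts3 = np.array([points[k] for k in loop])
        out.append(meta.to_plane_coords(pts3))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _as_point_array(obj) -> np.ndarray:
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        arr = arr.reshape(-1, arr.shape[-1])
    return arr


def resample_polyline(points: np.ndarray, step: float = 0.5,
                      closed: bool = True) -> np.ndarray:
    """Arc-length resampling of a polyline at (at most) ``step`` spacing."""
    pts = _as_point_array(points)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total == 0:
        return pts[:1]
    n = max(int(np.ceil(total / step)), len(pts))
    s = np.linspace(0.0, total, n, endpoint=not closed)
    return np.column_stack([np.interp(s, t, pts[:, k]) for k in range(pts.shape[1])])


def hausdorff(x, y) -> float:
    """Symmetric Hausdorff distance ``max(sup_x d(x, Y), sup_y d(y, X))``
    between two point sets (any dimension)."""
    x, y = _as_point_array(x), _as_point_array(y)
    if len(x) == 0 or len(y) == 0:
        raise UndefinedDistanceError("Hausdorff distance of an empty set is undefined")
    dxy = cKDTree(y).query(x)[0].max()
    dyx = cKDTree(x).query(y)[0].max()
    return float(max(dxy, dyx))


def _to_region(polygons):
    """Even-odd union of closed loops (nested loops become holes).

    Loops with substantive self-intersections are rejected.  Micro
    self-touches (smoothing can nudge a section curve across itself at
    machine scale) are repaired when the repaired area agrees with the
    loop's shoelace area to 1e-6 relative.
    """
    from shapely import make_valid

    polys = []
    for p in polygons:
        arr = _as_point_array(p)
        if len(arr) < 3:
            continue
        poly = Polygon(arr)
        if not poly.is_valid:
            shoelace = abs(0.5 * np.sum(
                arr[:, 0] * np.roll(arr[:, 1], -1)
                - np.roll(arr[:, 0], -1) * arr[:, 1]))
            repaired = make_valid(poly)
            if shoelace == 0 or abs(repaired.area - shoelace) / shoelace > 1e-6:
                raise InvalidRegionError(
                    "self-intersecting polygon handed to a region metric")
            poly = repaired
        polys.append(poly)
    if not polys:
        return Polygon()
    return reduce(lambda a, b: a.symmetric_difference(b), polys)


def overlap_scores(re_polygons, tr_polygons) -> tuple:
    """Dice and Jaccard overlap between two polygonal regions.

    Each argument is a list of closed loops (``(k, 2)`` arrays); nested
    loops are treated as holes.  Areas come from exact polygon clipping.
    """
    re_region = _to_region(re_polygons)
    tr_region = _to_region(tr_polygons)
    a_re = re_region.area
    a_tr = tr_region.area
    inter = re_region.intersection(tr_region).area
    union = re_region.union(tr_region).area
    dice = 2.0 * inter / (a_re + a_tr) if (a_re + a_tr) > 0 else 0.0
    jac = inter / union if union > 0 else 0.0
    return float(dice), float(jac)


# ---------------------------------------------------------------------------
# study-level validation
# ---------------------------------------------------------------------------

def validate_study(surface: TriSurface, contours, metas,
                   views=("2ch", "3ch", "4ch"), hausdorff_step: float = 0.5):
    """Score a reconstruction against the reference contours, per plane.

    For every plane whose view is in ``views``: ``Re`` is the union of the
    mesh/plane section polygons, ``Tr`` the union of the reference contour
    regions on that plane (both in in-plane mm coordinates).  Returns
    ``(records, summary)`` where ``summary`` holds the across-plane means.
    An empty intersection yields ``D = J = 0`` with ``H = nan``.
    """
    by_plane: dict = {}
    for c in contours:
        meta = metas[c.plane_id]
        if meta.view in views:
            by_plane.setdefault(c.plane_id, []).append(c)
    records = []
    for plane_id in sorted(by_plane):
        meta = metas[plane_id]
        tr_loops = []
        for c in by_plane[plane_id]:
            pts3 = project_contour_to_3d(c, meta)
            tr_loops.append(meta.to_plane_coords(pts3))
        re_loops = intersect_mesh_plane(surface, meta)
        if not re_loops:
            records.append(ValidationRecord(plane_id, meta.view, float("nan"), 0.0, 0.0))
            continue
        dice, jac = overlap_scores(re_loops, tr_loops)
        re_pts = np.vstack([resample_polyline(p, hausdorff_step) for p in re_loops])
        tr_pts = np.vstack([resample_polyline(p, hausdorff_step) for p in tr_loops])
        h = hausdorff(re_pts, tr_pts)
        records.append(ValidationRecord(plane_id, meta.view, h, dice, jac))
    summary = summarize(records)
    return records, summary


def summarize(records) -> dict:
    """Per-view and global mean H / D / J, Table-style."""
    out: dict = {"per_view": {}, "mean": {}}
    if not records:
        return out
    views = sorted({r.view for r in records})
    for v in views:
        rs = [r for r in records if r.view == v]
        out["per_view"][v] = {
            "H_mm": float(np.nanmean([r.hausdorff_mm for r in rs])),
            "D": float(np.mean([r.dice for r in rs])),
            "J": float(np.mean([r.jaccard for r in rs])),
        }
    out["mean"] = {
        "H_mm": float(np.nanmean([r.hausdorff_mm for r in records])),
        "D": float(np.mean([r.dice for r in records])),
        "J": float(np.mean([r.jaccard for r in records])),
    }
    return out


def write_report(path, records, case: str = "case") -> None:
    """CSV report: one row per validated plane (case, view, H_mm, D, J)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "plane_id", "view", "H_mm", "D", "J", "adequate"])
        for r in records:
            writer.writerow([
                case, r.plane_id, r.view,
                f"{r.hausdorff_mm:.4f}", f"{r.dice:.6f}", f"{r.jaccard:.6f}",
                int(r.adequate),
            ])
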