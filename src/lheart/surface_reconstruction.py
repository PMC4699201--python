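"""Variational surface reconstruction on a Delaunay tetrahedral mesh.

The densified contour cloud ``C_new`` samples the endocardial surface only
sparsely and anisotropically, so the surface is recovered as the minimizer
of the distance-weighted minimal-surface energy

    E(S) = ∫_S d(x, C_new) dx,

where ``d(x, C_new)`` is the Euclidean distance to the nearest cloud point.
Discretized on a Delaunay tetrahedralization of ``C_new`` plus an auxiliary
lattice ``Q`` (piecewise-constant quadrature: each candidate face
contributes ``Area × d(centroid)``), minimizing E over closed surfaces that
separate known-inside tetrahedra from known-outside ones is an s-t min-cut
problem on the tet adjacency graph: one node per tet, one arc per interior
face with capacity equal to the face's energy contribution, and
infinite-capacity terminal arcs to the seed tets.  The optimal surface is
the set of faces crossing the cut.

Seeds: interior = tetrahedra containing the per-level contour centroids
(endocardial contours are star-shaped about their centroid in practice);
exterior = every tetrahedron with a face on the convex hull.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.spatial import Delaunay, cKDTree

from lheart.contours_io import TriSurface
from lheart.errors import (
    DegenerateGeometryError,
    ResolutionCapError,
    SeedConflictError,
)

_INT_CAP = 2**30  # total integer capacity budget for the max-flow solver
_VOL_EPS = 1e-12


@dataclass
class TetMesh:
    """Delaunay tetrahedral mesh with precomputed face adjacency.

    ``interior_faces`` holds one record per face shared by two tets:
    ``(tet_a, tet_b)`` index pairs in ``face_tets`` and the three vertex
    indices in ``face_vertices``.  ``boundary_faces`` are convex-hull faces
    (single incident tet).
    """

    vertices: np.ndarray          # (nv, 3)
    tets: np.ndarray              # (nt, 4)
    neighbors: np.ndarray         # (nt, 4), -1 = hull
    face_tets: np.ndarray         # (nf, 2)
    face_vertices: np.ndarray     # (nf, 3)
    boundary_faces: np.ndarray    # (nb, 4): tet index + 3 vertex indices
    _locator: Delaunay | None = field(default=None, repr=False)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        a, b, c, d = (v[self.tets[:, i]] for i in range(4))
        return np.abs(np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))) / 6.0

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a = v[self.face_vertices[:, 0]]
        b = v[self.face_vertices[:, 1]]
        c = v[self.face_vertices[:, 2]]
        return np.linalg.norm(np.cross(b - a, c - a), axis=1) / 2.0

    def face_centroids(self) -> np.ndarray:
        v = self.vertices
        return v[self.face_vertices].mean(axis=1)

    def hull_tets(self) -> np.ndarray:
        """Tets with at least one face on the convex hull."""
        return np.flatnonzero((self.neighbors == -1).any(axis=1))

    def locate(self, points) -> np.ndarray:
        """Tet index containing each query point (-1 if outside the hull)."""
        if self._locator is None:
            raise RuntimeError("mesh was built without a point locator")
        return self._locator.find_simplex(np.asarray(points, dtype=float))


@dataclass
class CutLabeling:
    """Binary interior/exterior labeling of the tets and its cut cost."""

    interior: np.ndarray  # (nt,) bool
    cut_cost: float


# ---------------------------------------------------------------------------
# auxiliary grid
# ---------------------------------------------------------------------------

def auxiliary_grid(c_new, h: float, expand_frac: float = 0.1,
                   max_points: int = 400_000, jitter_frac: float = 1e-3,
                   seed: int = 0) -> np.ndarray:
    """Regular lattice of spacing ``h`` covering the cloud bounding box.

    The box is expanded by ``expand_frac`` per side so the convex hull
    encloses the anatomy with margin; lattice points within ``h/2`` of a
    cloud point are dropped (they would duplicate data points).  A tiny
    deterministic jitter (``jitter_frac * h``) breaks the cospherical
    degeneracy a perfect lattice would cause in the Delaunay construction.
    """
    pts = np.asarray(c_new, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("point cloud is empty")
    if h <= 0:
        raise ValueError(f"grid spacing must be positive, got {h}")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, h)  # degenerate boxes get one cell of breadth
    lo = lo - expand_frac * span
    hi = hi + expand_frac * span
    counts = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    if int(np.prod(counts)) > max_points:
        raise ResolutionCapError(
            f"auxiliary grid at h = {h:g} mm would need {int(np.prod(counts))} points "
            f"(cap {max_points}); increase h or the cap"
        )
    axes = [lo[i] + np.arange(counts[i]) * h for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    q = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rng = np.random.default_rng(seed)
    q = q + rng.uniform(-jitter_frac * h, jitter_frac * h, size=q.shape)
    near = cKDTree(pts).query(q, distance_upper_bound=h / 2.0)[0]
    return q[near > h / 2.0]  # inf = no cloud point within h/2


# ---------------------------------------------------------------------------
# Delaunay tetrahedralization
# ---------------------------------------------------------------------------

def tetrahedralize(points) -> TetMesh:
    """Delaunay tetrahedralization of a 3D point set with face adjacency.

    Slivers below ``1e-12`` mm³ are absent by construction for jittered
    input; the union of tets is the convex hull of the points.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 5:
        raise DegenerateGeometryError(f"need >= 5 points for a tet mesh, got {len(points)}")
    if np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-9) < 3:
        raise DegenerateGeometryError("points are coplanar; no tetrahedralization exists")
    tri = Delaunay(points)
    tets = tri.simplices.astype(np.int64)
    neighbors = tri.neighbors.astype(np.int64)

    # Interior faces: neighbor[k] is opposite local vertex k, so the shared
    # face is the tet minus that vertex.  Enumerate each face once (a < b).
    nt = len(tets)
    tet_idx = np.repeat(np.arange(nt), 4)
    nbr = neighbors.ravel()
    local = np.tile(np.arange(4), nt)
    face_cols = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
    verts = tets[tet_idx[:, None], face_cols[local]]

    interior_mask = (nbr != -1) & (nbr > tet_idx)
    face_tets = np.column_stack([tet_idx[interior_mask], nbr[interior_mask]])
    face_vertices = verts[interior_mask]

    bmask = nbr == -1
    boundary_faces = np.column_stack([tet_idx[bmask], verts[bmask]])

    return TetMesh(
        vertices=points,
        tets=tets,
        neighbors=neighbors,
        face_tets=face_tets,
        face_vertices=face_vertices,
        boundary_faces=boundary_faces,
        _locator=tri,
    )


# ---------------------------------------------------------------------------
# face weights (energy quadrature)
# ---------------------------------------------------------------------------

def face_weight(face_points, c_new) -> float:
    """Energy contribution of one triangular face: ``Area × d(centroid, C_new)``."""
    face_points = np.asarray(face_points, dtype=float).reshape(3, 3)
    area = float(np.linalg.norm(np.cross(face_points[1] - face_points[0],
                                         face_points[2] - face_points[0])) / 2.0)
    centroid = face_points.mean(axis=0)
    d = float(cKDTree(np.asarray(c_new, dtype=float).reshape(-1, 3)).query(centroid)[0])
    return area * d


def face_weights(mesh: TetMesh, c_new, d_floor: float = 0.0) -> np.ndarray:
    """Vectorized :func:`face_weight` for every interior face of the mesh.

    ``d_floor`` adds a constant to the distance term, i.e. a small
    area-proportional regularization: among surfaces at (near-)zero distance
    from the cloud it prefers the one with least area, which resolves the
    ties a discrete cut would otherwise break arbitrarily.
    """
    tree = cKDTree(np.asarray(c_new, dtype=float).reshape(-1, 3))
    d = tree.query(mesh.face_centroids())[0]
    return mesh.face_areas() * (d + d_floor)


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def bridge_anchors(anchors, step: float) -> np.ndarray:
    """Connect sparse interior anchors into a dense skeleton.

    A discrete minimal surface happily collapses around isolated seed tets
    (cutting a tiny box per anchor can be cheaper than following the data),
    so the anchors — per-level contour centroids and bifurcation interior
    points — are joined by their Euclidean minimum spanning tree and each
    tree edge is sampled every ``step`` mm.  Seeding every tet along this
    skeleton forces the interior to stay connected from apex to the LA and
    AO tops, which removes the shrinking bias.
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 3)
    if len(anchors) <= 1:
        return anchors
    from scipy.sparse.csgraph import minimum_spanning_tree as mst
    from scipy.spatial.distance import cdist

    dist = cdist(anchors, anchors)
    tree = mst(dist).tocoo()
    samples = [anchors]
    for i, j in zip(tree.row, tree.col):
        a, b = anchors[i], anchors[j]
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.arange(1, n)[:, None] / n
        if len(t):
            samples.append(a * (1 - t) + b * t)
    return np.vstack(samples)


def fill_loop_interior(loop3d, spacing: float, margin: float) -> np.ndarray:
    """Grid-sample the interior of a planar 3D loop, eroded by ``margin``.

    Every delineated or interpolated contour bounds known-inside blood pool;
    marking that area as source keeps the minimal surface from collapsing
    around sparse seeds.  The erosion keeps the samples clear of the cut
    band near the data.
    """
    from shapely import contains_xy
    from shapely.geometry import Polygon

    loop3d = np.asarray(loop3d, dtype=float)
    center = loop3d.mean(axis=0)
    d = loop3d - center
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    xy = np.column_stack([d @ e1, d @ e2])
    poly = Polygon(xy).buffer(-margin)
    if poly.is_empty:
        return np.empty((0, 3))
    lo_x, lo_y, hi_x, hi_y = poly.bounds
    gx = np.arange(lo_x, hi_x + spacing, spacing)
    gy = np.arange(lo_y, hi_y + spacing, spacing)
    if len(gx) == 0 or len(gy) == 0:
        return np.empty((0, 3))
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    keep = contains_xy(poly, xx.ravel(), yy.ravel())
    pts2 = np.column_stack([xx.ravel()[keep], yy.ravel()[keep]])
    return center + pts2[:, 0:1] * e1 + pts2[:, 1:2] * e2


def select_seeds(mesh: TetMesh, anchors) -> tuple:
    """Seed tets for the cut: ``(source_tets, sink_tets)``.

    ``anchors`` are guaranteed-inside points (per-level contour centroids);
    sinks are all convex-hull-adjacent tets.  Raises
    :class:`SeedConflictError` when an anchor lands in a sink tet or outside
    the hull — a sign the auxiliary grid is too coarse.
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 3)
    if len(anchors) == 0:
        raise ValueError("no anchor points supplied")
    loc = mesh.locate(anchors)
    if np.any(loc < 0):
        raise SeedConflictError(
            f"{int((loc < 0).sum())} anchor point(s) fall outside the mesh hull"
        )
    sink = mesh.hull_tets()
    sink_set = set(sink.tolist())
    conflicts = [i for i, t in enumerate(loc) if int(t) in sink_set]
    if conflicts:
        raise SeedConflictError(
            f"{len(conflicts)} anchor(s) landed in hull-adjacent tets (grid too "
            f"coarse), e.g. anchor index {conflicts[0]}"
        )
    source = np.unique(loc)
    return source.astype(np.int64), sink.astype(np.int64)


# ---------------------------------------------------------------------------
# min-cut
# ---------------------------------------------------------------------------

def min_cut(mesh: TetMesh, weights, seeds) -> CutLabeling:
    """Globally minimize the discretized energy by s-t max-flow/min-cut.

    One node per tet plus two terminals; every interior face becomes a
    symmetric arc whose capacity is its energy weight, terminal arcs are
    effectively infinite.  Capacities are scaled to integers for the solver
    (combinatorial max-flow); the reported ``cut_cost`` is re-accumulated
    from the exact float weights of the faces crossing the returned cut, so
    the energy bookkeeping is exact for the labeling found.  Node order is
    the tet index order, making runs reproducible.
    """
    source_tets, sink_tets = seeds
    source_tets = np.asarray(source_tets, dtype=np.int64)
    sink_tets = np.asarray(sink_tets, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    if len(source_tets) == 0 or len(sink_tets) == 0:
        raise ValueError("both seed sets must be non-empty")
    if np.intersect1d(source_tets, sink_tets).size:
        raise ValueError("seed sets overlap")
    if np.any(weights < 0):
        raise ValueError("face weights must be non-negative")
    nt = mesh.n_tets
    s, t = nt, nt + 1

    total = float(weights.sum())
    scale = _INT_CAP / total if total > 0 else 1.0
    cap = np.rint(weights * scale).astype(np.int64)
    inf = np.int64(2**31 - 1)

    fa, fb = mesh.face_tets[:, 0], mesh.face_tets[:, 1]
    rows = np.concatenate([
        fa, fb,
        np.full(len(source_tets), s), source_tets,
        sink_tets, np.full(len(sink_tets), t),
    ])
    cols = np.concatenate([
        fb, fa,
        source_tets, np.full(len(source_tets), s),
        np.full(len(sink_tets), t), sink_tets,
    ])
    data = np.concatenate([
        cap, cap,
        np.full(len(source_tets), inf), np.zeros(len(source_tets), dtype=np.int64),
        np.full(len(sink_tets), inf), np.zeros(len(sink_tets), dtype=np.int64),
    ])
    graph = csr_matrix((data, (rows, cols)), shape=(nt + 2, nt + 2), dtype=np.int32)
    result = maximum_flow(graph, s, t)

    residual = graph - result.flow
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    interior = np.zeros(nt, dtype=bool)
    interior[order[order < nt]] = True

    cut_faces = interior[fa] != interior[fb]
    cut_cost = float(weights[cut_faces].sum())
    if result.flow_value == 0 and not cut_faces.any():
        warnings.warn("seeds are disconnected: trivial cut with zero cost", stacklevel=2)
    return CutLabeling(interior=interior, cut_cost=cut_cost)


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------

def extract_surface(mesh: TetMesh, labeling: CutLabeling,
                    weights=None, max_repair: int = 20,
                    return_labeling: bool = False):
    """Extract the interior/exterior interface as an oriented triangle surface.

    Faces whose two incident tets carry different labels form the surface;
    each is oriented with its normal pointing out of the interior tet.
    Labelings that touch only along an edge produce a non-manifold
    interface; such junctions are repaired by dilating the interior through
    the ring of tets around each offending edge (logged via ``warnings``).
    With ``return_labeling=True`` the (possibly repaired) labeling is
    returned alongside, its ``cut_cost`` re-accumulated from ``weights``.
    """
    interior = labeling.interior.copy()
    for attempt in range(max_repair + 1):
        surf = _interface_surface(mesh, interior)
        bad_edges = _nonmanifold_edges(mesh, interior)
        if not bad_edges:
            if return_labeling:
                fa, fb = mesh.face_tets[:, 0], mesh.face_tets[:, 1]
                cost = (float(np.asarray(weights)[interior[fa] != interior[fb]].sum())
                        if weights is not None else labeling.cut_cost)
                return surf, CutLabeling(interior, cost)
            return surf
        if attempt == max_repair:
            raise DegenerateGeometryError(
                f"could not repair non-manifold interface ({len(bad_edges)} bad edges)"
            )
        interior = _repair_step(mesh, interior, bad_edges)
        warnings.warn(
            f"non-manifold cut interface at {len(bad_edges)} edge(s): dilated the "
            f"interior (pass {attempt + 1})",
            stacklevel=2,
        )
    raise AssertionError("unreachable")


def _interface_surface(mesh: TetMesh, interior: np.ndarray) -> TriSurface:
    fa, fb = mesh.face_tets[:, 0], mesh.face_tets[:, 1]
    cut = interior[fa] != interior[fb]
    tris = []
    verts = mesh.vertices
    for (ta, tb), fv in zip(mesh.face_tets[cut], mesh.face_vertices[cut]):
        tin = ta if interior[ta] else tb
        # vertex of the interior tet not on the face
        opp = [v for v in mesh.tets[tin] if v not in fv][0]
        a, b, c = fv
        n = np.cross(verts[b] - verts[a], verts[c] - verts[a])
        if np.dot(n, verts[opp] - verts[a]) > 0:
            a, b, c = a, c, b  # flip so the normal points away from interior
        tris.append((a, b, c))
    tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
    used = np.unique(tris)
    remap = {int(v): i for i, v in enumerate(used)}
    tris_local = np.vectorize(remap.get)(tris) if len(tris) else tris
    return TriSurface(verts[used] if len(tris) else np.empty((0, 3)), tris_local)


def _nonmanifold_edges(mesh: TetMesh, interior: np.ndarray) -> list:
    """Global vertex-index edges carrying != 2 interface faces."""
    fa, fb = mesh.face_tets[:, 0], mesh.face_tets[:, 1]
    cut = interior[fa] != interior[fb]
    counts: dict = {}
    for tri in mesh.face_vertices[cut]:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            key = (int(min(tri[i], tri[j])), int(max(tri[i], tri[j])))
            counts[key] = counts.get(key, 0) + 1
    return [e for e, c in counts.items() if c != 2]


def _repair_step(mesh: TetMesh, interior: np.ndarray, bad_edges):
    """Dilate the interior through the tet ring around each offending edge.

    Making every (non-hull) tet incident to a pinched edge interior removes
    the edge from the interface entirely; interior growth is monotone, so
    the repair terminates.
    """
    tets = mesh.tets
    hull = np.zeros(len(tets), dtype=bool)
    hull[mesh.hull_tets()] = True
    interior = interior.copy()
    for a, b in bad_edges:
        ring = (tets == a).any(axis=1) & (tets == b).any(axis=1)
        interior[ring & ~hull] = True
    return interior


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def reconstruct_surface(c_new, anchors, h: float, expand_frac: float = 0.1,
                        max_points: int = 400_000, seed: int = 0,
                        d_floor_frac: float = 0.05, fill_points=None):
    """Full reconstruction from a point cloud: grid → Delaunay → cut → surface.

    ``anchors`` are sparse guaranteed-inside points; they are bridged into a
    connected skeleton before seeding (see :func:`bridge_anchors`).
    ``fill_points`` are optional additional guaranteed-inside samples (e.g.
    an eroded fill of each delineated contour's interior) that pre-label the
    bulk of the blood pool, leaving the cut free only in the band near the
    data.  The distance term gets a floor of ``d_floor_frac * h`` (area
    regularization against degenerate ties).  Returns ``(TriSurface, info)``.
    """
    c_new = np.asarray(c_new, dtype=float).reshape(-1, 3)
    q = auxiliary_grid(c_new, h, expand_frac=expand_frac,
                       max_points=max_points, seed=seed)
    mesh = tetrahedralize(np.vstack([c_new, q]))
    w = face_weights(mesh, c_new, d_floor=d_floor_frac * h)
    skeleton = bridge_anchors(anchors, step=h / 2.0)
    if fill_points is not None and len(fill_points):
        skeleton = np.vstack([skeleton, np.asarray(fill_points, dtype=float)])
    seeds = select_seeds(mesh, skeleton)
    labeling = min_cut(mesh, w, seeds)
    surface = extract_surface(mesh, labeling)
    info = {
        "n_cloud_points": len(c_new),
        "n_grid_points": len(q),
        "n_tets": mesh.n_tets,
        "n_interior_tets": int(labeling.interior.sum()),
        "cut_cost": labeling.cut_cost,
        "n_surface_faces": len(surface.triangles),
        "h_mm": h,
    }
    return surface, info
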