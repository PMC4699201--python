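"""Synthetic left-heart phantom: analytic shape, virtual acquisition, motion.

The phantom is an implicit solid built from three primitives arranged like
the left cardiac blood pool:

* **LV** — a prolate ellipsoid (apex down, long axis = z);
* **LA** — a smaller ellipsoid above the base plane, laterally offset;
* **AO** — a tube of circular cross-section along a circular-arc centerline
  leaving the LV outflow region and bending away from the long axis.

The three signed quasi-distance fields are combined with a smooth-min blend
so the junction region genuinely merges, which makes virtual short-axis
slices exhibit the three cases seen in clinical delineations: LV-only
contours, separate LA + AO contours, and a single merged contour at the
inflow/outflow bifurcation.

A virtual acquisition slices the solid into a parallel short-axis stack
(8 mm spacing, no gap) plus three long-axis planes orthogonal to the stack
(in-plane rotations 0°/60°/120° about the long axis, standing in for the
3-/2-/4-chamber views), all at 1.43 mm pixel spacing.  Optional per-plane
rigid perturbations emulate breath-hold misalignment and come with their
ground-truth transforms for registration recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely import contains_xy
from skimage.measure import find_contours, marching_cubes

from lheart.contours_io import LabeledContour2D, PlaneMeta, TriSurface
from lheart.errors import InvalidSpecError
from lheart.registration import RigidTransform


@dataclass
class PhantomSpec:
    """Geometry of the analytic left-heart solid (all lengths mm)."""

    lv_semiaxes: tuple = (25.0, 25.0, 40.0)
    la_semiaxes: tuple = (16.0, 16.0, 18.0)
    ao_radius: float = 9.0
    ao_length: float = 40.0
    base_plane_offset: float = 35.0
    blend_radius: float = 5.0
    la_lateral_offset: float = -15.0
    ao_arc_radius: float = 80.0
    seed: int = 0

    def __post_init__(self):
        lengths = (*self.lv_semiaxes, *self.la_semiaxes, self.ao_radius,
                   self.ao_length, self.blend_radius, self.ao_arc_radius)
        if any(x <= 0 for x in lengths):
            raise InvalidSpecError("all phantom lengths must be positive")

    # derived placement ---------------------------------------------------
    @property
    def lv_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.base_plane_offset - self.lv_semiaxes[2]])

    @property
    def la_center(self) -> np.ndarray:
        return np.array([
            self.la_lateral_offset, 0.0,
            self.base_plane_offset + self.la_semiaxes[2] / 2.0,
        ])

    @property
    def ao_start(self) -> np.ndarray:
        return np.array([15.0, 0.0, self.base_plane_offset - 13.0])


@dataclass
class AcquisitionGeometry:
    """Virtual scanner geometry for :func:`slice_study`.

    The in-plane origins are deliberately offset by sub-pixel amounts and
    the long-axis view angles are irregular: a perfectly centered, mirror-
    symmetric layout creates exact nearest-neighbour ties between the pixel
    grids of different planes — a measure-zero degeneracy no real scan
    exhibits — which would make registration results depend on tie-breaking.
    """

    sax_spacing: float = 8.0          # inter-slice distance, no gap
    pixel_spacing: float = 1.43       # mm / pixel
    n_pixels: int = 96
    sax_z: tuple = tuple(np.arange(-48.0, 64.0 + 1e-9, 8.0))
    sax_origin_offset: tuple = (0.37, -0.53)
    lax_views: dict = field(default_factory=lambda: {"3ch": 8.0, "2ch": 63.0, "4ch": 122.0})
    lax_origin_offset: tuple = (0.29, -0.41)
    lax_z_min: float = -56.0
    lax_n_v: int = 96


# ---------------------------------------------------------------------------
# implicit solid
# ---------------------------------------------------------------------------

def _ellipsoid_field(points, center, semiaxes):
    d = (np.asarray(points, dtype=float) - center) / np.asarray(semiaxes, dtype=float)
    r = np.linalg.norm(d, axis=-1)
    return (r - 1.0) * min(semiaxes)


def _arc_tube_field(points, start, arc_radius, arc_angle, tube_radius):
    """Signed distance to a tube around a circular arc in the y = start_y
    plane, bending from vertical towards +x; clamped ends give spherical caps."""
    p = np.asarray(points, dtype=float)
    cx = start[0] + arc_radius
    cz = start[2]
    u = cx - p[..., 0]
    w = p[..., 2] - cz
    theta = np.clip(np.arctan2(w, u), 0.0, arc_angle)
    qx = cx - arc_radius * np.cos(theta)
    qz = cz + arc_radius * np.sin(theta)
    dist = np.sqrt((p[..., 0] - qx) ** 2 + (p[..., 1] - start[1]) ** 2
                   + (p[..., 2] - qz) ** 2)
    return dist - tube_radius


def _smooth_min(a, b, k):
    h = np.maximum(k - np.abs(a - b), 0.0) / k
    return np.minimum(a, b) - h * h * k / 4.0


def implicit_components(spec: PhantomSpec) -> dict:
    """Per-structure signed fields (negative inside), keyed LV / LA / AO."""
    arc_angle = spec.ao_length / spec.ao_arc_radius
    return {
        "LV": lambda p: _ellipsoid_field(p, spec.lv_center, spec.lv_semiaxes),
        "LA": lambda p: _ellipsoid_field(p, spec.la_center, spec.la_semiaxes),
        "AO": lambda p: _arc_tube_field(p, spec.ao_start, spec.ao_arc_radius,
                                        arc_angle, spec.ao_radius),
    }


def implicit_shape(spec: PhantomSpec):
    """Blended scalar field of the whole solid: ``f < 0`` inside.

    Raises :class:`InvalidSpecError` if the components do not mutually
    overlap at the junctions (checked by sign sampling along the segments
    joining the component centers).
    """
    comps = implicit_components(spec)
    k = spec.blend_radius

    def f(points):
        points = np.asarray(points, dtype=float)
        val = _smooth_min(comps["LV"](points), comps["LA"](points), k)
        return _smooth_min(val, comps["AO"](points), k)

    _check_overlap(spec, comps)
    return f


def _check_overlap(spec: PhantomSpec, comps: dict) -> None:
    t = np.linspace(0.0, 1.0, 200)[:, None]
    for other, target in (("LA", spec.la_center), ("AO", spec.ao_start)):
        seg = spec.lv_center * (1 - t) + target * t
        both = (comps["LV"](seg) < 0) & (comps[other](seg) < 0)
        if not both.any():
            raise InvalidSpecError(
                f"LV and {other} do not overlap; junction slices cannot merge"
            )


# ---------------------------------------------------------------------------
# ground-truth surface
# ---------------------------------------------------------------------------

def _field_bounds(f, probe_half_extent: float = 130.0, step: float = 4.0):
    ax = np.arange(-probe_half_extent, probe_half_extent + step, step)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    inside = f(pts.reshape(-1, 3)).reshape(gx.shape) < 0
    if not inside.any():
        raise InvalidSpecError("implicit solid is empty")
    idx = np.argwhere(inside)
    lo = np.array([ax[idx[:, k].min()] for k in range(3)])
    hi = np.array([ax[idx[:, k].max()] for k in range(3)])
    return lo - step, hi + step


def ground_truth_mesh(spec: PhantomSpec, resolution: float = 1.0) -> TriSurface:
    """Marching-cubes surface of the zero level set (watertight)."""
    f = implicit_shape(spec)
    lo, hi = _field_bounds(f)
    pad = 2.0 * resolution
    for _ in range(2):
        lo_p, hi_p = lo - pad, hi + pad
        axes = [np.arange(lo_p[k], hi_p[k] + resolution, resolution) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        vol = f(np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)).reshape(gx.shape)
        verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(resolution,) * 3)
        # marching cubes on a closed level set yields a welded, watertight,
        # outward-oriented mesh; no vertex merging needed (merging by
        # tolerance can create degenerate faces)
        surf = TriSurface(verts + lo_p, faces)
        if surf.is_watertight():
            return surf
        pad = pad + 10.0  # surface clipped by the domain: expand and retry
    surf.check_watertight()
    return surf


# ---------------------------------------------------------------------------
# virtual acquisition
# ---------------------------------------------------------------------------

def _plane_grid_field(f, meta: PlaneMeta, n_u: int, n_v: int) -> np.ndarray:
    u = np.arange(n_u) * meta.spacing[0]
    v = np.arange(n_v) * meta.spacing[1]
    uu, vv = np.meshgrid(u, v, indexing="ij")  # A[u, v]
    pts = (meta.position
           + uu[..., None] * meta.row_dir
           + vv[..., None] * meta.col_dir)
    return f(pts.reshape(-1, 3)).reshape(n_u, n_v)


def _contours_on_plane(f, comps, meta: PlaneMeta, n_u: int, n_v: int,
                       boundary_fraction: float = 0.1):
    """Zero-level contours of ``f`` on one plane, labeled by the components
    that shape their boundary (two or more present -> MERGED)."""
    a = _plane_grid_field(f, meta, n_u, n_v)
    raw = find_contours(a, 0.0)
    out = []
    for arr in raw:
        if len(arr) < 8 or not np.allclose(arr[0], arr[-1]):
            continue  # open chain clipped by the field of view
        uv = arr[:-1]  # drop duplicated closing point; already (u, v) order
        keep = np.ones(len(uv), dtype=bool)
        keep[1:] = np.any(np.diff(uv, axis=0) != 0, axis=1)
        uv = uv[keep]
        if len(uv) < 3:
            continue
        pts3 = (meta.position
                + np.outer(uv[:, 0] * meta.spacing[0], meta.row_dir)
                + np.outer(uv[:, 1] * meta.spacing[1], meta.col_dir))
        vals = np.column_stack([comps[k](pts3) for k in ("LV", "LA", "AO")])
        owner = np.argmin(vals, axis=1)
        fractions = np.bincount(owner, minlength=3) / len(owner)
        present = [k for k, fr in zip(("LV", "LA", "AO"), fractions)
                   if fr >= boundary_fraction]
        label = present[0] if len(present) == 1 else "MERGED"
        out.append(LabeledContour2D(points=uv, label=label,
                                    plane_id=meta.plane_id, closed=True))
    return out


def slice_study(spec: PhantomSpec, geometry: AcquisitionGeometry | None = None):
    """Slice the phantom into a contour study.

    Returns ``(contours, metas)`` in the study-file structure: a short-axis
    stack plus three long-axis planes, every contour in pixel coordinates
    against its plane's metadata.  Planes that miss the solid are omitted.
    """
    geometry = geometry or AcquisitionGeometry()
    f = implicit_shape(spec)
    comps = implicit_components(spec)
    n = geometry.n_pixels
    dp = geometry.pixel_spacing
    half = 0.5 * (n - 1) * dp
    contours, metas = [], {}
    ox, oy = geometry.sax_origin_offset
    for i, z in enumerate(geometry.sax_z):
        meta = PlaneMeta(
            position=(-half + ox, -half + oy, float(z)),
            row_dir=(1.0, 0.0, 0.0),
            col_dir=(0.0, 1.0, 0.0),
            spacing=(dp, dp),
            plane_id=f"sax{i:02d}",
            view="sax",
        )
        found = _contours_on_plane(f, comps, meta, n, n)
        if found:
            metas[meta.plane_id] = meta
            contours.extend(found)
    for view, angle_deg in geometry.lax_views.items():
        phi = np.radians(angle_deg)
        row = np.array([np.cos(phi), np.sin(phi), 0.0])
        lx, ly = geometry.lax_origin_offset
        meta = PlaneMeta(
            position=tuple(-half * row + np.array([lx, ly, geometry.lax_z_min])),
            row_dir=tuple(row),
            col_dir=(0.0, 0.0, 1.0),
            spacing=(dp, dp),
            plane_id=f"lax_{view}",
            view=view,
        )
        found = _contours_on_plane(f, comps, meta, n, geometry.lax_n_v)
        if found:
            metas[meta.plane_id] = meta
            contours.extend(found)
    return contours, metas


# ---------------------------------------------------------------------------
# breath-hold perturbation
# ---------------------------------------------------------------------------

def _random_rigid(rng, max_shift_mm, max_rot_deg, about) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rot_deg))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = direction * rng.uniform(0.0, max_shift_mm)
    rot = RigidTransform.from_axis_angle(axis, angle).rotation
    about = np.asarray(about, dtype=float)
    return RigidTransform(rot, about - rot @ about + shift)


def perturb(contours, metas, max_shift_mm: float, max_rot_deg: float, seed: int = 0):
    """Rigidly misalign each long-axis plane (the short-axis stack is the
    registration reference and stays fixed).

    The per-plane transform rotates about the plane's contour centroid
    (breath-hold-like motion) and is drawn uniformly within the bounds,
    deterministically per ``seed``.  Returns ``(contours, new_metas,
    truth)`` where ``truth`` maps view -> the applied
    :class:`RigidTransform` in patient coordinates.
    """
    if max_shift_mm < 0 or max_rot_deg < 0:
        raise ValueError("perturbation bounds must be non-negative")
    rng = np.random.default_rng(seed)
    new_metas = dict(metas)
    truth = {}
    for plane_id in sorted(metas):
        meta = metas[plane_id]
        if meta.view == "sax":
            continue
        own = [c for c in contours if c.plane_id == plane_id]
        pts3 = []
        for c in own:
            uv = c.points
            pts3.append(meta.position
                        + np.outer(uv[:, 0] * meta.spacing[0], meta.row_dir)
                        + np.outer(uv[:, 1] * meta.spacing[1], meta.col_dir))
        center = np.vstack(pts3).mean(axis=0) if pts3 else meta.position
        t = _random_rigid(rng, max_shift_mm, max_rot_deg, about=center)
        new_metas[plane_id] = PlaneMeta(
            position=t.apply(meta.position[None])[0],
            row_dir=t.rotation @ meta.row_dir,
            col_dir=t.rotation @ meta.col_dir,
            spacing=meta.spacing,
            plane_id=meta.plane_id,
            view=meta.view,
        )
        truth[meta.view] = t
    return list(contours), new_metas, truth


# ---------------------------------------------------------------------------
# reference sections for validation tests
# ---------------------------------------------------------------------------

def analytic_section_polygons(spec: PhantomSpec, meta: PlaneMeta,
                              n_u: int = 192, n_v: int = 192):
    """High-resolution true cross-section of the solid on a plane, as closed
    in-plane mm polygons (independent of the study's contour sampling)."""
    f = implicit_shape(spec)
    comps = implicit_components(spec)
    fine = PlaneMeta(
        position=meta.position,
        row_dir=meta.row_dir,
        col_dir=meta.col_dir,
        spacing=(meta.spacing[0] / 2.0, meta.spacing[1] / 2.0),
        plane_id=meta.plane_id,
        view=meta.view,
    )
    found = _contours_on_plane(f, comps, fine, n_u, n_v)
    return [c.points * np.array(fine.spacing) for c in found]


def contour_interior_point(points_uv) -> np.ndarray:
    """A point strictly inside a closed pixel-coordinate contour."""
    poly = Polygon(points_uv)
    rp = poly.representative_point()
    assert contains_xy(poly, rp.x, rp.y)
    return np.array([rp.x, rp.y])
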