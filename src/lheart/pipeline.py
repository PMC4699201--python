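"""End-to-end reconstruction pipeline.

Stage order: read study → project contours to 3D → register long-axis
clouds to the short-axis cloud → densify the parallel short-axis groups →
assemble the joint cloud → Delaunay mesh + graph-cut surface → post-process
→ validate against the long-axis reference contours.

Every stage is also available as a library function; this module only wires
them together with a validated configuration and structured logging.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from lheart import contour_processing, contours_io, registration, surface_reconstruction
from lheart.contours_io import TriSurface
from lheart.postprocess import remesh, smooth
from lheart.validation import validate_study

log = logging.getLogger("lheart")


@dataclass
class RegistrationConfig:
    enabled: bool = True
    alpha: float = 0.35
    max_iter: int = 100
    tol: float = 1e-6
    trim_fraction: float = 0.5


@dataclass
class InterpConfig:
    n: int = 64                       # points per resampled contour
    target_spacing_mm: float | None = None  # inter-level spacing; None = auto
    m: int | None = None              # explicit level count (overrides spacing)


@dataclass
class ReconConfig:
    h_mm: float | None = None         # auxiliary-grid spacing; None = auto
    grid_expand_frac: float = 0.1
    max_points: int = 400_000


@dataclass
class PostConfig:
    enabled: bool = True
    smooth_iters: int = 10
    lam: float = 0.5
    mu: float = -0.53
    target_edge_mm: float | None = None  # None = skip remeshing


@dataclass
class PipelineConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    interp: InterpConfig = field(default_factory=InterpConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    post: PostConfig = field(default_factory=PostConfig)
    seed: int = 0

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        """Build a config from nested dicts, rejecting unknown keys."""
        sections = {
            "registration": RegistrationConfig,
            "interp": InterpConfig,
            "recon": ReconConfig,
            "post": PostConfig,
        }
        cfg = PipelineConfig()
        for key, value in data.items():
            if key == "seed":
                cfg.seed = int(value)
            elif key in sections:
                cls = sections[key]
                known = set(cls.__dataclass_fields__)
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {key!r}")
                setattr(cfg, key, cls(**value))
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cfg

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    surface: TriSurface
    raw_surface: TriSurface
    records: list
    summary: dict
    info: dict
    transforms: dict
    diagnostics: dict
    warnings: list


def _interior_point_3d(contour, meta) -> np.ndarray:
    """A guaranteed-inside point of a planar contour, in patient coordinates."""
    from shapely.geometry import Polygon

    rp = Polygon(contour.points).representative_point()
    return (meta.position
            + rp.x * meta.spacing[0] * meta.row_dir
            + rp.y * meta.spacing[1] * meta.col_dir)


def _median_nn_spacing(points: np.ndarray) -> float:
    if len(points) < 2:
        return 1.0
    d = cKDTree(points).query(points, k=2)[0][:, 1]
    return float(np.median(d))


def reconstruct(contours, metas, config: PipelineConfig | None = None,
                validation_contours=None, validation_metas=None) -> PipelineResult:
    """Run the full chain on a study and score the result.

    ``validation_contours`` / ``validation_metas`` default to the input
    study; pass a pristine study here to score a reconstruction of a
    motion-perturbed study against the true geometry.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    run_warnings: list = []

    # --- stage 1: project ------------------------------------------------
    clouds = contours_io.project_study_to_clouds(contours, metas)
    c_sax = clouds["sax"]
    if len(c_sax) == 0:
        raise ValueError("study has no short-axis contours")
    sax_meta = next(m for m in metas.values() if m.view == "sax")
    sax_normal = sax_meta.normal
    log.info(json.dumps({"stage": "project",
                         "points": {v: len(clouds[v]) for v in clouds}}))

    # --- stage 2: register -----------------------------------------------
    transforms: dict = {}
    diagnostics: dict = {}
    lax_points: dict = {}
    for view in ("2ch", "3ch", "4ch"):
        cloud = clouds[view]
        if len(cloud) == 0:
            run_warnings.append(f"no {view} contours; view skipped")
            continue
        if config.registration.enabled:
            t, diag = registration.register_pair(
                c_sax.points, cloud.points,
                alpha=config.registration.alpha,
                max_iter=config.registration.max_iter,
                tol=config.registration.tol,
                trim_fraction=config.registration.trim_fraction,
                pair=f"sax-{view}",
            )
            transforms[view] = t
            diagnostics[view] = diag
            lax_points[view] = t.apply(cloud.points)
            log.info(json.dumps({"stage": "register", **diag.as_dict()}))
        else:
            transforms[view] = registration.RigidTransform.identity()
            lax_points[view] = cloud.points

    # --- stage 3: densify short-axis groups ------------------------------
    sax_contours3d = []
    merged_points = []
    merged_anchors = []
    for c in contours:
        meta = metas[c.plane_id]
        if meta.view != "sax":
            continue
        pts3 = contours_io.project_contour_to_3d(c, meta)
        if c.label == "MERGED":
            merged_points.append(pts3)
            merged_anchors.append(_interior_point_3d(c, meta))
        else:
            sax_contours3d.append((c.label, pts3))
    target = config.interp.target_spacing_mm
    if target is None:
        # tie the level spacing to the intra-contour point spacing after
        # resampling to n points
        per = [np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1).sum()
               for _, p in sax_contours3d]
        target = float(np.median(per)) / config.interp.n if per else 2.0
    matrices, warns = contour_processing.densify_groups(
        sax_contours3d, sax_normal, n=config.interp.n,
        target_spacing_mm=target, m=config.interp.m,
    )
    run_warnings.extend(warns)
    log.info(json.dumps({"stage": "densify",
                         "groups": {k: list(m.shape) for k, m in matrices.items()},
                         "warnings": warns}))

    # --- stage 4: assemble C_new -----------------------------------------
    parts = [m.flat_points() for m in matrices.values()]
    parts.extend(merged_points)
    densified_labels = set(matrices)
    for label, pts3 in sax_contours3d:
        if label not in densified_labels:
            parts.append(pts3)  # pass-through group (< 2 contours)
    parts.extend(lax_points.values())
    c_new = np.vstack(parts)
    anchor_parts = [m.row_centroids() for m in matrices.values()]
    if merged_anchors:
        anchor_parts.append(np.vstack(merged_anchors))
    anchors = np.vstack(anchor_parts)

    # --- stage 5: reconstruct ---------------------------------------------
    h = config.recon.h_mm
    if h is None:
        # ~2.5 nearest-neighbour spacings: fine enough to resolve the
        # inter-structure gaps, coarse enough to keep the tet count moderate
        h = float(np.clip(2.5 * _median_nn_spacing(c_new), 2.0, 6.0))
    fill_loops = [m.points[i] for m in matrices.values() for i in range(m.points.shape[0])]
    fill_loops.extend(merged_points)
    fills = [surface_reconstruction.fill_loop_interior(loop, spacing=h, margin=h)
             for loop in fill_loops]
    fills = [f for f in fills if len(f)]
    fill_points = np.vstack(fills) if fills else None
    raw_surface, info = surface_reconstruction.reconstruct_surface(
        c_new, anchors, h,
        expand_frac=config.recon.grid_expand_frac,
        max_points=config.recon.max_points,
        seed=config.seed,
        fill_points=fill_points,
    )
    log.info(json.dumps({"stage": "reconstruct", **{k: float(v) for k, v in info.items()}}))

    # --- stage 6: post-process --------------------------------------------
    surface = raw_surface
    if config.post.enabled:
        surface = smooth(surface, iterations=config.post.smooth_iters,
                         lam=config.post.lam, mu=config.post.mu)
        if config.post.target_edge_mm is not None:
            surface = remesh(surface, config.post.target_edge_mm)
        log.info(json.dumps({"stage": "postprocess",
                             "vertices": len(surface.vertices),
                             "faces": len(surface.triangles)}))

    # --- stage 7: validate -------------------------------------------------
    v_contours = validation_contours if validation_contours is not None else contours
    v_metas = validation_metas if validation_metas is not None else metas
    records, summary = validate_study(surface, v_contours, v_metas)
    info["runtime_s"] = time.time() - t0
    info["validation_planes"] = len(records)
    log.info(json.dumps({"stage": "validate", "summary": summary}))

    return PipelineResult(
        surface=surface,
        raw_surface=raw_surface,
        records=records,
        summary=summary,
        info=info,
        transforms=transforms,
        diagnostics={k: d.as_dict() for k, d in diagnostics.items()},
        warnings=run_warnings,
    )
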