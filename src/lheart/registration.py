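"""Rigid registration of long-axis contour clouds to the short-axis cloud.

Breath-hold motion shifts each long-axis acquisition rigidly with respect to
the short-axis stack.  Because a long-axis contour and the short-axis cloud
overlap only along a narrow band, plain ICP is fed with *mutual subsets*
first: points farther than a tolerance ``ε`` from the other cloud are
removed, iterating until stable.  With ``ε = α·d_H`` (``d_H`` the Hausdorff
distance between the original clouds, ``α`` in the empirical 0.2–0.5 band)
the filtered subsets satisfy:

1. ``d_H(C_X', C_Y') <= ε``;
2. ``ε >= d_H(C_X, C_Y)`` implies nothing is removed;
3. subsets grow monotonically with ``ε``.

Point-to-point ICP with a closed-form orthogonal-Procrustes (Kabsch) update
then aligns the filtered moving subset to the fixed short-axis subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from lheart.errors import DegenerateGeometryError, EpsilonTooSmallError

@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + v``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is a reflection (det = -1)")
        # keep long compositions drift-free
        u, _, vt = np.linalg.svd(r)
        self.rotation = u @ vt

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_axis_angle(axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)
        return RigidTransform(rot, translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def apply_rigid(transform: RigidTransform, points) -> np.ndarray:
    """Apply ``p -> R p + v`` to an ``(n, 3)`` array of points."""
    return transform.apply(points)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _as_points(arr) -> np.ndarray:
    return np.asarray(arr, dtype=float).reshape(-1, 3)


def hausdorff_distance(x, y) -> float:
    """Symmetric Hausdorff distance between two 3D point sets."""
    x, y = _as_points(x), _as_points(y)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateGeometryError("Hausdorff distance of an empty set is undefined")
    dxy = cKDTree(y).query(x)[0].max()
    dyx = cKDTree(x).query(y)[0].max()
    return float(max(dxy, dyx))


# ---------------------------------------------------------------------------
# Mutual subset filtering
# ---------------------------------------------------------------------------

def mutual_subset(c_x, c_y, epsilon: float, return_indices: bool = False):
    """Iteratively strip points farther than ``epsilon`` from the other cloud.

    Starting from the full clouds, each sweep removes the outlier sets
    ``O_X = {x : d(x, C_Y') > ε}`` and ``O_Y = {y : d(y, C_X') > ε}`` and
    repeats until both are empty.  The survivors are mutually ε-close, hence
    ``d_H(C_X', C_Y') <= ε``.

    Raises
    ------
    EpsilonTooSmallError
        If either subset empties out before the loop stabilizes.
    """
    c_x, c_y = _as_points(c_x), _as_points(c_y)
    if len(c_x) == 0 or len(c_y) == 0:
        raise EpsilonTooSmallError("input cloud is empty", last_sizes=(len(c_x), len(c_y)))
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    keep_x = np.arange(len(c_x))
    keep_y = np.arange(len(c_y))
    while True:
        d_x = cKDTree(c_y[keep_y]).query(c_x[keep_x])[0]
        d_y = cKDTree(c_x[keep_x]).query(c_y[keep_y])[0]
        out_x = d_x > epsilon
        out_y = d_y > epsilon
        if not out_x.any() and not out_y.any():
            break
        new_x = keep_x[~out_x]
        new_y = keep_y[~out_y]
        if len(new_x) == 0 or len(new_y) == 0:
            raise EpsilonTooSmallError(
                f"mutual-subset filtering emptied a cloud at epsilon = {epsilon:g} mm "
                f"(last non-empty sizes {len(keep_x)}, {len(keep_y)})",
                last_sizes=(len(keep_x), len(keep_y)),
            )
        keep_x, keep_y = new_x, new_y
    if return_indices:
        return c_x[keep_x], c_y[keep_y], keep_x, keep_y
    return c_x[keep_x], c_y[keep_y]


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

def _kabsch(moving: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid alignment of paired point sets, with
    the standard det = -1 reflection guard."""
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (moving - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    return RigidTransform(rot, mu_t - rot @ mu_m)


def icp_rigid(reference, moving, max_iter: int = 100, tol: float = 1e-6,
              trim_fraction: float = 0.5):
    """Point-to-point ICP of ``moving`` onto the fixed ``reference`` cloud.

    Alternates nearest-neighbour correspondence (k-d tree; ties resolved to
    the lowest point index) with a closed-form Kabsch update, starting from
    the identity.  Stops when the trimmed RMS correspondence distance
    changes by less than ``tol`` mm or after ``max_iter`` sweeps.

    ``trim_fraction`` is the fraction of moving points with the smallest
    correspondence distances used in each update (trimmed ICP).  On
    cross-plane cardiac contour clouds the reference is sampled on slices
    8 mm apart, so moving points over the inter-slice gaps have no true
    counterpart; matching them anyway drags the fit towards the slices.
    Keeping the closest half restricts the update to the plane-crossing
    regions where genuine correspondences exist.  ``trim_fraction = 1``
    recovers the classic Besl–McKay iteration.

    Returns
    -------
    (RigidTransform, list of float)
        The cumulative transform and the per-iteration trimmed-RMS history
        (element 0 is the value at the identity).  The history is
        non-increasing: both ICP half-steps minimize the same functional.
    """
    reference = _as_points(reference)
    moving = _as_points(moving)
    if len(reference) < 3 or len(moving) < 3:
        raise DegenerateGeometryError("ICP needs >= 3 points in both clouds")
    if not (0 < trim_fraction <= 1):
        raise ValueError(f"trim_fraction must be in (0, 1], got {trim_fraction}")
    if np.linalg.matrix_rank(moving - moving.mean(axis=0), tol=1e-9) < 2:
        raise DegenerateGeometryError("moving cloud is collinear or coincident")
    k = max(int(round(trim_fraction * len(moving))), 3)
    tree = cKDTree(reference)
    transform = RigidTransform.identity()
    current = moving.copy()

    def trimmed(dist):
        return float(np.sqrt(np.mean(np.sort(dist)[:k] ** 2)))

    dist, idx = tree.query(current)
    history = [trimmed(dist)]
    for _ in range(max_iter):
        sel = np.argsort(dist)[:k]
        step = _kabsch(current[sel], reference[idx[sel]])
        transform = step.compose(transform)
        current = transform.apply(moving)
        dist, idx = tree.query(current)
        history.append(trimmed(dist))
        if abs(history[-2] - history[-1]) < tol:
            break
    return transform, history


# ---------------------------------------------------------------------------
# Pairwise / study-level drivers
# ---------------------------------------------------------------------------

@dataclass
class RegistrationDiagnostics:
    pair: str
    epsilon: float
    subset_size_ref: int
    subset_size_mov: int
    iterations: int
    rms_before: float
    rms_after: float
    hausdorff_before: float
    hausdorff_after: float
    history: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "pair": self.pair,
            "epsilon_mm": self.epsilon,
            "subset_size_ref": self.subset_size_ref,
            "subset_size_mov": self.subset_size_mov,
            "iterations": self.iterations,
            "rms_before_mm": self.rms_before,
            "rms_after_mm": self.rms_after,
            "hausdorff_before_mm": self.hausdorff_before,
            "hausdorff_after_mm": self.hausdorff_after,
        }


def register_pair(c_sax, c_lax, alpha: float = 0.35, max_iter: int = 100,
                  tol: float = 1e-6, trim_fraction: float = 0.5,
                  pair: str = "pair"):
    """Register one long-axis cloud to the short-axis reference.

    Sets ``ε = α · d_H(C_sax, C_lax)``, filters both clouds with
    :func:`mutual_subset`, and runs ICP with the filtered short-axis subset
    fixed as reference.  Returns ``(RigidTransform, RegistrationDiagnostics)``.
    """
    if not (0.2 <= alpha <= 0.5):
        raise ValueError(f"alpha must lie in [0.2, 0.5], got {alpha}")
    c_sax = _as_points(c_sax)
    c_lax = _as_points(c_lax)
    d_h0 = hausdorff_distance(c_sax, c_lax)
    epsilon = alpha * d_h0
    sub_ref, sub_mov = mutual_subset(c_sax, c_lax, epsilon)
    transform, history = icp_rigid(sub_ref, sub_mov, max_iter=max_iter, tol=tol,
                                   trim_fraction=trim_fraction)
    moved = transform.apply(sub_mov)
    diag = RegistrationDiagnostics(
        pair=pair,
        epsilon=float(epsilon),
        subset_size_ref=len(sub_ref),
        subset_size_mov=len(sub_mov),
        iterations=len(history) - 1,
        rms_before=history[0],
        rms_after=history[-1],
        hausdorff_before=hausdorff_distance(sub_ref, sub_mov),
        hausdorff_after=hausdorff_distance(sub_ref, moved),
        history=history,
    )
    return transform, diag


def register_study(c_sax, c_2ch, c_3ch, c_4ch, alpha: float = 0.35,
                   max_iter: int = 100, tol: float = 1e-6,
                   trim_fraction: float = 0.5):
    """Register all three long-axis clouds to the (fixed) short-axis cloud.

    The three pairs {sax, 2ch}, {sax, 3ch}, {sax, 4ch} are handled
    independently — the short-axis subset selected for each pair may differ.

    Returns ``(moved_clouds, transforms, diagnostics)`` where each item is a
    dict keyed by ``"2ch"``/``"3ch"``/``"4ch"``.
    """
    laxes = {"2ch": c_2ch, "3ch": c_3ch, "4ch": c_4ch}
    moved, transforms, diags = {}, {}, {}
    for view, cloud in laxes.items():
        try:
            t, diag = register_pair(
                c_sax, cloud, alpha=alpha, max_iter=max_iter, tol=tol,
                trim_fraction=trim_fraction, pair=f"sax-{view}",
            )
        except Exception as exc:
            raise type(exc)(f"registration of pair {{sax, {view}}} failed: {exc}") from exc
        moved[view] = t.apply(_as_points(cloud))
        transforms[view] = t
        diags[view] = diag
    return moved, transforms, diags
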