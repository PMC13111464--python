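"""Stem diameter at a fixed height above the plant base.

The stem cloud is sliced in a thin slab 10 mm above its base (seedling stems
taper, so the measurement height is fixed), an oriented bounding box aligns
the slab's principal axes with the coordinate frame, the aligned slab is
projected to a plane, and a least-squares circle (x - a)^2 + (y - b)^2 = r^2
is fitted; the stem diameter is d = 2r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OrientedBoundingBox",
    "CircleFit",
    "StemDiameterConfig",
    "slice_at_height",
    "compute_obb",
    "align_with_obb",
    "fit_circle",
    "stem_diameter",
]


@dataclass
class OrientedBoundingBox:
    """Rotation R (orthogonal, det +1), center, and half-extents in mm.

    R's columns are the covariance eigenvectors ordered by decreasing
    eigenvalue; applying R^T maps the content's principal axes onto the
    coordinate axes.
    """

    rotation: np.ndarray
    center: np.ndarray
    half_extents: np.ndarray

    @property
    def volume(self) -> float:
        return float(np.prod(2 * self.half_extents))


@dataclass
class CircleFit:
    center: tuple[float, float]
    radius: float
    rms_residual: float      # RMS of (distance to center - r)
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class StemDiameterConfig:
    """Measurement geometry: height above base (10 mm by field convention),
    slab half-thickness, projection plane, and circle-fit refinement."""

    height_mm: float = 10.0
    slab_half_thickness_mm: float = 2.5
    height_axis: int = 2                       # z is up
    projection: str = "auto"                   # XOY | XOZ | auto (cross-section)
    refine: bool = True
    straighten: bool = True                    # rotate the stem axis upright first

    def __post_init__(self) -> None:
        if self.slab_half_thickness_mm <= 0:
            raise ValueError("slab half-thickness must be positive")
        if self.projection not in ("XOY", "XOZ", "auto"):
            raise ValueError(f"unknown projection rule {self.projection!r}")


def slice_at_height(points: np.ndarray,
                    cfg: StemDiameterConfig | None = None) -> np.ndarray:
    """Points with height in [base + h - delta, base + h + delta].

    The base is the minimum height coordinate of the (stem-labeled) cloud,
    so the slab is invariant to vertical offsets of the whole plant.
    """
    cfg = cfg or StemDiameterConfig()
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    h = pts[:, cfg.height_axis]
    base = h.min()
    lo = base + cfg.height_mm - cfg.slab_half_thickness_mm
    hi = base + cfg.height_mm + cfg.slab_half_thickness_mm
    slab = pts[(h >= lo) & (h <= hi)]
    if len(slab) == 0:
        raise ValueError(
            f"empty slab at {cfg.height_mm} mm above base; increase the "
            f"slab half-thickness (currently {cfg.slab_half_thickness_mm} mm)")
    return slab


def compute_obb(points: np.ndarray) -> OrientedBoundingBox:
    """PCA-oriented bounding box: eigenvectors of the covariance as axes.

    This approximates the minimal-volume box well for elongated slabs; the
    axes are sign-fixed (largest-magnitude entry of each column positive)
    and the determinant corrected to +1 so R is a proper rotation with
    R^T R = I.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("OBB needs at least 3 points")
    center = pts.mean(axis=0)
    X = pts - center
    cov = X.T @ X / max(len(X) - 1, 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    V = V[:, order]
    if w[order[1]] <= 1e-12 * max(w[order[0]], 1e-300):
        raise ValueError("degenerate point set: points are collinear")
    for j in range(3):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    local = X @ V
    lo, hi = local.min(axis=0), local.max(axis=0)
    box_center = center + V @ ((lo + hi) / 2.0)
    return OrientedBoundingBox(V, box_center, (hi - lo) / 2.0)


def align_with_obb(points: np.ndarray, obb: OrientedBoundingBox) -> np.ndarray:
    """Rotate points into the OBB frame (principal axis -> first axis)."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    return (pts - obb.center) @ obb.rotation


def fit_circle(points2d: np.ndarray, refine: bool = False) -> CircleFit:
    """Least-squares circle through a 2D point set.

    The algebraic (Kaasa) formulation linearizes
    sum_k [(x_k - a)^2 + (y_k - b)^2 - r^2]^2 into a linear system solved in
    closed form; with ``refine`` the exact quartic objective is polished by
    Gauss-Newton from that start.
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    # center the data for conditioning
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    A = np.column_stack([2 * u, 2 * v, np.ones(len(u))])
    rhs = u ** 2 + v ** 2
    sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise ValueError("collinear points admit no finite circle")
    a, b, c = sol
    r2 = c + a ** 2 + b ** 2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    a, b, r = a + mx, b + my, float(np.sqrt(r2))

    if refine:
        def residuals(p):
            return (x - p[0]) ** 2 + (y - p[1]) ** 2 - p[2] ** 2

        out = least_squares(residuals, x0=[a, b, r], method="lm")
        a, b, r = out.x
        r = abs(float(r))
    d = np.sqrt((x - a) ** 2 + (y - b) ** 2)
    rms = float(np.sqrt(np.mean((d - r) ** 2)))
    return CircleFit((float(a), float(b)), float(r), rms, len(pts))


def _straighten_stem(points: np.ndarray, height_axis: int) -> np.ndarray:
    """Rotate the stem so its principal (longitudinal) axis is vertical.

    A tilted stem sliced horizontally yields an elliptical cross-section and
    a biased diameter; rotating the principal axis onto the height axis makes
    the slab perpendicular to the stem before slicing.
    """
    center = points.mean(axis=0)
    X = points - center
    cov = X.T @ X / max(len(X) - 1, 1)
    w, V = np.linalg.eigh(cov)
    axis = V[:, np.argmax(w)]
    up = np.zeros(3)
    up[height_axis] = 1.0 if axis[height_axis] >= 0 else -1.0
    v = np.cross(axis, up)
    s, c = np.linalg.norm(v), float(axis @ up)
    if s < 1e-12:
        return X + center
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)  # Rodrigues
    return X @ R.T + center


def stem_diameter(points: np.ndarray,
                  cfg: StemDiameterConfig | None = None
                  ) -> tuple[float, CircleFit, OrientedBoundingBox]:
    """Stem diameter d = 2r: straighten -> slice -> OBB -> align -> project
    -> circle fit.

    The ``auto`` projection drops the OBB axis most parallel to the stem
    direction, so the fit always sees the cross-section plane — a fixed
    max-spread plane choice picks the wrong plane for single-view (partial
    arc) stems, whose chord/height spread exceeds their sagittal depth.
    """
    cfg = cfg or StemDiameterConfig()
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if cfg.straighten and len(pts) >= 3:
        pts = _straighten_stem(pts, cfg.height_axis)
    slab = slice_at_height(pts, cfg)
    if len(slab) < 3:
        raise ValueError("slab contains fewer than 3 points")
    obb = compute_obb(slab)
    aligned = align_with_obb(slab, obb)
    if cfg.projection == "XOY":
        proj = aligned[:, [0, 1]]
    elif cfg.projection == "XOZ":
        proj = aligned[:, [0, 2]]
    else:
        # auto: drop the OBB axis most parallel to the stem (height) direction
        up = np.zeros(3)
        up[cfg.height_axis] = 1.0
        stem_like = int(np.argmax(np.abs(obb.rotation.T @ up)))
        keep = [a for a in range(3) if a != stem_like]
        proj = aligned[:, keep]
    fit = fit_circle(proj, refine=cfg.refine)
    return fit.diameter, fit, obb
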