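"""Leaf length from a single-view leaf point cloud.

Single-view leaf clouds are non-closed surfaces, so mesh-based skeleton
extraction does not apply.  Instead the leaf is projected onto the XOY and
YOZ planes, each projection is fitted with a least-squares polynomial, the
two fitted curves are extruded into surfaces, and their intersection — the
parametric space curve r(y) = (f_xoy(y), y, f_yoz(y)) — is taken as the leaf
midrib.  Its arc length L = integral of sqrt(x'^2 + y'^2 + z'^2) dy is the
leaf length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.integrate import simpson

__all__ = [
    "PolynomialCurve2D",
    "SpaceCurve",
    "LeafLengthConfig",
    "project",
    "fit_polynomial",
    "intersect_extrusions",
    "arc_length",
    "leaf_length",
]

_PLANES = {"XOY": (0, 1), "YOZ": (1, 2), "XOZ": (0, 2)}


@dataclass
class PolynomialCurve2D:
    """Least-squares polynomial y_dep = sum_j a_j * t^j on [t_lo, t_hi].

    ``coefficients`` are in ascending order in the original (unscaled)
    independent variable; ``residual`` is the sum of squared errors S at the
    solution.
    """

    coefficients: np.ndarray
    independent_axis: str
    dependent_axis: str
    domain: tuple[float, float]
    residual: float

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return Polynomial(self.coefficients)(np.asarray(t, dtype=np.float64))

    def derivative(self, t: np.ndarray) -> np.ndarray:
        return Polynomial(self.coefficients).deriv()(np.asarray(t, dtype=np.float64))


@dataclass
class SpaceCurve:
    """Parametric curve r(t) = (x(t), t, z(t)) built from two planar fits
    sharing the parameter axis; carries its arc length once computed."""

    curve_xoy: PolynomialCurve2D
    curve_yoz: PolynomialCurve2D
    domain: tuple[float, float]
    length_mm: float | None = None

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return np.column_stack([self.curve_xoy(t), t, self.curve_yoz(t)])

    def speed(self, t: np.ndarray) -> np.ndarray:
        return np.sqrt(self.curve_xoy.derivative(t) ** 2 + 1.0
                       + self.curve_yoz.derivative(t) ** 2)


@dataclass(frozen=True)
class LeafLengthConfig:
    """Degree of the midrib fits, quadrature resolution, and pre-alignment.

    Degree 3 captures a single-bend tomato leaflet without oscillation;
    pre-alignment rotates the leaf's principal axis onto y so that both
    planar projections are single-valued functions of the shared parameter.
    """

    degree: int = 3
    quadrature_subintervals: int = 1000
    pre_align: bool = True
    endpoint_correction: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.degree <= 6:
            raise ValueError("degree must be in [1, 6]")
        if self.quadrature_subintervals < 10:
            raise ValueError("need at least 10 quadrature subintervals")


def project(points: np.ndarray, plane: str) -> np.ndarray:
    """Drop the coordinate orthogonal to the given plane (order preserved)."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot project an empty point set")
    try:
        i, j = _PLANES[plane.upper()]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; use XOY, YOZ or XOZ") from None
    return pts[:, [i, j]]


def fit_polynomial(points2d: np.ndarray, degree: int,
                   independent_axis: str = "t",
                   dependent_axis: str = "f") -> PolynomialCurve2D:
    """Least-squares polynomial fit minimizing S = sum_i (y_i - f(x_i))^2.

    The normal equations dS/da_j = 0 are solved on an internally rescaled
    abscissa for conditioning; coefficients are reported in original units.
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    t, y = pts[:, 0], pts[:, 1]
    if len(pts) < degree + 1:
        raise ValueError(f"degree {degree} needs at least {degree + 1} points")
    if len(np.unique(t)) < degree + 1:
        raise ValueError(
            f"rank-deficient design: only {len(np.unique(t))} distinct "
            f"abscissa values for a degree-{degree} fit")
    # numpy.polynomial fits in a mapped domain; convert back to raw coeffs
    series = Polynomial.fit(t, y, deg=degree)
    coeffs = series.convert().coef
    if len(coeffs) < degree + 1:  # trailing zeros trimmed by convert()
        coeffs = np.pad(coeffs, (0, degree + 1 - len(coeffs)))
    resid = float(np.sum((y - Polynomial(coeffs)(t)) ** 2))
    return PolynomialCurve2D(coeffs, independent_axis, dependent_axis,
                             (float(t.min()), float(t.max())), resid)


def intersect_extrusions(curve_xoy: PolynomialCurve2D,
                         curve_yoz: PolynomialCurve2D) -> SpaceCurve:
    """Intersect the two extruded fitted surfaces into a space curve.

    Extruding the XOY fit x = f(y) along z and the YOZ fit z = g(y) along x
    gives surfaces whose intersection is r(y) = (f(y), y, g(y)) on the
    overlap of the two fit domains.
    """
    lo = max(curve_xoy.domain[0], curve_yoz.domain[0])
    hi = min(curve_xoy.domain[1], curve_yoz.domain[1])
    if hi <= lo:
        raise ValueError("fitted curves have no overlapping parameter domain")
    return SpaceCurve(curve_xoy, curve_yoz, (lo, hi))


def arc_length(curve: SpaceCurve, subintervals: int = 1000,
               check_convergence: bool = True) -> float:
    """Composite-Simpson arc length of the space curve over its domain.

    The integrand uses the analytic polynomial derivatives.  With
    ``check_convergence`` the subinterval count is doubled until the result
    changes by < 1e-8 relative.
    """
    a, b = curve.domain
    if a >= b:
        raise ValueError("curve domain is empty")
    n = max(10, subintervals)
    n += n % 2  # Simpson needs an even count

    def integrate(k: int) -> float:
        t = np.linspace(a, b, k + 1)
        return float(simpson(curve.speed(t), x=t))

    L = integrate(n)
    if check_convergence:
        for _ in range(8):
            L2 = integrate(2 * n)
            if abs(L2 - L) <= 1e-8 * max(abs(L2), 1.0):
                L = L2
                break
            L, n = L2, 2 * n
    curve.length_mm = L
    return L


def _principal_alignment(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation sending the principal component onto y (and PC3 onto x)."""
    center = points.mean(axis=0)
    X = points - center
    cov = X.T @ X / max(len(X) - 1, 1)
    w, V = np.linalg.eigh(cov)  # ascending eigenvalues
    # rows of R: new x <- smallest-variance dir, y <- principal, z <- middle
    R = np.vstack([V[:, 0], V[:, 2], V[:, 1]]).astype(np.float64)
    if np.linalg.det(R) < 0:
        R[0] = -R[0]
    return R, center


def leaf_length(points: np.ndarray,
                cfg: LeafLengthConfig | None = None) -> tuple[float, SpaceCurve]:
    """Leaf length via project -> fit -> intersect -> integrate.

    ``points`` is the (N, 3) leaf cloud in mm.  With pre-alignment on, the
    leaf is first rotated so its principal axis is y; the two projections
    are then fitted with degree-``cfg.degree`` polynomials sharing y as the
    parameter.  Returns the length and the fitted :class:`SpaceCurve`.
    """
    cfg = cfg or LeafLengthConfig()
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < cfg.degree + 1:
        raise ValueError("not enough points for the requested degree")
    if cfg.pre_align:
        R, center = _principal_alignment(pts)
        pts = (pts - center) @ R.T
    span = np.ptp(pts, axis=0)
    if span[1] <= 0:
        raise ValueError("degenerate leaf: no extent along the parameter axis")
    # projections share y as the independent variable
    xy = project(pts, "XOY")[:, ::-1]        # (y, x)
    yz = project(pts, "YOZ")                 # (y, z)
    curve_xoy = fit_polynomial(xy, cfg.degree, "y", "x")
    curve_yoz = fit_polynomial(yz, cfg.degree, "y", "z")
    curve = intersect_extrusions(curve_xoy, curve_yoz)
    if cfg.endpoint_correction:
        # The observed parameter extremes overshoot the true leaf extent by
        # the extreme-value tail of the measurement noise (~ sigma*sqrt(2 ln n)
        # for Gaussian noise).  The smaller of the two fit residuals is a
        # noise-scale estimate uncontaminated by the leaf's own width, and it
        # vanishes for noiseless data, so the correction is inert there.
        n = len(pts)
        dof = max(n - cfg.degree - 1, 1)
        sigma = np.sqrt(min(curve_xoy.residual, curve_yoz.residual) / dof)
        lo, hi = curve.domain
        shrink = min(sigma * np.sqrt(2.0 * np.log(n)), 0.025 * (hi - lo))
        curve = SpaceCurve(curve_xoy, curve_yoz, (lo + shrink, hi - shrink))
    L = arc_length(curve, cfg.quadrature_subintervals)
    return L, curve
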