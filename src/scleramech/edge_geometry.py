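"""Analytic meridian descriptions of tracked scleral edges.

The inflation analysis views the sclera from the side, so each eye
contributes a planar trace of edge points running from the optic nerve
head (ONH) to the holder fixture.  This module turns such traces into an
analytic description: a least-squares ellipse, an angle / arc-length
parameterization of the meridian, and region labels (R1 peripapillary
... R5 at the fixture).

Coordinates are in mm in the camera frame (e1, e2), where e2 is the axis
of revolution through the ONH center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import ellipe, ellipeinc

__all__ = [
    "EdgeTrace",
    "EllipseFit",
    "AxisSpec",
    "MeridianParam",
    "fit_ellipse",
    "parameterize_meridian",
    "assign_regions",
    "mirror_trace",
]

REGION_LABELS = ("R1", "R2", "R3", "R4", "R5")
DEFAULT_REGION_BOUNDARIES = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class EdgeTrace:
    """Ordered edge points for one eye at one pressure.

    ``points`` is an (n, 2) array in mm; the first point is the one
    nearest the ONH, the last the one nearest the fixture.
    """

    eye_id: str
    pressure: float  # mmHg
    points: np.ndarray
    side: str = "right"  # "left" eyes are mirrored before analysis

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 10:
            raise ValueError("an edge trace needs at least 10 points")
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def mirror_trace(trace: EdgeTrace, axis_x: float = 0.0) -> EdgeTrace:
    """Reflect a trace about the vertical line e1 = axis_x.

    Used to bring left eyes to the common nasal-temporal orientation.
    """
    pts = trace.points.copy()
    pts[:, 0] = 2.0 * axis_x - pts[:, 0]
    return replace(trace, points=pts, side="right")


# ---------------------------------------------------------------------------
# Ellipse representation
# ---------------------------------------------------------------------------

def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class EllipseFit:
    """Ellipse described by center, semi-axes and tilt of the major axis.

    The parametric point at angle ``t`` (eccentric anomaly measured
    counterclockwise from the major axis) is

        P(t) = center + R(tilt) @ (a cos t, b sin t)

    with a = ``semi_major`` and b = ``semi_minor``.
    """

    center: np.ndarray
    semi_major: float
    semi_minor: float
    tilt: float
    rms_residual: float = 0.0

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    # -- parametric curve ---------------------------------------------------
    def point(self, t):
        t = np.asarray(t, dtype=float)
        local = np.stack(
            [self.semi_major * np.cos(t), self.semi_minor * np.sin(t)], axis=-1
        )
        return self.center + local @ _rotation(self.tilt).T

    def d_point(self, t):
        t = np.asarray(t, dtype=float)
        local = np.stack(
            [-self.semi_major * np.sin(t), self.semi_minor * np.cos(t)], axis=-1
        )
        return local @ _rotation(self.tilt).T

    def d2_point(self, t):
        t = np.asarray(t, dtype=float)
        local = np.stack(
            [-self.semi_major * np.cos(t), -self.semi_minor * np.sin(t)], axis=-1
        )
        return local @ _rotation(self.tilt).T

    def speed(self, t):
        """|dP/dt| at parameter t."""
        t = np.asarray(t, dtype=float)
        return np.sqrt(
            self.semi_major**2 * np.sin(t) ** 2
            + self.semi_minor**2 * np.cos(t) ** 2
        )

    def curvature_radius(self, t):
        """Radius of curvature of the ellipse at parameter t (mm)."""
        return self.speed(t) ** 3 / (self.semi_major * self.semi_minor)

    # -- arc length ---------------------------------------------------------
    @property
    def _m(self) -> float:
        return 1.0 - (self.semi_minor / self.semi_major) ** 2

    def arc_length_from(self, t0, t):
        """Signed arc length along the ellipse from parameter t0 to t.

        Closed form via incomplete elliptic integrals of the second kind:
        d(arc)/dt = sqrt(a^2 sin^2 t + b^2 cos^2 t) = a sqrt(1 - m cos^2 t).
        """
        m = self._m

        def S(tt):
            tt = np.asarray(tt, dtype=float)
            return self.semi_major * (ellipe(m) - ellipeinc(np.pi / 2 - tt, m))

        return S(t) - S(t0)

    def param_from_arc_length(self, s, t0):
        """Invert the (monotone) arc length measured from parameter t0."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty_like(s)
        for i, si in enumerate(s):
            # Newton with bisection safeguard; d(arc)/dt >= semi_minor > 0
            lo, hi = t0 + si / self.semi_major - 1.0, t0 + si / self.semi_minor + 1.0
            out[i] = optimize.brentq(
                lambda tt: self.arc_length_from(t0, tt) - si, lo, hi, xtol=1e-13
            )
        return out if out.size > 1 else out[0]

    # -- projection ---------------------------------------------------------
    def project(self, points):
        """Orthogonal projection of points onto the ellipse.

        Returns (t, signed_distance) where t is the parameter of the foot
        point and the distance is positive outside the ellipse.  Uses a
        damped Newton iteration on the stationarity condition of the
        squared distance; the traces handled here lie close to the fitted
        curve, where the projection is unique and the iteration converges
        quadratically.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - self.center) @ _rotation(self.tilt)
        a, b = self.semi_major, self.semi_minor
        x, y = local[:, 0], local[:, 1]
        t = np.arctan2(y / b, x / a)
        for _ in range(60):
            dx = a * np.cos(t) - x
            dy = b * np.sin(t) - y
            g = -dx * a * np.sin(t) + dy * b * np.cos(t)
            h = (
                a**2 * np.sin(t) ** 2
                + b**2 * np.cos(t) ** 2
                - dx * a * np.cos(t)
                - dy * b * np.sin(t)
            )
            step = g / np.where(np.abs(h) < 1e-300, 1e-300, h)
            step = np.clip(step, -0.5, 0.5)
            t = t - step
            if np.max(np.abs(step)) < 1e-15:
                break
        foot = np.stack([a * np.cos(t), b * np.sin(t)], axis=-1)
        d = np.linalg.norm(local - foot, axis=-1)
        inside = (x / a) ** 2 + (y / b) ** 2 < 1.0
        d = np.where(inside, -d, d)
        if pts.shape[0] == 1 and np.asarray(points).ndim == 1:
            return t[0], d[0]
        return t, d


# ---------------------------------------------------------------------------
# Ellipse fitting
# ---------------------------------------------------------------------------

def _algebraic_ellipse_fit(pts: np.ndarray) -> tuple[float, ...]:
    """Direct ellipse-specific least squares (Halir & Flusser variant).

    Returns the conic coefficients (A, B, C, D, E, F) of
    A x^2 + B xy + C y^2 + D x + E y + F = 0 with B^2 - 4AC < 0.
    """
    x = pts[:, 0]
    y = pts[:, 1]
    D1 = np.column_stack([x**2, x * y, y**2])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point configuration (no ellipse exists)") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C1) with C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(np.isreal(eigval) & (cond > 0))[0]
    if valid.size == 0:
        raise ValueError("input points do not determine an ellipse")
    a1 = np.real(eigvec[:, valid[0]])
    a2 = T @ a1
    return (a1[0], a1[1], a1[2], a2[0], a2[1], a2[2])


def _conic_to_geometric(coeffs) -> tuple[np.ndarray, float, float, float]:
    A, B, C, D, E, F = coeffs
    disc = B**2 - 4 * A * C
    if disc >= 0:
        raise ValueError("fitted conic is not an ellipse")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    # value of the quadratic form at the center
    Fc = A * cx**2 + B * cx * cy + C * cy**2 + D * cx + E * cy + F
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    eigval, eigvec = np.linalg.eigh(M)
    axes2 = -Fc / eigval
    if np.any(axes2 <= 0):
        raise ValueError("fitted conic is not an ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]
    semi_major, semi_minor = axes[order]
    major_dir = eigvec[:, order[0]]
    tilt = np.arctan2(major_dir[1], major_dir[0])
    if tilt <= -np.pi / 2:
        tilt += np.pi
    elif tilt > np.pi / 2:
        tilt -= np.pi
    return np.array([cx, cy]), semi_major, semi_minor, tilt


def _geometric_refine(pts: np.ndarray, init: EllipseFit) -> EllipseFit:
    """Minimise the orthogonal point-to-ellipse distances."""

    def unpack(p):
        cx, cy, a, b, th = p
        a, b = abs(a), abs(b)
        if b > a:
            a, b = b, a
            th += np.pi / 2
        return EllipseFit(np.array([cx, cy]), a, b, th)

    def residuals(p):
        fit = unpack(p)
        _, d = fit.project(pts)
        return np.atleast_1d(d)

    x0 = np.array(
        [init.center[0], init.center[1], init.semi_major, init.semi_minor, init.tilt]
    )
    sol = optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    fit = unpack(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return replace(fit, rms_residual=rms)


def fit_ellipse(points, refine: bool = True) -> EllipseFit:
    """Least-squares ellipse through 2D points.

    An algebraic fit with the ellipse-specific constraint provides the
    starting value; a geometric (orthogonal-distance) refinement then
    gives parameters that are stable at the sub-micrometre noise scale of
    the displacement tracking and exactly invariant under rigid motions.

    Parameters
    ----------
    points : (n, 2) array_like, n >= 6
    refine : bool
        Skip the geometric refinement if False (testing hook).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ValueError("need at least 6 two-dimensional points")
    centroid = pts.mean(axis=0)
    scale = np.max(np.abs(pts - centroid))
    if scale == 0:
        raise ValueError("degenerate point configuration (no ellipse exists)")
    work = (pts - centroid) / scale
    coeffs = _algebraic_ellipse_fit(work)
    center, a, b, tilt = _conic_to_geometric(coeffs)
    init = EllipseFit(center * scale + centroid, a * scale, b * scale, tilt)
    if not refine:
        _, d = init.project(pts)
        return replace(init, rms_residual=float(np.sqrt(np.mean(d**2))))
    return _geometric_refine(pts, init)


# ---------------------------------------------------------------------------
# Axis of revolution and meridian parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisSpec:
    """Axis of revolution: a point and a unit direction in the camera frame."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    @classmethod
    def from_ellipse(cls, fit: EllipseFit, prefer=(0.0, 1.0)) -> "AxisSpec":
        """Axis through the ellipse center along the ellipse axis closest
        in direction to ``prefer`` (default: the e2 camera axis)."""
        prefer = np.asarray(prefer, dtype=float)
        major = np.array([np.cos(fit.tilt), np.sin(fit.tilt)])
        minor = np.array([-np.sin(fit.tilt), np.cos(fit.tilt)])
        d = major if abs(major @ prefer) >= abs(minor @ prefer) else minor
        return cls(fit.center, d)

    def distance(self, points):
        """Perpendicular distance of points from the axis line."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.point
        along = rel @ self.direction
        perp = rel - np.outer(along, self.direction)
        d = np.linalg.norm(perp, axis=-1)
        return d if d.size > 1 else float(d[0])


@dataclass
class MeridianParam:
    """Angle / arc-length parameterization of one meridian trace.

    Per point: the ellipse angle (counterclockwise from the major axis of
    the fitted ellipse), the cumulative reference arc length s (mm, zero
    at the first, ONH-nearest point), the meridian angle phi (rad,
    measured from the axis of revolution), the circumferential angle
    theta (constant within the imaged meridian plane; kept for the
    axisymmetric bookkeeping), the reference diameter D(s) = 2 x distance
    from the axis of revolution, and a region label.
    """

    trace: EdgeTrace
    ellipse: EllipseFit
    axis: AxisSpec
    angle: np.ndarray
    arc_length_s: np.ndarray
    meridian_angle_phi: np.ndarray
    circumferential_angle_theta: float
    reference_diameter_D: np.ndarray
    region: np.ndarray = field(default=None)

    @property
    def points(self) -> np.ndarray:
        return self.trace.points

    @property
    def total_arc_length(self) -> float:
        return float(self.arc_length_s[-1] - self.arc_length_s[0])

    def angle_from_s(self, s):
        """Ellipse angle of the material point at reference arc length s."""
        s = np.asarray(s, dtype=float)
        lo = min(self.arc_length_s[0], self.arc_length_s[-1])
        hi = max(self.arc_length_s[0], self.arc_length_s[-1])
        if np.any(s < lo - 1e-9) or np.any(s > hi + 1e-9):
            raise ValueError("arc-length location outside the traced meridian")
        sign = 1.0 if self.angle[-1] >= self.angle[0] else -1.0
        return self.ellipse.param_from_arc_length(sign * s, self.angle[0])

    def region_span(self, labels) -> tuple[float, float]:
        """(s_min, s_max) covered by the given region label(s)."""
        if isinstance(labels, str):
            labels = (labels,)
        mask = np.isin(self.region, labels)
        if not mask.any():
            raise ValueError(f"no points in regions {labels}")
        return float(self.arc_length_s[mask].min()), float(self.arc_length_s[mask].max())


def parameterize_meridian(
    fit: EllipseFit,
    trace: EdgeTrace,
    axis: AxisSpec | None = None,
    max_residual_factor: float = 5.0,
) -> MeridianParam:
    """Assign each trace point its ellipse angle, arc length s, meridian
    angle phi, and reference diameter D.

    Arc length is measured along the fitted ellipse from the first point
    of the (ordered) trace, by the closed-form elliptic-integral
    quadrature of the ellipse perimeter.
    """
    if axis is None:
        axis = AxisSpec.from_ellipse(fit)
    t, d = fit.project(trace.points)
    tol = max(max_residual_factor * fit.rms_residual, 1e-9)
    if np.max(np.abs(d)) > max(tol, 5e-2 * fit.semi_minor):
        raise ValueError("trace points stray too far from the fitted ellipse")
    t = np.unwrap(t)
    if not (np.all(np.diff(t) > 0) or np.all(np.diff(t) < 0)):
        raise ValueError("points do not project monotonically onto the ellipse")
    s = np.abs(fit.arc_length_from(t[0], t))
    dist = np.atleast_1d(axis.distance(trace.points))
    rel = trace.points - axis.point
    along = rel @ axis.direction
    phi = np.arctan2(dist, along)
    param = MeridianParam(
        trace=trace,
        ellipse=fit,
        axis=axis,
        angle=t,
        arc_length_s=s,
        meridian_angle_phi=phi,
        circumferential_angle_theta=0.0,
        reference_diameter_D=2.0 * dist,
    )
    return assign_regions(param)


def assign_regions(
    param: MeridianParam, boundaries: Sequence[float] = DEFAULT_REGION_BOUNDARIES
) -> MeridianParam:
    """Label points R1 (nearest the ONH) through R5 (nearest the fixture).

    ``boundaries`` are increasing fractions of the ONH-to-fixture arc in
    (0, 1); the default splits the traced arc into five equal arc-length
    bands.  Every point receives a label.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.size != 4 or np.any(b <= 0) or np.any(b >= 1) or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be 4 increasing fractions in (0, 1)")
    s = param.arc_length_s
    s0, s1 = s[0], s[-1]
    total = s1 - s0
    if total <= 0:
        raise ValueError("arc too short to contain the region bands")
    frac = (s - s0) / total
    idx = np.searchsorted(b, frac, side="right")
    param.region = np.asarray(REGION_LABELS)[idx]
    return param
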