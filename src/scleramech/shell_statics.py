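"""Membrane statics of the inflated sclera as a thin shell of revolution.

For an axisymmetric thin shell under internal pressure p, equilibrium
determines the membrane stress resultants (force per unit length of
mid-surface) from the two radii of the deformed surface:

    n_phi   = p * r_t / 2
    n_theta = p * r_t * (2 * r_m - r_t) / (2 * r_m)

where r_m is the radius of curvature of the deformed meridian and r_t
the transverse radius (distance from the surface point to the axis of
revolution measured along the outward surface normal).  The pair
satisfies the normal-equilibrium identity n_phi/r_m + n_theta/r_t = p
and reduces to Laplace's law n = p r / 2 on a sphere and to
n_theta = p R, n_phi = p R / 2 in the cylinder limit r_m -> inf.

Pressures are accepted in mmHg (1 mmHg = 133.322 Pa), lengths in mm;
resultants are reported in N/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edge_geometry import AxisSpec, EllipseFit

__all__ = [
    "MMHG_TO_PA",
    "CurvatureSample",
    "StressResultantSample",
    "deformed_curvatures",
    "curvatures_at_params",
    "stress_resultants",
    "anisotropy_ratios",
    "membrane_pressure_residual",
]

MMHG_TO_PA = 133.322
DEFAULT_RATIO_EPSILON = 1e-4


@dataclass(frozen=True)
class CurvatureSample:
    """Deformed-surface radii at one meridian location (mm)."""

    location_s: float
    r_meridional: float
    r_transverse: float
    pressure: float

    def __post_init__(self):
        if self.r_meridional <= 0 or self.r_transverse <= 0:
            raise ValueError("radii must be positive for a convex inflated shell")


@dataclass(frozen=True)
class StressResultantSample:
    """Membrane stress resultants (N/m) at one location and pressure."""

    location_s: float
    region: str
    pressure: float
    n_phi: float
    n_theta: float


def curvatures_at_params(
    fit: EllipseFit, t, axis: AxisSpec, location_s=None, pressure: float = 0.0
) -> list[CurvatureSample]:
    """Radii of the surface of revolution generated by a fitted meridian
    ellipse, at ellipse parameters ``t``.

    r_meridional is the closed-form radius of curvature of the ellipse;
    r_transverse = r |P'| / |P' . axis|, the distance from the surface
    point to the axis along the outward normal (shell-of-revolution
    construction; r is the perpendicular distance to the axis).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if location_s is None:
        location_s = np.full(t.shape, np.nan)
    location_s = np.atleast_1d(np.asarray(location_s, dtype=float))
    pts = fit.point(t)
    tangent = fit.d_point(t)
    speed = np.linalg.norm(tangent, axis=-1)
    r_m = fit.curvature_radius(t)
    r = np.atleast_1d(axis.distance(pts))
    z_rate = np.abs(tangent @ axis.direction)
    out = []
    for i in range(t.size):
        if z_rate[i] < 1e-12 * speed[i]:
            raise ValueError(
                "transverse radius undefined: meridian tangent is normal to "
                "the axis (polar point)"
            )
        out.append(
            CurvatureSample(
                location_s=float(location_s[i]),
                r_meridional=float(r_m[i]),
                r_transverse=float(r[i] * speed[i] / z_rate[i]),
                pressure=pressure,
            )
        )
    return out


def deformed_curvatures(
    deformed_fit: EllipseFit,
    points,
    axis: AxisSpec,
    location_s=None,
    pressure: float = 0.0,
) -> list[CurvatureSample]:
    """Curvature radii of the deformed surface at given surface points.

    The points (e.g. reference points advanced by the fitted
    displacement) are orthogonally projected onto the deformed ellipse
    fit, and the radii are evaluated analytically at the foot parameters.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t, _ = deformed_fit.project(pts)
    return curvatures_at_params(
        deformed_fit, np.atleast_1d(t), axis, location_s=location_s, pressure=pressure
    )


def stress_resultants(
    p_mmhg: float, curv: CurvatureSample, region: str = ""
) -> StressResultantSample:
    """Membrane stress resultants from equilibrium of a thin shell of
    revolution under internal pressure.

    ``r_meridional`` may be ``inf`` (cylinder limit).
    """
    if p_mmhg <= 0:
        raise ValueError("pressure must be positive")
    if curv.r_meridional <= 0:
        raise ValueError("meridional curvature radius must be positive")
    p = p_mmhg * MMHG_TO_PA  # Pa
    r_t = curv.r_transverse * 1e-3  # m
    n_phi = 0.5 * p * r_t
    n_theta = p * r_t * (1.0 - curv.r_transverse / (2.0 * curv.r_meridional))
    return StressResultantSample(
        location_s=curv.location_s,
        region=region,
        pressure=p_mmhg,
        n_phi=float(n_phi),
        n_theta=float(n_theta),
    )


def anisotropy_ratios(
    E_phi, E_theta, n_phi, n_theta, epsilon: float = DEFAULT_RATIO_EPSILON
):
    """Mechanical anisotropy ratios (E_theta/E_phi, n_theta/n_phi).

    Where a denominator magnitude falls below ``epsilon`` the ratio is
    undefined and encoded as NaN rather than raised.
    """
    E_phi = np.asarray(E_phi, dtype=float)
    E_theta = np.asarray(E_theta, dtype=float)
    n_phi = np.asarray(n_phi, dtype=float)
    n_theta = np.asarray(n_theta, dtype=float)
    strain_ratio = np.where(np.abs(E_phi) < epsilon, np.nan, E_theta / np.where(np.abs(E_phi) < epsilon, np.inf, E_phi))
    res_ratio = np.where(np.abs(n_phi) < epsilon, np.nan, n_theta / np.where(np.abs(n_phi) < epsilon, np.inf, n_phi))
    if strain_ratio.ndim == 0:
        return float(strain_ratio), float(res_ratio)
    return strain_ratio, res_ratio


def membrane_pressure_residual(sample: StressResultantSample, curv: CurvatureSample):
    """Normal-equilibrium residual n_phi/r_m + n_theta/r_t - p (Pa).

    An independent consistency check of the resultant formulas against
    the membrane equilibrium of a shell of revolution.
    """
    p = sample.pressure * MMHG_TO_PA
    return (
        sample.n_phi / (curv.r_meridional * 1e-3)
        + sample.n_theta / (curv.r_transverse * 1e-3)
        - p
    )
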