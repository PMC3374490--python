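"""Displacement fields and Green-Lagrange strains of the scleral meridian.

The deformed edge position is x(s) = X(s) + u(s).  Each Cartesian
displacement component is least-squares fitted to a fourth-order
polynomial in the ellipse angle of the reference configuration; strains
are evaluated with analytic derivatives of the fit, chained through the
analytic angle-vs-arc-length relation of the fitted reference ellipse.

With s the reference arc length (|dX/ds| = 1), the meridional
Green-Lagrange strain reduces to

    E_phi = dX/ds . du/ds + 1/2 du/ds . du/ds
          = 1/2 (|dx/ds|^2 - 1),

and the circumferential strain follows from the deformed/reference
diameter ratio of the cross-section at s (axisymmetry):

    E_theta = 1/2 [ (d/D)^2 - 1 ].

Strains are referenced to the baseline-pressure configuration, i.e. to a
pre-stressed state; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edge_geometry import EdgeTrace, MeridianParam

__all__ = [
    "DisplacementFit",
    "StrainSample",
    "fit_displacement",
    "meridional_strain",
    "circumferential_strain",
    "deformed_diameter",
    "strain_samples",
]

DEFAULT_POLY_DEGREE = 4


@dataclass(frozen=True)
class DisplacementFit:
    """Polynomial displacement field u(angle) of one pressure step.

    Coefficients are in ascending order (numpy ``polynomial`` convention)
    and in mm; ``fit_rms`` is the rms residual of the least-squares fit
    over both Cartesian components.
    """

    coeffs_u1: np.ndarray
    coeffs_u2: np.ndarray
    fit_rms: float
    pressure: float

    def __post_init__(self):
        c1 = np.asarray(self.coeffs_u1, dtype=float)
        c2 = np.asarray(self.coeffs_u2, dtype=float)
        if c1.shape != c2.shape or c1.ndim != 1:
            raise ValueError("coefficient arrays must be 1-D and equal length")
        object.__setattr__(self, "coeffs_u1", c1)
        object.__setattr__(self, "coeffs_u2", c2)

    @property
    def degree(self) -> int:
        return self.coeffs_u1.size - 1

    def u(self, angle):
        angle = np.asarray(angle, dtype=float)
        return np.stack(
            [
                np.polynomial.polynomial.polyval(angle, self.coeffs_u1),
                np.polynomial.polynomial.polyval(angle, self.coeffs_u2),
            ],
            axis=-1,
        )

    def du_dangle(self, angle):
        angle = np.asarray(angle, dtype=float)
        d1 = np.polynomial.polynomial.polyder(self.coeffs_u1)
        d2 = np.polynomial.polynomial.polyder(self.coeffs_u2)
        return np.stack(
            [
                np.polynomial.polynomial.polyval(angle, d1),
                np.polynomial.polynomial.polyval(angle, d2),
            ],
            axis=-1,
        )


@dataclass(frozen=True)
class StrainSample:
    """Strain state at one meridian location and pressure step."""

    location_s: float
    region: str
    pressure: float
    E_phi: float
    E_theta: float
    deformed_diameter_d: float


def fit_displacement(
    reference: MeridianParam,
    deformed_trace: EdgeTrace,
    degree: int = DEFAULT_POLY_DEGREE,
) -> DisplacementFit:
    """Fit u = x - X componentwise to polynomials in the reference
    ellipse angle.

    The reference and deformed traces must share point correspondence
    (same tracked material points, same order).
    """
    if deformed_trace.n_points != reference.points.shape[0]:
        raise ValueError("reference and deformed traces have mismatched point counts")
    if reference.points.shape[0] < degree + 2:
        raise ValueError("too few matched points for the polynomial degree")
    u = deformed_trace.points - reference.points
    angle = reference.angle
    V = np.vander(angle, degree + 1, increasing=True)
    coeffs, _, _, _ = np.linalg.lstsq(V, u, rcond=None)
    resid = u - V @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return DisplacementFit(
        coeffs_u1=coeffs[:, 0],
        coeffs_u2=coeffs[:, 1],
        fit_rms=rms,
        pressure=deformed_trace.pressure,
    )


def meridional_strain(reference: MeridianParam, fit: DisplacementFit, locations):
    """Meridional Green-Lagrange strain E_phi at reference arc lengths.

    Derivatives are taken analytically: du/dangle from the fitted
    polynomial, dX/dangle from the reference ellipse, and the chain rule
    through ds/dangle = |dX/dangle| converts to arc-length derivatives.
    Locations outside the traced arc are refused (no extrapolation).
    """
    s = np.atleast_1d(np.asarray(locations, dtype=float))
    t = np.atleast_1d(reference.angle_from_s(s))
    dXdt = reference.ellipse.d_point(t)
    dudt = fit.du_dangle(t)
    dxdt = dXdt + dudt
    speed2 = np.sum(dXdt**2, axis=-1)
    E = (np.sum(dxdt**2, axis=-1) - speed2) / (2.0 * speed2)
    return E if E.size > 1 else float(E[0])


def circumferential_strain(reference_diameter_D, deformed_diameter_d):
    """E_theta from the deformed/reference cross-section diameter ratio."""
    D = np.asarray(reference_diameter_D, dtype=float)
    d = np.asarray(deformed_diameter_d, dtype=float)
    if np.any(D <= 0) or np.any(d <= 0):
        raise ValueError("diameters must be positive")
    E = 0.5 * ((d / D) ** 2 - 1.0)
    return E if E.size > 1 else float(E)


def deformed_diameter(reference: MeridianParam, fit: DisplacementFit, locations):
    """Deformed cross-section diameter d(s): twice the distance of the
    deformed material point (reference point + fitted displacement) from
    the axis of revolution."""
    s = np.atleast_1d(np.asarray(locations, dtype=float))
    t = np.atleast_1d(reference.angle_from_s(s))
    x = reference.ellipse.point(t) + fit.u(t)
    d = 2.0 * np.atleast_1d(reference.axis.distance(x))
    return d if d.size > 1 else float(d[0])


def _region_at(reference: MeridianParam, s: float) -> str:
    idx = int(np.argmin(np.abs(reference.arc_length_s - s)))
    return str(reference.region[idx])


def strain_samples(
    reference: MeridianParam, fit: DisplacementFit, locations
) -> list[StrainSample]:
    """Full strain state (E_phi, E_theta, d) at the given arc lengths."""
    s = np.atleast_1d(np.asarray(locations, dtype=float))
    t = np.atleast_1d(reference.angle_from_s(s))
    E_phi = np.atleast_1d(meridional_strain(reference, fit, s))
    d = np.atleast_1d(deformed_diameter(reference, fit, s))
    D = 2.0 * np.atleast_1d(reference.axis.distance(reference.ellipse.point(t)))
    E_theta = np.atleast_1d(circumferential_strain(D, d))
    return [
        StrainSample(
            location_s=float(si),
            region=_region_at(reference, float(si)),
            pressure=fit.pressure,
            E_phi=float(ep),
            E_theta=float(et),
            deformed_diameter_d=float(di),
        )
        for si, ep, et, di in zip(s, E_phi, E_theta, d)
    ]
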