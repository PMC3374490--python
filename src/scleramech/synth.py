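"""Synthetic inflation, IOP, axon-count and morphometry data with known
ground truth.

The forward model for inflation is a prescribed kinematic map on a
revolved ellipsoid, not a constitutive solve: the analysis estimates
kinematics, so ground truth only needs a known deformation.  Three
deformation families are provided (see :class:`StretchField`):

``"ellipsoid"``
    The deformed configuration is again an ellipsoid of revolution with
    per-direction axis scale factors.  Ellipse fits of the deformed trace
    are then exact, making this the reference family for curvature and
    stress-resultant checks.
``"stretch"``
    Meridional and circumferential stretch ratios are prescribed as
    polynomials in the meridian parameter; the deformed meridian is
    reconstructed from the arc-length ODE.  This is the most general,
    physically parameterised family.
``"displacement"``
    The displacement components are quartic polynomials in the meridian
    parameter — exactly the function class of the fourth-order polynomial
    displacement fit used by the analysis, so noise-free strain recovery
    is limited only by round-off.

In every family the truth strains are E = (lambda^2 - 1)/2 per principal
direction and the truth stress resultants follow from the exact deformed
curvatures and thin-shell equilibrium.

Edge positions carry i.i.d. Gaussian noise per coordinate with the
displacement-tracking error budget (default 0.46 um) as standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.optimize import brentq
from scipy.special import ellipe, ellipeinc

from .edge_geometry import EdgeTrace
from .glaucoma_metrics import AxonSample, IOPSeries
from .shell_statics import CurvatureSample, stress_resultants

__all__ = [
    "ShellGeometry",
    "StretchField",
    "random_displacement_field",
    "NoiseModel",
    "TruthModel",
    "SyntheticEye",
    "simulate_inflation",
    "simulate_eye_cohort",
    "simulate_iop_series",
    "default_elevation_profile",
    "expected_positive_integral",
    "simulate_axon_cohort",
    "simulate_morphometry",
    "DEFAULT_MORPHOMETRY",
]

_P = np.polynomial.polynomial


@dataclass(frozen=True)
class ShellGeometry:
    """Revolved-ellipsoid geometry of the scleral shell.

    The axis of revolution is the camera e2 axis through the ONH center.
    The meridian parameter t is the eccentric angle measured from the
    ONH pole (t = 0); the visible arc runs from ``onh_gap_angle`` to
    ``pi - fixture_gap_angle``.  Default semi-axes follow adult mouse
    morphometry: equatorial 1.7 mm (half of the ~3.4 mm equatorial
    width), polar 1.9 mm; the fixture gap excludes the anterior third of
    the globe glued to the holder.
    """

    semi_axis_polar: float = 1.9  # mm, along the axis of revolution
    semi_axis_equatorial: float = 1.7  # mm
    onh_gap_angle: float = 0.25  # rad excluded around the ONH
    fixture_gap_angle: float = np.pi / 3.0  # rad excluded at the holder

    def __post_init__(self):
        if self.semi_axis_polar <= 0 or self.semi_axis_equatorial <= 0:
            raise ValueError("semi-axes must be positive")
        if self.onh_gap_angle < 0 or self.fixture_gap_angle < 0:
            raise ValueError("gap angles must be non-negative")
        if self.onh_gap_angle + self.fixture_gap_angle >= np.pi:
            raise ValueError("gap angles leave no visible meridian arc")

    @property
    def is_spherical(self) -> bool:
        return np.isclose(self.semi_axis_polar, self.semi_axis_equatorial)

    @property
    def arc_interval(self) -> tuple[float, float]:
        return (self.onh_gap_angle, np.pi - self.fixture_gap_angle)

    def reference_points(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack(
            [
                self.semi_axis_equatorial * np.sin(t),
                self.semi_axis_polar * np.cos(t),
            ],
            axis=-1,
        )

    def reference_speed(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sqrt(
            self.semi_axis_equatorial**2 * np.cos(t) ** 2
            + self.semi_axis_polar**2 * np.sin(t) ** 2
        )

    def arc_length(self, t) -> np.ndarray:
        """Reference arc length from the ONH pole (t = 0), closed form."""
        t = np.asarray(t, dtype=float)
        a_eq, a_pol = self.semi_axis_equatorial, self.semi_axis_polar
        if a_pol >= a_eq:
            m = 1.0 - (a_eq / a_pol) ** 2
            return a_pol * (ellipe(m) - ellipeinc(np.pi / 2 - t, m))
        m = 1.0 - (a_pol / a_eq) ** 2
        return a_eq * ellipeinc(t, m)

    def param_from_arc_length(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        hi_speed = max(self.semi_axis_polar, self.semi_axis_equatorial)
        lo_speed = min(self.semi_axis_polar, self.semi_axis_equatorial)
        out = np.empty_like(s)
        for i, si in enumerate(s):
            out[i] = brentq(
                lambda tt: self.arc_length(tt) - si,
                si / hi_speed - 1.0,
                si / lo_speed + 1.0,
                xtol=1e-13,
            )
        return out if out.size > 1 else out[0]


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian position noise per coordinate.

    The default standard deviation is the displacement-tracking error
    budget of the imaging chain, 0.46 um (0.36 um pixel-distance
    calibration + 0.10 um correlation error).
    """

    position_sd_um: float = 0.46
    seed: int = 0

    def __post_init__(self):
        if self.position_sd_um < 0:
            raise ValueError("position_sd must be non-negative")

    @property
    def position_sd_mm(self) -> float:
        return self.position_sd_um * 1e-3


@dataclass(frozen=True)
class StretchField:
    """Prescribed pressure-dependent deformation of the shell meridian.

    The deformation at pressure p scales a full-load shape by the load
    factor g(p) = ((p - P0)/(P_full - P0)) ** pressure_response_exponent,
    so g = 0 at the reference pressure (stretches are exactly 1 there)
    and g = 1 at ``full_load_pressure``.  An exponent below 1 mimics the
    stiffening of collagenous tissue: strain grows sublinearly with
    pressure.

    Families (``kind``): "ellipsoid" (axis scale factors at full load),
    "stretch" (ascending polynomial coefficients of lambda - 1 in t at
    full load, per direction), "displacement" (ascending quartic
    coefficients of the displacement components in t at full load, mm).
    """

    kind: str = "ellipsoid"
    equatorial_scale: float = 1.02
    polar_scale: float = 1.018
    meridional_stretch_coeffs: tuple = ()
    circumferential_stretch_coeffs: tuple = ()
    u1_coeffs: tuple = ()
    u2_coeffs: tuple = ()
    pressure_response_exponent: float = 0.5
    full_load_pressure: float = 30.0  # mmHg

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "stretch", "displacement"):
            raise ValueError(f"unknown deformation kind: {self.kind!r}")
        if self.pressure_response_exponent <= 0:
            raise ValueError("pressure_response_exponent must be positive")

    def load_factor(self, p, p0) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any(p < p0 - 1e-12):
            raise ValueError("pressure below the reference pressure")
        x = np.clip((p - p0) / (self.full_load_pressure - p0), 0.0, None)
        return x**self.pressure_response_exponent

    @classmethod
    def uniform(cls, stretch: float, exponent: float = 0.5) -> "StretchField":
        """Spatially uniform stretch (same in both directions) at full load."""
        return cls(
            kind="ellipsoid",
            equatorial_scale=stretch,
            polar_scale=stretch,
            pressure_response_exponent=exponent,
        )

    @classmethod
    def identity(cls) -> "StretchField":
        return cls(kind="ellipsoid", equatorial_scale=1.0, polar_scale=1.0)


def random_displacement_field(
    seed: int,
    geometry: ShellGeometry = ShellGeometry(),
    scale_range: tuple[float, float] = (1.01, 1.04),
    modulation: float = 0.15,
    exponent: float = 0.5,
    max_tries: int = 50,
) -> StretchField:
    """Random physical displacement-kind stretch field.

    Draws an inflation map (per-direction axis scaling with a mild
    angular modulation of the circumferential stretch, plus a small
    rigid axial shift), projects its displacement components onto
    quartic polynomials in the meridian parameter over the visible arc,
    and validates that both principal stretches stay >= 1.  Redraws on
    the rare physicality failure.
    """
    rng = np.random.default_rng(seed)
    t_lo, t_hi = geometry.arc_interval
    t_dense = np.linspace(t_lo, t_hi, 200)
    V = np.vander(t_dense, 5, increasing=True)
    for _ in range(max_tries):
        alpha_eq = rng.uniform(*scale_range)
        alpha_pol = rng.uniform(*scale_range)
        mod = rng.uniform(-modulation, modulation, size=2)
        shift = rng.uniform(-0.05, 0.05)
        tc = 0.5 * (t_lo + t_hi)
        lam_theta = 1.0 + (alpha_eq - 1.0) * (
            1.0 + mod[0] * (t_dense - tc) + mod[1] * (t_dense - tc) ** 2
        )
        u1 = (lam_theta - 1.0) * geometry.semi_axis_equatorial * np.sin(t_dense)
        u2 = (alpha_pol - 1.0) * geometry.semi_axis_polar * np.cos(t_dense) + shift
        q1, _, _, _ = np.linalg.lstsq(V, u1, rcond=None)
        q2, _, _, _ = np.linalg.lstsq(V, u2, rcond=None)
        field = StretchField(
            kind="displacement",
            u1_coeffs=tuple(q1),
            u2_coeffs=tuple(q2),
            pressure_response_exponent=exponent,
        )
        truth = TruthModel(geometry, field, p0=0.0)
        ok = True
        for p_chk in (field.full_load_pressure, 0.25 * field.full_load_pressure):
            lam_p = np.atleast_1d(truth.lambda_phi(t_dense, p_chk))
            lam_t = np.atleast_1d(truth.lambda_theta(t_dense, p_chk))
            ok = ok and bool(np.all(lam_p >= 1.0) and np.all(lam_t >= 1.0))
        if ok:
            return field
    raise RuntimeError("could not draw a physical displacement field")


class TruthModel:
    """Closed-form ground truth of a synthetic inflation experiment.

    Provides deformed positions, principal stretches, Green-Lagrange
    strains and (via exact deformed curvatures and thin-shell
    equilibrium) stress resultants as functions of the meridian
    parameter t and pressure.
    """

    def __init__(self, geometry: ShellGeometry, field: StretchField, p0: float):
        self.geometry = geometry
        self.field = field
        self.p0 = p0
        g = field
        if g.kind == "stretch":
            self._c_phi = np.asarray(g.meridional_stretch_coeffs, dtype=float)
            self._c_theta = np.asarray(g.circumferential_stretch_coeffs, dtype=float)
            if self._c_phi.size == 0 or self._c_theta.size == 0:
                raise ValueError("stretch kind requires polynomial coefficients")
        elif g.kind == "displacement":
            self._q1 = np.asarray(g.u1_coeffs, dtype=float)
            self._q2 = np.asarray(g.u2_coeffs, dtype=float)
            if self._q1.size == 0 or self._q2.size == 0:
                raise ValueError("displacement kind requires quartic coefficients")

    # -- stretches ----------------------------------------------------------
    def _g(self, p):
        return self.field.load_factor(p, self.p0)

    def _deformed_axes(self, p):
        g = self._g(p)
        a_e = self.geometry.semi_axis_equatorial * (
            1.0 + g * (self.field.equatorial_scale - 1.0)
        )
        a_p = self.geometry.semi_axis_polar * (1.0 + g * (self.field.polar_scale - 1.0))
        return a_e, a_p

    def lambda_theta(self, t, p):
        t = np.asarray(t, dtype=float)
        g = self._g(p)
        if self.field.kind == "ellipsoid":
            a_e, _ = self._deformed_axes(p)
            return np.full(t.shape, a_e / self.geometry.semi_axis_equatorial)
        if self.field.kind == "stretch":
            return 1.0 + g * _P.polyval(t, self._c_theta)
        X1 = self.geometry.semi_axis_equatorial * np.sin(t)
        return (X1 + g * _P.polyval(t, self._q1)) / X1

    def lambda_phi(self, t, p):
        t = np.asarray(t, dtype=float)
        g = self._g(p)
        if self.field.kind == "stretch":
            return 1.0 + g * _P.polyval(t, self._c_phi)
        r, rp, _, zp, _ = self._meridian_derivatives(t, p)
        return np.sqrt(rp**2 + zp**2) / self.geometry.reference_speed(t)

    def E_phi(self, t, p):
        return 0.5 * (self.lambda_phi(t, p) ** 2 - 1.0)

    def E_theta(self, t, p):
        return 0.5 * (self.lambda_theta(t, p) ** 2 - 1.0)

    # -- deformed meridian --------------------------------------------------
    def _meridian_derivatives(self, t, p):
        """(r, r', r'', z', z'') of the deformed meridian (r = distance
        from the axis, z = coordinate along it; primes are d/dt).

        All analytic except z(t) itself, which is not needed here.
        """
        t = np.asarray(t, dtype=float)
        geo = self.geometry
        g = self._g(p)
        if self.field.kind == "ellipsoid":
            a_e, a_p = self._deformed_axes(p)
            r = a_e * np.sin(t)
            rp = a_e * np.cos(t)
            rpp = -a_e * np.sin(t)
            zp = -a_p * np.sin(t)
            zpp = -a_p * np.cos(t)
            return r, rp, rpp, zp, zpp
        if self.field.kind == "displacement":
            q1 = self._q1
            q2 = self._q2
            r = geo.semi_axis_equatorial * np.sin(t) + g * _P.polyval(t, q1)
            rp = geo.semi_axis_equatorial * np.cos(t) + g * _P.polyval(t, _P.polyder(q1))
            rpp = -geo.semi_axis_equatorial * np.sin(t) + g * _P.polyval(
                t, _P.polyder(q1, 2)
            )
            zp = -geo.semi_axis_polar * np.sin(t) + g * _P.polyval(t, _P.polyder(q2))
            zpp = -geo.semi_axis_polar * np.cos(t) + g * _P.polyval(
                t, _P.polyder(q2, 2)
            )
            return r, rp, rpp, zp, zpp
        # stretch kind: r = lambda_theta * R; z from the arc-length ODE
        lam_t = 1.0 + g * _P.polyval(t, self._c_theta)
        lam_tp = g * _P.polyval(t, _P.polyder(self._c_theta))
        lam_tpp = g * _P.polyval(t, _P.polyder(self._c_theta, 2))
        lam_f = 1.0 + g * _P.polyval(t, self._c_phi)
        lam_fp = g * _P.polyval(t, _P.polyder(self._c_phi))
        a, c = geo.semi_axis_equatorial, geo.semi_axis_polar
        R = a * np.sin(t)
        Rp = a * np.cos(t)
        Rpp = -a * np.sin(t)
        r = lam_t * R
        rp = lam_tp * R + lam_t * Rp
        rpp = lam_tpp * R + 2.0 * lam_tp * Rp + lam_t * Rpp
        S2 = a**2 * np.cos(t) ** 2 + c**2 * np.sin(t) ** 2
        S2p = 2.0 * (c**2 - a**2) * np.sin(t) * np.cos(t)
        G = lam_f**2 * S2 - rp**2
        if np.any(G <= 0):
            raise ValueError(
                "prescribed stretch field is not realizable as a meridian "
                "(circumferential gradient too steep for the meridional stretch)"
            )
        Gp = 2.0 * lam_f * lam_fp * S2 + lam_f**2 * S2p - 2.0 * rp * rpp
        zp = -np.sqrt(G)
        zpp = -Gp / (2.0 * np.sqrt(G))
        return r, rp, rpp, zp, zpp

    def deformed_points(self, t, p) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        geo = self.geometry
        if self.field.kind == "ellipsoid":
            a_e, a_p = self._deformed_axes(p)
            return np.stack([a_e * np.sin(t), a_p * np.cos(t)], axis=-1)
        if self.field.kind == "displacement":
            g = self._g(p)
            u = np.stack(
                [_P.polyval(t, self._q1), _P.polyval(t, self._q2)], axis=-1
            )
            return geo.reference_points(t) + g * u
        r, *_ = self._meridian_derivatives(t, p)
        t0 = geo.arc_interval[0]
        z0 = geo.semi_axis_polar * np.cos(t0)
        z = np.empty_like(t)
        grid = np.argsort(t)
        prev_t, prev_z = t0, z0

        def zprime(tt):
            return self._meridian_derivatives(np.asarray(tt), p)[3]

        for i in grid:
            seg, _ = integrate.quad(zprime, prev_t, t[i], epsabs=1e-13, epsrel=1e-12)
            z[i] = prev_z + seg
            prev_t, prev_z = t[i], z[i]
        return np.stack([r, z], axis=-1)

    # -- curvatures and resultants -----------------------------------------
    def curvatures(self, t, p) -> tuple[np.ndarray, np.ndarray]:
        """(r_meridional, r_transverse) in mm at parameters t."""
        r, rp, rpp, zp, zpp = self._meridian_derivatives(t, p)
        speed2 = rp**2 + zp**2
        kappa = (rp * zpp - zp * rpp) / speed2**1.5
        r_m = 1.0 / np.abs(kappa)
        r_t = r * np.sqrt(speed2) / np.abs(zp)
        return r_m, r_t

    def resultants(self, t, p) -> tuple[np.ndarray, np.ndarray]:
        """(n_phi, n_theta) in N/m at parameters t and pressure p (mmHg)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        r_m, r_t = self.curvatures(t, p)
        n_phi = np.empty_like(r_m)
        n_theta = np.empty_like(r_m)
        for i in range(t.size):
            curv = CurvatureSample(
                location_s=np.nan, r_meridional=r_m[i], r_transverse=r_t[i], pressure=p
            )
            res = stress_resultants(p, curv)
            n_phi[i] = res.n_phi
            n_theta[i] = res.n_theta
        return n_phi, n_theta

    def validate_physical(self, t, pressures) -> None:
        for p in pressures:
            lam_p = np.atleast_1d(self.lambda_phi(t, p))
            lam_t = np.atleast_1d(self.lambda_theta(t, p))
            if np.any(lam_p < 1.0 - 1e-9) or np.any(lam_t < 1.0 - 1e-9):
                raise ValueError(
                    "unphysical stretch field: stretch below 1 at some "
                    "sampled angle/pressure"
                )


@dataclass
class SyntheticEye:
    """One simulated inflation experiment with ground truth attached."""

    eye_id: str
    geometry: ShellGeometry
    field: StretchField
    pressures: tuple
    t_grid: np.ndarray
    traces: list  # noisy EdgeTrace per pressure (first is reference)
    exact_traces: list
    truth: TruthModel
    side: str = "right"

    @property
    def reference_trace(self) -> EdgeTrace:
        return self.traces[0]

    def s_of_t(self, t):
        """Reference arc length from the first traced point."""
        return self.geometry.arc_length(t) - self.geometry.arc_length(self.t_grid[0])

    def t_of_s(self, s):
        s0 = self.geometry.arc_length(self.t_grid[0])
        return self.geometry.param_from_arc_length(np.asarray(s, dtype=float) + s0)

    def truth_table(self) -> pd.DataFrame:
        """Per-pressure, per-point truth strains and resultants."""
        rows = []
        s = self.s_of_t(self.t_grid)
        for p in self.pressures:
            E_phi = np.atleast_1d(self.truth.E_phi(self.t_grid, p))
            E_theta = np.atleast_1d(self.truth.E_theta(self.t_grid, p))
            n_phi, n_theta = self.truth.resultants(self.t_grid, p)
            for i, t in enumerate(self.t_grid):
                rows.append(
                    {
                        "eye_id": self.eye_id,
                        "pressure_mmHg": p,
                        "point_index": i,
                        "t_rad": t,
                        "s_mm": s[i],
                        "E_phi": E_phi[i],
                        "E_theta": E_theta[i],
                        "n_phi_N_per_m": n_phi[i],
                        "n_theta_N_per_m": n_theta[i],
                    }
                )
        return pd.DataFrame(rows)


def simulate_inflation(
    geometry: ShellGeometry,
    stretch: StretchField,
    pressures: Sequence[float],
    n_points: int = 40,
    noise: NoiseModel = NoiseModel(),
    eye_id: str = "synthetic",
    side: str = "right",
) -> SyntheticEye:
    """Simulate one pressure-controlled inflation test.

    ``pressures`` must be ascending with the first entry the reference
    pressure P0.  Returns noise-corrupted edge traces whose underlying
    deformation map and truth strains/resultants are known in closed
    form.
    """
    pressures = tuple(float(p) for p in pressures)
    if len(pressures) < 1 or np.any(np.diff(pressures) <= 0):
        raise ValueError("pressures must be a non-empty ascending list")
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    p0 = pressures[0]
    truth = TruthModel(geometry, stretch, p0)
    t_lo, t_hi = geometry.arc_interval
    t_grid = np.linspace(t_lo, t_hi, n_points)
    truth.validate_physical(t_grid, pressures)
    rng = np.random.default_rng(noise.seed)
    sd = noise.position_sd_mm
    exact_traces, traces = [], []
    for p in pressures:
        pts = truth.deformed_points(t_grid, p)
        exact_traces.append(EdgeTrace(eye_id=eye_id, pressure=p, points=pts, side=side))
        noisy = pts + rng.normal(0.0, sd, size=pts.shape) if sd > 0 else pts.copy()
        traces.append(EdgeTrace(eye_id=eye_id, pressure=p, points=noisy, side=side))
    return SyntheticEye(
        eye_id=eye_id,
        geometry=geometry,
        field=stretch,
        pressures=pressures,
        t_grid=t_grid,
        traces=traces,
        exact_traces=exact_traces,
        truth=truth,
        side=side,
    )


def simulate_eye_cohort(
    n_eyes: int,
    pressures: Sequence[float],
    seed: int,
    geometry: ShellGeometry = ShellGeometry(),
    base_field: StretchField = StretchField(),
    circumferential_factor: float = 1.0,
    eye_cv: float = 0.2,
    geometry_cv: float = 0.02,
    noise_sd_um: float = 0.46,
    n_points: int = 40,
    eye_prefix: str = "eye",
) -> list[SyntheticEye]:
    """Simulate a cohort of eyes with biological between-eye variability.

    Each eye draws a common stretch-amplitude multiplier (lognormal, CV
    ``eye_cv``) and mild semi-axis jitter (CV ``geometry_cv``).
    ``circumferential_factor`` scales the circumferential (equatorial)
    stretch amplitude of the whole cohort — e.g. 0.7 emulates a 30%
    circumferentially stiffer group.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + eye_cv**2))
    eyes = []
    for i in range(n_eyes):
        m = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        geom = ShellGeometry(
            semi_axis_polar=geometry.semi_axis_polar
            * (1.0 + geometry_cv * rng.standard_normal()),
            semi_axis_equatorial=geometry.semi_axis_equatorial
            * (1.0 + geometry_cv * rng.standard_normal()),
            onh_gap_angle=geometry.onh_gap_angle,
            fixture_gap_angle=geometry.fixture_gap_angle,
        )
        field = replace(
            base_field,
            equatorial_scale=1.0
            + circumferential_factor * m * (base_field.equatorial_scale - 1.0),
            polar_scale=1.0 + m * (base_field.polar_scale - 1.0),
        )
        eyes.append(
            simulate_inflation(
                geom,
                field,
                pressures,
                n_points=n_points,
                noise=NoiseModel(noise_sd_um, seed=int(rng.integers(2**31))),
                eye_id=f"{eye_prefix}{i:03d}",
            )
        )
    return eyes


# ---------------------------------------------------------------------------
# IOP series
# ---------------------------------------------------------------------------

def default_elevation_profile(peak: float = 8.0, tau: float = 12.0) -> Callable:
    """Exponentially decaying IOP elevation (mmHg) over the six-week
    bead-injection experiment: peak at injection, time constant ``tau``
    days.  The defaults integrate to ~92 mmHg*days over 42 days, in the
    range of the reported cohort means."""

    def profile(day):
        return peak * np.exp(-np.asarray(day, dtype=float) / tau)

    return profile


def _as_profile(elevation_profile) -> Callable:
    if elevation_profile is None:
        return default_elevation_profile()
    if callable(elevation_profile):
        return elevation_profile
    arr = np.asarray(elevation_profile, dtype=float)
    if arr.ndim == 0:
        return lambda day: np.full_like(np.asarray(day, dtype=float), float(arr))
    days = np.arange(arr.size, dtype=float)
    return lambda day: np.interp(np.asarray(day, dtype=float), days, arr)


def expected_positive_integral(elevation_profile, measurement_days) -> float:
    """Trapezoidal area of the (non-negative) elevation profile over the
    measurement schedule — the noise-free positive integral IOP."""
    profile = _as_profile(elevation_profile)
    days = np.asarray(measurement_days, dtype=float)
    return float(np.trapezoid(np.maximum(profile(days), 0.0), days))


def simulate_iop_series(
    baseline_mean: float = 12.2,
    elevation_profile=None,
    measurement_days: Sequence[float] = (0, 3, 7, 14, 21, 28, 35, 42),
    noise_sd: float = 2.0,
    seed: int = 0,
    eye_id: str = "eye",
) -> tuple[IOPSeries, IOPSeries]:
    """Paired (treated, fellow) IOP series over the six-week experiment.

    The fellow eye fluctuates about the baseline; the treated eye adds
    the elevation profile.  Measurement noise is Gaussian per reading.
    """
    days = np.asarray(measurement_days, dtype=float)
    if days.size < 2 or np.any(np.diff(days) <= 0):
        raise ValueError("measurement days must be ascending")
    if days[0] < 0 or days[-1] > 42:
        raise ValueError("measurement days must lie within [0, 42]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    profile = _as_profile(elevation_profile)
    rng = np.random.default_rng(seed)
    fellow = baseline_mean + rng.normal(0.0, noise_sd, size=days.size)
    treated = (
        baseline_mean
        + np.asarray(profile(days), dtype=float)
        + rng.normal(0.0, noise_sd, size=days.size)
    )
    return (
        IOPSeries(eye_id=f"{eye_id}_treated", arm="treated", days=days, iop=treated),
        IOPSeries(eye_id=f"{eye_id}_fellow", arm="fellow", days=days, iop=fellow),
    )


# ---------------------------------------------------------------------------
# Axon sampling
# ---------------------------------------------------------------------------

def simulate_axon_cohort(
    true_count: float = 46905.0,
    nerve_area: float = 0.0889,  # mm^2; five 0.0016 mm^2 fields = 9% of it
    field_area: float = 0.0016,  # mm^2 (40 x 40 um image)
    n_fields: int = 5,
    loss_fraction: float = 0.0,
    dispersion: float = 0.0,
    seed: int = 0,
    n_nerves: int = 1,
    nerve_prefix: str = "nerve",
) -> list[AxonSample]:
    """Simulate optic-nerve axon sampling.

    Per-field counts are drawn around the surviving density
    true_count * (1 - loss_fraction) / nerve_area.  ``dispersion`` = 0
    gives deterministic densities; ``dispersion`` > 0 draws Poisson
    counts with a gamma-modulated rate of coefficient of variation
    ``dispersion`` (the limit dispersion -> 0+ is pure Poisson).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be at least 1")
    if field_area * n_fields > nerve_area + 1e-12:
        raise ValueError("sampled fields exceed the nerve cross-section area")
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError("loss_fraction must be in [0, 1)")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    density = true_count * (1.0 - loss_fraction) / nerve_area
    mu = density * field_area
    rng = np.random.default_rng(seed)
    samples = []
    for j in range(n_nerves):
        if dispersion == 0.0:
            dens = np.full(n_fields, density)
        else:
            shape = 1.0 / dispersion**2
            rates = mu * rng.gamma(shape, 1.0 / shape, size=n_fields)
            counts = rng.poisson(rates)
            dens = counts / field_area
        samples.append(
            AxonSample(
                nerve_id=f"{nerve_prefix}{j:03d}",
                nerve_area=nerve_area,
                field_densities=dens,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

#: Default cohort cells: (strain, age months, treatment) ->
#: per-dimension (mean, SD) in mm and cohort size.
DEFAULT_MORPHOMETRY: dict = {
    ("Aca23", 4, "control"): {
        "axial_length": (3.81, 0.10),
        "width_NT": (3.51, 0.13),
        "width_SI": None,
        "n": 37,
    },
    ("Aca23", 4, "glaucoma"): {
        "axial_length": (4.15, 0.26),
        "width_NT": (3.74, 0.18),
        "width_SI": None,
        "n": 37,
    },
    ("Aca23", 17, "control"): {
        "axial_length": (4.17, 0.12),
        "width_NT": (3.65, 0.14),
        "width_SI": (3.56, 0.15),
        "n": 48,
    },
    ("WT", 4, "control"): {
        "axial_length": (3.39, 0.14),
        "width_NT": (3.27, 0.14),
        "width_SI": (3.23, 0.12),
        "n": 127,
    },
    ("WT", 4, "glaucoma"): {
        "axial_length": (4.01, 0.25),
        "width_NT": (3.69, 0.29),
        "width_SI": None,
        "n": 30,
    },
    ("WT", 17, "control"): {
        "axial_length": (3.59, 0.11),
        "width_NT": (3.55, 0.08),
        "width_SI": (3.49, 0.09),
        "n": 48,
    },
}


def simulate_morphometry(
    cells: dict | None = None,
    n_per_cell: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian caliper-morphometry draws per cohort cell.

    ``cells`` maps (strain, age_months, treatment) to per-dimension
    (mean, SD) pairs and a cohort size ``n`` (see
    :data:`DEFAULT_MORPHOMETRY`); ``n_per_cell`` overrides every cohort
    size.  With SD = 0 the group means are reproduced exactly.
    """
    if cells is None:
        cells = DEFAULT_MORPHOMETRY
    if n_per_cell is not None and n_per_cell < 2:
        raise ValueError("n_per_cell must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    for (strain, age, treatment), spec in cells.items():
        n = n_per_cell if n_per_cell is not None else int(spec["n"])
        if n < 2:
            raise ValueError("each cell needs at least 2 eyes")
        draws = {}
        for dim in ("axial_length", "width_NT", "width_SI"):
            ms = spec.get(dim)
            if ms is None:
                draws[dim] = np.full(n, np.nan)
                continue
            mean, sd = ms
            if mean <= 0 or sd < 0:
                raise ValueError("means must be positive and SDs non-negative")
            draws[dim] = mean + sd * rng.standard_normal(n)
        for i in range(n):
            rows.append(
                {
                    "eye_id": f"{strain}_{age}m_{treatment}_{i:03d}",
                    "strain_label": strain,
                    "age_months": age,
                    "treatment": treatment,
                    "axial_length": draws["axial_length"][i],
                    "width_NT": draws["width_NT"][i],
                    "width_SI": draws["width_SI"][i],
                }
            )
    return pd.DataFrame(rows)
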