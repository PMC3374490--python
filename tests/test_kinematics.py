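"""Displacement fitting and Green-Lagrange strain evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scleramech.edge_geometry import AxisSpec, EdgeTrace, fit_ellipse, parameterize_meridian
from scleramech.kinematics import (
    circumferential_strain,
    deformed_diameter,
    fit_displacement,
    meridional_strain,
    strain_samples,
)
from scleramech.pipeline import PressureSchedule, analyze_eye
from scleramech.synth import NoiseModel, ShellGeometry, StretchField, simulate_inflation

from conftest import ellipse_points


@pytest.fixture(scope="module")
def reference_param():
    pts = ellipse_points(1.7, 1.9, tilt=np.pi / 2, t=np.linspace(0.25, 2.0, 40))
    fit = fit_ellipse(pts)
    axis = AxisSpec(np.zeros(2), np.array([0.0, 1.0]))
    return parameterize_meridian(fit, EdgeTrace("e", 7.0, pts), axis=axis)


class TestFitDisplacement:
    def test_identity_gives_zero_coefficients(self, reference_param):
        deformed = EdgeTrace("e", 15.0, reference_param.points.copy())
        fit = fit_displacement(reference_param, deformed)
        assert np.allclose(fit.coeffs_u1, 0, atol=1e-14)
        assert np.allclose(fit.coeffs_u2, 0, atol=1e-14)
        assert fit.fit_rms < 1e-14

    def test_exact_quartic_recovered(self, reference_param):
        rng = np.random.default_rng(1)
        q1 = rng.normal(0, 0.02, 5)
        q2 = rng.normal(0, 0.02, 5)
        t = reference_param.angle
        u = np.stack(
            [np.polynomial.polynomial.polyval(t, q) for q in (q1, q2)], axis=-1
        )
        deformed = EdgeTrace("e", 15.0, reference_param.points + u)
        fit = fit_displacement(reference_param, deformed)
        assert np.allclose(fit.coeffs_u1, q1, atol=1e-10)
        assert np.allclose(fit.coeffs_u2, q2, atol=1e-10)
        assert fit.fit_rms < 1e-12

    def test_quintic_residual_matches_normal_equations_oracle(self, reference_param):
        t = reference_param.angle
        u = np.stack([0.003 * t**5, -0.002 * t**5 + 0.01 * t], axis=-1)
        deformed = EdgeTrace("e", 15.0, reference_param.points + u)
        fit = fit_displacement(reference_param, deformed)
        # brute-force least squares via the normal equations
        V = np.vander(t, 5, increasing=True)
        beta = np.linalg.solve(V.T @ V, V.T @ u)
        resid = u - V @ beta
        oracle_rms = np.sqrt(np.mean(resid**2))
        assert fit.fit_rms == pytest.approx(oracle_rms, rel=1e-9)

    def test_mismatched_point_counts_rejected(self, reference_param):
        deformed = EdgeTrace("e", 15.0, reference_param.points[:-1])
        with pytest.raises(ValueError):
            fit_displacement(reference_param, deformed)


class TestStrains:
    def test_zero_displacement_zero_strain(self, reference_param):
        deformed = EdgeTrace("e", 15.0, reference_param.points.copy())
        fit = fit_displacement(reference_param, deformed)
        s = np.linspace(0.5, 2.0, 7)
        assert np.allclose(meridional_strain(reference_param, fit, s), 0, atol=1e-12)

    def test_axial_rigid_translation_is_strain_free(self, reference_param):
        # translation along the axis of revolution: exact objectivity
        deformed = EdgeTrace(
            "e", 15.0, reference_param.points + np.array([0.0, 0.15])
        )
        fit = fit_displacement(reference_param, deformed)
        s = np.linspace(0.5, 2.0, 7)
        E_phi = meridional_strain(reference_param, fit, s)
        d = deformed_diameter(reference_param, fit, s)
        t = reference_param.angle_from_s(s)
        D = 2 * np.abs(reference_param.ellipse.point(t)[:, 0])
        assert np.max(np.abs(E_phi)) < 1e-8
        assert np.max(np.abs(circumferential_strain(D, d))) < 1e-8

    def test_uniform_dilation_circle(self):
        # x = 1.05 X about the axis on a circular meridian: E = (1.05^2-1)/2.
        # E_phi carries the small quartic-representation bias of the
        # polynomial displacement fit; E_theta is nearly exact.
        geo = ShellGeometry(1.7, 1.7)
        eye = simulate_inflation(
            geo, StretchField.uniform(1.05), [7.0, 30.0], n_points=60,
            noise=NoiseModel(0.0, 0),
        )
        _, _, samples = analyze_eye(eye.traces, PressureSchedule(7.0, (30.0,)))
        assert np.allclose(samples.E_phi, 0.05125, atol=2e-4)
        assert np.allclose(samples.E_theta, 0.05125, atol=1e-5)

    def test_strain_monotone_in_uniform_stretch(self):
        geo = ShellGeometry(1.7, 1.7)
        previous = -np.inf
        for lam in (1.01, 1.03, 1.05, 1.08):
            eye = simulate_inflation(
                geo, StretchField.uniform(lam), [7.0, 30.0], n_points=30,
                noise=NoiseModel(0.0, 0),
            )
            E = float(np.atleast_1d(eye.truth.E_phi(eye.t_grid[:1], 30.0))[0])
            assert E > previous
            previous = E

    def test_matches_finite_difference_oracle(self, displacement_eye):
        """Strains from the analytic polynomial derivatives agree with
        central differences of the noiseless deformed positions."""
        eye = displacement_eye
        ref_fit = fit_ellipse(eye.reference_trace.points)
        param = parameterize_meridian(
            ref_fit, eye.reference_trace,
            axis=AxisSpec(np.zeros(2), np.array([0.0, 1.0])),
        )
        tr = eye.exact_traces[-1]
        disp = fit_displacement(param, tr)
        s_mid = 0.5 * (param.arc_length_s[10:30:4] + param.arc_length_s[11:31:4])
        E = np.atleast_1d(meridional_strain(param, disp, s_mid))
        # FD oracle on a fine material grid of the true map
        t_lo, t_hi = eye.geometry.arc_interval
        t_fine = np.linspace(t_lo, t_hi, 4000)
        X = eye.geometry.reference_points(t_fine)
        x = eye.truth.deformed_points(t_fine, tr.pressure)
        lam = np.linalg.norm(np.diff(x, axis=0), axis=1) / np.linalg.norm(
            np.diff(X, axis=0), axis=1
        )
        E_fd = 0.5 * (lam**2 - 1)
        s_fd = eye.s_of_t(0.5 * (t_fine[:-1] + t_fine[1:]))
        oracle = np.interp(s_mid, s_fd, E_fd)
        assert np.max(np.abs(E - oracle)) < 1e-6

    def test_extrapolation_refused(self, reference_param):
        deformed = EdgeTrace("e", 15.0, reference_param.points.copy())
        fit = fit_displacement(reference_param, deformed)
        with pytest.raises(ValueError):
            meridional_strain(reference_param, fit, [reference_param.arc_length_s[-1] + 1.0])


class TestCircumferential:
    @pytest.mark.parametrize(
        "D, d, expected",
        [(1.0, 1.0, 0.0), (2.0, 2.2, 0.105), (3.4, 3.4, 0.0)],
    )
    def test_diameter_ratio_arithmetic(self, D, d, expected):
        assert circumferential_strain(D, d) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            circumferential_strain(0.0, 1.0)
        with pytest.raises(ValueError):
            circumferential_strain(1.0, -0.1)

    @given(lam=st.floats(min_value=0.2, max_value=3.0))
    @settings(derandomize=True, max_examples=50)
    def test_green_lagrange_identity(self, lam):
        # E_theta of a pure circumferential stretch is (lambda^2 - 1)/2
        E = circumferential_strain(1.0, lam)
        assert E == pytest.approx(0.5 * (lam**2 - 1), rel=1e-12)
        assert E >= -0.5


def test_strain_samples_carry_regions_and_pressure(displacement_eye, schedule):
    eye = displacement_eye
    ref_fit = fit_ellipse(eye.reference_trace.points)
    param = parameterize_meridian(
        ref_fit, eye.reference_trace, axis=AxisSpec(np.zeros(2), np.array([0.0, 1.0]))
    )
    disp = fit_displacement(param, eye.exact_traces[3])
    s = param.arc_length_s[15:20]
    samples = strain_samples(param, disp, s)
    assert [sm.region for sm in samples] == list(param.region[15:20])
    assert all(sm.pressure == eye.pressures[3] for sm in samples)
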