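"""Synthetic-data generator: forward model, truth self-consistency, and
cohort simulators."""

import numpy as np
import pytest

from scleramech.glaucoma_metrics import (
    estimate_axon_count,
    positive_integral_iop,
)
from scleramech.synth import (
    DEFAULT_MORPHOMETRY,
    NoiseModel,
    ShellGeometry,
    StretchField,
    default_elevation_profile,
    expected_positive_integral,
    random_displacement_field,
    simulate_axon_cohort,
    simulate_inflation,
    simulate_iop_series,
    simulate_morphometry,
)

PRESSURES = (7.0, 15.0, 30.0)


class TestSimulateInflation:
    def test_uniform_sphere_strain_closed_form(self, spherical_geometry):
        eye = simulate_inflation(
            spherical_geometry, StretchField.uniform(1.05), [7.0, 30.0],
            noise=NoiseModel(0.0, 0),
        )
        assert np.allclose(eye.truth.E_phi(eye.t_grid, 30.0), 0.05125, atol=1e-12)
        assert np.allclose(eye.truth.E_theta(eye.t_grid, 30.0), 0.05125, atol=1e-12)

    def test_reference_only_is_identity(self, geometry):
        eye = simulate_inflation(
            geometry, StretchField(), [7.0], noise=NoiseModel(0.0, 0)
        )
        assert len(eye.traces) == 1
        assert np.array_equal(eye.traces[0].points, eye.exact_traces[0].points)
        assert np.allclose(eye.truth.E_phi(eye.t_grid, 7.0), 0.0, atol=1e-12)
        assert np.allclose(eye.truth.E_theta(eye.t_grid, 7.0), 0.0, atol=1e-12)

    def test_identity_stretch_traces_equal_reference(self, geometry):
        eye = simulate_inflation(
            geometry, StretchField.identity(), PRESSURES, noise=NoiseModel(0.0, 0)
        )
        for tr in eye.traces[1:]:
            assert np.allclose(tr.points, eye.traces[0].points, atol=1e-12)

    def test_sphere_laplace_law(self, spherical_geometry):
        # identity deformation, deformed radius 1.7 mm, p = 15 mmHg
        eye = simulate_inflation(
            spherical_geometry, StretchField.identity(), [7.0, 15.0],
            noise=NoiseModel(0.0, 0),
        )
        n_phi, n_theta = eye.truth.resultants(eye.t_grid, 15.0)
        expected = 15.0 * 133.322 * 1.7e-3 / 2.0  # ~1.7 N/m
        assert np.allclose(n_phi, expected, atol=1e-12)
        assert np.allclose(n_theta, expected, atol=1e-12)
        assert n_phi[0] == pytest.approx(1.7, abs=2e-4)

    def test_sphere_resultants_symmetric_at_all_points(self, spherical_geometry):
        eye = simulate_inflation(
            spherical_geometry, StretchField.uniform(1.04), PRESSURES,
            noise=NoiseModel(0.0, 0),
        )
        for p in PRESSURES[1:]:
            n_phi, n_theta = eye.truth.resultants(eye.t_grid, p)
            assert np.allclose(n_phi, n_theta, rtol=1e-12)

    def test_seeded_runs_bit_reproducible(self, geometry):
        a = simulate_inflation(geometry, StretchField(), PRESSURES, noise=NoiseModel(0.46, 5))
        b = simulate_inflation(geometry, StretchField(), PRESSURES, noise=NoiseModel(0.46, 5))
        c = simulate_inflation(geometry, StretchField(), PRESSURES, noise=NoiseModel(0.46, 6))
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.points, tb.points)
        assert not np.array_equal(a.traces[0].points, c.traces[0].points)

    @pytest.mark.parametrize("kind", ["ellipsoid", "stretch", "displacement"])
    def test_truth_strains_consistent_with_traces(self, geometry, kind):
        """Finite-difference strains of the noiseless traces agree with
        the closed-form truth (self-consistency oracle)."""
        if kind == "ellipsoid":
            field = StretchField(kind="ellipsoid", equatorial_scale=1.03, polar_scale=1.02)
        elif kind == "stretch":
            field = StretchField(
                kind="stretch",
                meridional_stretch_coeffs=(0.02, 0.005, -0.002),
                circumferential_stretch_coeffs=(0.025, -0.004, 0.001),
            )
        else:
            field = random_displacement_field(seed=3, geometry=geometry)
        eye = simulate_inflation(
            geometry, field, [7.0, 30.0], n_points=2000, noise=NoiseModel(0.0, 0)
        )
        X = eye.exact_traces[0].points
        x = eye.exact_traces[1].points
        lam = np.linalg.norm(np.diff(x, axis=0), axis=1) / np.linalg.norm(
            np.diff(X, axis=0), axis=1
        )
        E_fd = 0.5 * (lam**2 - 1)
        t_mid = 0.5 * (eye.t_grid[:-1] + eye.t_grid[1:])
        assert np.max(np.abs(E_fd - eye.truth.E_phi(t_mid, 30.0))) < 1e-6
        lam_th = x[:, 0] / X[:, 0]
        E_th_fd = 0.5 * (lam_th**2 - 1)
        assert np.max(np.abs(E_th_fd - eye.truth.E_theta(eye.t_grid, 30.0))) < 1e-9

    def test_unphysical_and_invalid_inputs_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_inflation(geometry, StretchField(), [7.0, 15.0, 12.0])
        with pytest.raises(ValueError):
            simulate_inflation(geometry, StretchField(), PRESSURES, n_points=5)
        shrinking = StretchField(kind="ellipsoid", equatorial_scale=0.97, polar_scale=1.0)
        with pytest.raises(ValueError):
            simulate_inflation(geometry, shrinking, PRESSURES)
        with pytest.raises(ValueError):
            NoiseModel(-0.1)

    def test_random_displacement_fields_are_physical(self, geometry):
        for seed in range(5):
            field = random_displacement_field(seed=seed, geometry=geometry)
            eye = simulate_inflation(geometry, field, PRESSURES, noise=NoiseModel(0.0, 0))
            for p in PRESSURES:
                assert np.all(np.atleast_1d(eye.truth.lambda_phi(eye.t_grid, p)) >= 1 - 1e-9)
                assert np.all(np.atleast_1d(eye.truth.lambda_theta(eye.t_grid, p)) >= 1 - 1e-9)


class TestGeometry:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ShellGeometry(semi_axis_polar=-1.0)
        with pytest.raises(ValueError):
            ShellGeometry(onh_gap_angle=2.0, fixture_gap_angle=2.0)

    def test_arc_length_matches_quadrature(self):
        from scipy.integrate import quad

        for geo in (ShellGeometry(1.9, 1.7), ShellGeometry(1.6, 1.8)):
            for t in (0.4, 1.2, 2.3):
                oracle, _ = quad(
                    lambda u: np.sqrt(
                        geo.semi_axis_equatorial**2 * np.cos(u) ** 2
                        + geo.semi_axis_polar**2 * np.sin(u) ** 2
                    ),
                    0.0, t, epsabs=1e-13,
                )
                assert geo.arc_length(t) == pytest.approx(oracle, abs=1e-9)
                assert geo.param_from_arc_length(oracle) == pytest.approx(t, abs=1e-9)


class TestIOPSimulation:
    def test_zero_elevation_zero_noise_identical_arms(self):
        tr, fe = simulate_iop_series(elevation_profile=0.0, noise_sd=0.0)
        assert np.array_equal(tr.iop, fe.iop)

    def test_constant_elevation_integral(self):
        days = np.arange(0, 43, 7)
        tr, fe = simulate_iop_series(
            elevation_profile=5.0, measurement_days=days, noise_sd=0.0
        )
        assert positive_integral_iop(tr, fe) == pytest.approx(210.0, abs=1e-9)

    def test_monte_carlo_mean_recovers_truth_integral(self):
        # linearly decaying elevation, 10 -> 0 mmHg over 42 days
        profile = np.maximum(10.0 * (1 - np.arange(43) / 42.0), 0.0)
        days = np.arange(0, 43, 7)
        truth = expected_positive_integral(profile, days)
        vals = []
        for seed in range(500):
            tr, fe = simulate_iop_series(
                elevation_profile=profile, measurement_days=days,
                noise_sd=2.0, seed=seed,
            )
            vals.append(positive_integral_iop(tr, fe))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        # the positive-part integral of a noisy difference is biased
        # upward where the true difference is near zero; allow the bias
        # of the last (near-zero) intervals on top of 2 SE
        near_zero_bias = 2.0 * np.sqrt(2 / np.pi) * 7.0  # E|N(0, sd*sqrt2)| per day x last week
        assert abs(vals.mean() - truth) < 2 * se + near_zero_bias

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_iop_series(noise_sd=-1.0)
        with pytest.raises(ValueError):
            simulate_iop_series(measurement_days=[0, 50])
        with pytest.raises(ValueError):
            simulate_iop_series(measurement_days=[5, 3])


class TestAxonSimulation:
    def test_deterministic_recovers_count(self):
        (sample,) = simulate_axon_cohort(
            true_count=46905, nerve_area=0.0889, field_area=0.0016,
            n_fields=5, loss_fraction=0.0, dispersion=0.0,
        )
        # five 0.0016 mm^2 fields sample 9% of the 0.0889 mm^2 nerve
        assert 5 * 0.0016 / 0.0889 == pytest.approx(0.09, abs=0.001)
        assert estimate_axon_count(sample) == 46905

    def test_half_loss_halves_estimate(self):
        (sample,) = simulate_axon_cohort(loss_fraction=0.5, dispersion=0.0)
        assert estimate_axon_count(sample) == pytest.approx(46905 * 0.5, abs=1)

    def test_poisson_sampling_nearly_unbiased(self):
        # dispersion -> 0+ is pure Poisson; 1000 replicate nerves
        samples = simulate_axon_cohort(
            dispersion=1e-9, seed=10, n_nerves=1000
        )
        counts = np.array([estimate_axon_count(s) for s in samples])
        assert abs(counts.mean() - 46905) / 46905 < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_axon_cohort(loss_fraction=1.0)
        with pytest.raises(ValueError):
            simulate_axon_cohort(n_fields=0)
        with pytest.raises(ValueError):
            simulate_axon_cohort(field_area=0.02, n_fields=5)


class TestMorphometrySimulation:
    def test_zero_sd_reproduces_cell_means(self):
        cells = {
            k: {
                dim: ((v[0], 0.0) if isinstance(v, tuple) else v)
                for dim, v in spec.items()
            }
            for k, spec in DEFAULT_MORPHOMETRY.items()
        }
        df = simulate_morphometry(cells, seed=0)
        means = df.groupby(["strain_label", "age_months", "treatment"])[
            "axial_length"
        ].mean()
        for (strain, age, treat), spec in DEFAULT_MORPHOMETRY.items():
            assert means[(strain, age, treat)] == pytest.approx(
                spec["axial_length"][0], abs=1e-12
            )

    def test_percent_difference_recovered_within_2se(self):
        # Aca23 vs WT axial length at 4 months, n = 37 / 127
        df = simulate_morphometry(seed=42)
        sel = (df.age_months == 4) & (df.treatment == "control")
        aca = df.loc[sel & (df.strain_label == "Aca23"), "axial_length"]
        wt = df.loc[sel & (df.strain_label == "WT"), "axial_length"]
        est = 100.0 * (aca.mean() - wt.mean()) / wt.mean()
        truth = 100.0 * (3.81 - 3.39) / 3.39
        # propagate the SEs of both group means onto the percent difference
        se = (
            100.0
            / 3.39
            * np.sqrt(aca.std(ddof=1) ** 2 / len(aca) + wt.std(ddof=1) ** 2 / len(wt))
        )
        assert abs(est - truth) < 2 * se

    def test_sample_sd_close_to_population_sd(self):
        cells = {("X", 4, "control"): {"axial_length": (3.5, 0.1), "width_NT": (3.3, 0.1), "width_SI": None, "n": 1000}}
        df = simulate_morphometry(cells, seed=7)
        assert abs(df.axial_length.std(ddof=1) - 0.1) / 0.1 < 0.10

    def test_small_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_morphometry(n_per_cell=1)


def test_default_elevation_profile_scale():
    profile = default_elevation_profile()
    days = np.arange(0, 43, 7)
    integral = expected_positive_integral(profile, days)
    assert 60 < integral < 130  # cohort-mean exposure range
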