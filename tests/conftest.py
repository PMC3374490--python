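import numpy as np
import pytest

from scleramech.pipeline import PressureSchedule
from scleramech.synth import (
    NoiseModel,
    ShellGeometry,
    StretchField,
    random_displacement_field,
    simulate_inflation,
)

PRESSURES = (7.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0)


@pytest.fixture(scope="session")
def schedule():
    return PressureSchedule(reference_pressure=7.0, steps=PRESSURES[1:])


@pytest.fixture(scope="session")
def geometry():
    return ShellGeometry()


@pytest.fixture(scope="session")
def spherical_geometry():
    return ShellGeometry(semi_axis_polar=1.7, semi_axis_equatorial=1.7)


@pytest.fixture(scope="session")
def displacement_eye(geometry):
    """Noise-free synthetic eye whose displacement field lies exactly in
    the quartic function class of the analysis."""
    field = random_displacement_field(seed=11, geometry=geometry)
    return simulate_inflation(
        geometry, field, PRESSURES, n_points=40, noise=NoiseModel(0.0, 0)
    )


@pytest.fixture(scope="session")
def ellipsoid_eye(geometry):
    """Noise-free eye whose deformed configurations are exact ellipsoids."""
    field = StretchField(kind="ellipsoid", equatorial_scale=1.03, polar_scale=1.02)
    return simulate_inflation(
        geometry, field, PRESSURES, n_points=40, noise=NoiseModel(0.0, 0)
    )


def ellipse_points(a, b, tilt=0.0, center=(0.0, 0.0), t=None, n=40, span=(0.2, 2.6)):
    """Exact points on an ellipse arc (helper shared across test modules)."""
    if t is None:
        t = np.linspace(span[0], span[1], n)
    c, s = np.cos(tilt), np.sin(tilt)
    R = np.array([[c, -s], [s, c]])
    pts = np.stack([a * np.cos(t), b * np.sin(t)], axis=-1) @ R.T
    return pts + np.asarray(center, dtype=float)
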