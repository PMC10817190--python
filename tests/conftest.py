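import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from contourdyn.contour import GPRConfig, circle_samples, fit_contour
from contourdyn.fixtures import ellipse_points, star_points
from contourdyn.simulate import SimulationConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def circle80():
    """Smooth contour fitted to a clean circle of area 80 um^2."""
    return fit_contour(circle_samples(80.0, 100), GPRConfig(0.6, 0.05),
                       n_markers=100, n_dense=384)


@pytest.fixture(scope="session")
def star_contour():
    """Five-armed star smoothed with the figure-style hyperparameters."""
    return fit_contour(star_points(), GPRConfig(0.4, 0.01),
                       n_markers=100, n_dense=384)


@pytest.fixture(scope="session")
def ellipse21():
    """Tightly fitted 2 x 1 um ellipse (near-interpolating regression)."""
    return fit_contour(ellipse_points(2.0, 1.0, 200), GPRConfig(0.9, 1e-4),
                       n_markers=100, n_dense=512)


@pytest.fixture(scope="session")
def short_track():
    """One short reference-parameter simulation shared across tests."""
    cfg = SimulationConfig(T=60.0, dt=0.5, n_markers=100, seed=4, n_dense=384)
    return simulate(cfg)
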