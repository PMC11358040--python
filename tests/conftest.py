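import numpy as np
import pytest

from trsaxs.io import CurveMeta, ScatteringCurve
from trsaxs.pipeline import ScreenConfig, run_screen
from trsaxs.synth import ParticleModel, SimConfig, simulate_screen_plate


@pytest.fixture(scope="session")
def q_grid():
    """Default acquisition grid, 0.01-0.59 A^-1."""
    return np.linspace(0.01, 0.59, 256)


@pytest.fixture(scope="session")
def model():
    return ParticleModel()


def make_curve(q, intensity, sigma=None, label="c"):
    return ScatteringCurve(np.asarray(q, float), np.asarray(intensity, float),
                           None if sigma is None else np.asarray(sigma, float),
                           CurveMeta(label=label))


@pytest.fixture(scope="session")
def default_plate():
    """One seeded default screen plate (raw series + truth)."""
    return simulate_screen_plate(seed=1)


@pytest.fixture(scope="session")
def screen_report():
    """Full pipeline run on the default synthetic plate, seed 1."""
    return run_screen(ScreenConfig(seed=1))


@pytest.fixture(scope="session")
def screen_truth(screen_report):
    return screen_report.meta["truth"].set_index("compound_id")
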