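"""Shared fixtures: phantoms and model bundles built once per session."""

import numpy as np
import pytest
from hypothesis import settings

import littplan as lp
from littplan.anatomy import HeadModel, distance_field, extract_roi

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_phantom():
    """Default left-sided phantom plus its analytic ground truth."""
    return lp.generate_phantom(lp.PhantomParams())


@pytest.fixture(scope="session")
def base_model(base_phantom):
    vol, gt = base_phantom
    return HeadModel.from_phantom(vol, gt)


@pytest.fixture(scope="session")
def base_plan(base_model):
    return lp.plan(base_model)


@pytest.fixture(scope="session")
def planar_model():
    """Spherical head with a single mid-sagittal critical sheet."""
    vol, skull = lp.planar_risk_phantom()
    return HeadModel(
        volume=vol,
        skull=skull,
        side="left",
        ventricles=extract_roi(vol, "ventricles"),
        critical_field=distance_field(extract_roi(vol, "critical")),
    )


def parallel_trajectory(distance: float) -> lp.Trajectory:
    """Planar-phantom trajectory at a given closest approach to the x=0 sheet."""
    return lp.Trajectory((float(distance), -65.0, 0.0), (float(distance), 20.0, 0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
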