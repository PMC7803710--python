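"""Shared fixtures.

Full-scale phantoms and pipeline runs are expensive, so they are generated
once per session and shared; unit tests that only need geometry use the tiny
phantom helper instead.
"""

import dataclasses
import time

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from ztebone import PipelineConfig, default_specs, generate_phantom
from ztebone.phantom import Ellipsoid, PhantomSpec
from ztebone.core import Grid
from ztebone.segment import bb_only_pipeline, zte_driven_pipeline


def tiny_spec(**overrides) -> PhantomSpec:
    """A small, fast head phantom for unit tests (coarse master grid)."""
    base = dict(
        name="tiny",
        head_semiaxes_mm=(14.0, 17.0, 15.5),
        scalp_thickness_mm=4.0,
        skull_thickness_mm=2.0,
        master_spacing_mm=0.8,
        margin_mm=5.0,
        noise_sigma=0.0,
        bias_amplitude=0.0,
    )
    base.update(overrides)
    spec = PhantomSpec(**base)
    if spec.grids is None:
        spec.grids = {
            "bb": spec._grid_for_spacing((1.0, 1.0, 1.2)),
            "zte": spec._grid_for_spacing((1.2, 1.2, 1.6)),
        }
    return spec


def tiny_sinus_spec(**overrides) -> PhantomSpec:
    cavities = (Ellipsoid(center_mm=(0.0, 9.5, 1.5), semiaxes_mm=(3.0, 3.5, 3.0),
                          name="sinus"),)
    return tiny_spec(air_cavities=cavities, **overrides)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def sinus_set(specs):
    return generate_phantom(specs["sinus"])


@pytest.fixture(scope="session")
def clean_set(specs):
    return generate_phantom(specs["clean"], modalities=("bb", "zte"))


@pytest.fixture(scope="session")
def tendon_set(specs):
    return generate_phantom(specs["tendon"], modalities=("bb", "zte"))


@pytest.fixture(scope="session")
def moved_set(specs):
    return generate_phantom(specs["moved"], modalities=("bb", "zte"))


@pytest.fixture(scope="session")
def sinus_bb_only(sinus_set, config):
    return bb_only_pipeline(sinus_set.bb, config)


@pytest.fixture(scope="session")
def sinus_zte_driven(sinus_set, config):
    """(result, wall_seconds) for the ZTE-driven run on the sinus phantom."""
    t0 = time.perf_counter()
    result = zte_driven_pipeline(sinus_set.zte, sinus_set.bb, config)
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def sinus_fiesta_driven(sinus_set, config):
    return zte_driven_pipeline(sinus_set.zte, sinus_set.fiesta, config)


@pytest.fixture(scope="session")
def tendon_bb_only(tendon_set, config):
    return bb_only_pipeline(tendon_set.bb, config)


@pytest.fixture(scope="session")
def tendon_zte_driven(tendon_set, config):
    return zte_driven_pipeline(tendon_set.zte, tendon_set.bb, config)


@pytest.fixture(scope="session")
def clean_zte_driven(clean_set, config):
    return zte_driven_pipeline(clean_set.zte, clean_set.bb, config)


@pytest.fixture(scope="session")
def tiny_set():
    return generate_phantom(tiny_spec(noise_sigma=20.0))


@pytest.fixture(scope="session")
def tiny_sinus_set():
    return generate_phantom(tiny_sinus_spec(noise_sigma=20.0))
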