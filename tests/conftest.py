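"""Shared fixtures.

Heavy builds are session-scoped and shared: the demo-scale build exercises
the full pipeline cheaply, the half-resolution build/series carries the
volume-stability and mapping-quality measurements, and the native-resolution
build carries the liver-calibration and tumor-kinematics measurements.
"""

import warnings

import numpy as np
import pytest

from liverphantom.anatomy import build_anatomy
from liverphantom.grid import default_grid
from liverphantom.pipeline import RunConfig, build_reference, build_series, measure_build
from liverphantom.structures import StructureTable

SEED = 1


@pytest.fixture(scope="session")
def table():
    return StructureTable.default()


@pytest.fixture(scope="session")
def demo_build():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference(RunConfig(grid_scale=4.0, seed=7))


@pytest.fixture(scope="session")
def demo_series(demo_build):
    return build_series(demo_build)


@pytest.fixture(scope="session")
def half_build():
    """Half-resolution (128x128x75) reference build."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference(RunConfig(grid_scale=2.0, seed=SEED))


@pytest.fixture(scope="session")
def half_series(half_build):
    return build_series(half_build)


@pytest.fixture(scope="session")
def half_measurement(half_build, half_series):
    return measure_build(half_build, half_series)


@pytest.fixture(scope="session")
def full_anatomy():
    """Native 256x256x150 anatomy (labels only — no texture)."""
    return build_anatomy(default_grid(1.0))


@pytest.fixture(scope="session")
def fullres_kinematics():
    """Native-grid phases P1 and P5 of the normal series, measured."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        build = build_reference(RunConfig(grid_scale=1.0, seed=SEED))
        series = build_series(build, phases=[0.0, 2.0])
    return build, series, measure_build(build, series)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
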