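import numpy as np
import pytest

from clickmap3d import pipeline, synthgen


@pytest.fixture(scope="session")
def toy_atlas():
    """Small symmetric atlas shared across tests (6 regions, 10 um voxels)."""
    return synthgen.build_toy_atlas(10.0, (48, 48, 48), 6, seed=100)


@pytest.fixture(scope="session")
def small_atlas():
    """Even smaller atlas for fast geometry tests."""
    return synthgen.build_toy_atlas(10.0, (24, 24, 24), 4, seed=7)


@pytest.fixture(scope="session")
def benchmark_result(toy_atlas):
    """The fixed-seed synthetic benchmark, run once per session."""
    return pipeline.run_benchmark(seed=1, atlas=toy_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
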