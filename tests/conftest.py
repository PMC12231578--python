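import numpy as np
import pytest

from becharlib import make_fixture, run_pipeline
from becharlib.library import LibraryConfig, design_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_library():
    """5-pair library (1 scrambled control, mixed strands)."""
    cfg = LibraryConfig(n_pairs=5, n_negative_controls=1, seed=42)
    return design_library(cfg)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Full pipeline run on the tiny fixture (seconds)."""
    return run_pipeline(make_fixture("tiny", seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """Full pipeline run on the 50-pair recovery fixture (minutes).

    The editor profile is the narrow-window preset: efficiency 0.3,
    window support -18..-13, spectrum 67:16:18, no target-strand editing.
    """
    return run_pipeline(make_fixture("small", seed=1))
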