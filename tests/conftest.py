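import numpy as np
import pytest

from syntepan import SimConfig, simulate_hits, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """10-genome, 300-SG panel with a planted block; zero hit noise."""
    cfg = SimConfig(
        seed=42,
        group_sizes={"popA": 5, "popB": 5},
        n_sgs=300,
        mixture=(0.5, 0.2, 0.2, 0.1),
        planted_blocks=(("chr1", 50, 90, "popA"),),
    )
    annotations, groups, truth = simulate_panel(cfg)
    hits = simulate_hits(annotations, truth)
    return cfg, annotations, groups, truth, hits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
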