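import numpy as np
import pytest

from ranksets import PlantedSet, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples with known values."""
    from ranksets import ExpressionMatrix

    return ExpressionMatrix(
        probe_ids=["pA", "pB", "pC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[5.0, 1.0, 3.0, 2.0], [4.0, 0.0, 3.5, 1.0], [0.0, 9.0, 1.0, 8.0]]
        ),
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Standard desk-scale benchmark: 200 probes x 60 samples, one 10-probe
    set active in 15 samples, shift 3 SD."""
    cfg = SynthConfig(planted_sets=(PlantedSet(),), seed=1)
    return generate(cfg)


@pytest.fixture(scope="session")
def three_block_fixture():
    """Three disjoint 10-probe planted sets with disjoint active supports."""
    cfg = SynthConfig(
        planted_sets=tuple(PlantedSet() for _ in range(3)), seed=1
    )
    return generate(cfg)
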