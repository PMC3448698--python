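import numpy as np
import pandas as pd
import pytest

from probescreen import ProbeLevelMatrix, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One mid-sized simulated dataset shared by read-only tests."""
    config = SimulationConfig(n_probesets=300, seed=7)
    data, truth = generate_dataset(config)
    return config, data, truth


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-probe / 2-set / 4-sample probe-level matrix."""
    intensities = pd.DataFrame(
        [[10.0, 20.0, 30.0, 40.0],
         [11.0, 22.0, 33.0, 44.0],
         [5.0, 5.0, 5.0, 5.0],
         [8.0, 6.0, 4.0, 2.0]],
        index=["a_p1", "a_p2", "b_p1", "b_p2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    probe_map = pd.Series(["a", "a", "b", "b"], index=intensities.index)
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=intensities.columns)
    return ProbeLevelMatrix(intensities, probe_map, groups)


@pytest.fixture()
def two_group_theta():
    """Null expression table: 500 probe sets, 2 groups x 3 replicates."""
    rng = np.random.default_rng(42)
    cols = [f"s{i}" for i in range(6)]
    baseline = np.exp(rng.normal(6, 1, size=(500, 1)))
    theta = pd.DataFrame(baseline * (1 + rng.normal(0, 0.1, size=(500, 6))),
                         index=[f"ps{i:04d}" for i in range(500)], columns=cols)
    groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=cols)
    return theta, groups
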