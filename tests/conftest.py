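import numpy as np
import pandas as pd
import pytest

from effectorkit.expression import CountMatrix
from effectorkit.synthetic import SimulationConfig, simulate_repertoires


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 transcripts x 6 libraries (3 head, 3 body).

    One flat transcript, one strongly head-biased, one large balanced
    reference keeping the library compositions comparable.
    """
    libs = ["h1", "h2", "h3", "b1", "b2", "b3"]
    counts = pd.DataFrame(
        [
            [100, 110, 90, 102, 95, 105],
            [800, 900, 850, 10, 12, 9],
            [10000, 10050, 9950, 10020, 9990, 10010],
        ],
        index=pd.Index(["t_flat", "t_head", "t_ref"], name="transcript"),
        columns=libs,
    )
    design = pd.DataFrame(
        {"tissue": ["head"] * 3 + ["body"] * 3, "replicate": ["1", "2", "3"] * 2},
        index=pd.Index(libs, name="library"),
    )
    lengths = pd.Series([1000, 1000, 1000], index=counts.index, name="length")
    return CountMatrix(counts=counts, design=design, lengths=lengths)


@pytest.fixture(scope="session")
def default_simulation():
    """One shared default-condition simulation (seed 11)."""
    config = SimulationConfig(seed=11)
    records, annotations, truth = simulate_repertoires(config)
    return config, records, annotations, truth


def null_count_matrix(n: int, seed: int, mean_log: float = np.log(300.0),
                      sd_log: float = 0.5, phi: float = 0.1) -> CountMatrix:
    """NB counts with identical head/body means (no differential expression)."""
    rng = np.random.default_rng(seed)
    r = 1.0 / phi
    mu = np.exp(rng.normal(mean_log, sd_log, n))
    mat = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 6))
    libs = ["h1", "h2", "h3", "b1", "b2", "b3"]
    design = pd.DataFrame(
        {"tissue": ["head"] * 3 + ["body"] * 3, "replicate": ["1", "2", "3"] * 2},
        index=pd.Index(libs, name="library"),
    )
    counts = pd.DataFrame(mat, index=[f"t{i}" for i in range(n)], columns=libs)
    return CountMatrix(counts=counts, design=design)
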