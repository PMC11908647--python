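import logging

import numpy as np
import pytest

from trajalign.io import TrajectoryData

logging.getLogger("trajalign").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(
    n_genes=8, n_cells=40, seed=0, name="T", pseudotime=None
) -> TrajectoryData:
    """Small random trajectory with smoothly drifting expression."""
    r = np.random.default_rng(seed)
    p = np.sort(r.uniform(0, 1, n_cells)) if pseudotime is None else np.asarray(pseudotime)
    centers = np.linspace(0, 1, n_genes)
    X = np.exp(-((p[None, :] - centers[:, None]) ** 2) / 0.05) * 3.0
    X += r.normal(0, 0.05, X.shape)
    X = np.abs(X)
    return TrajectoryData(
        name=name,
        genes=[f"g{k}" for k in range(n_genes)],
        cells=[f"{name}c{l}" for l in range(len(p))],
        expression=X,
        pseudotime=p,
    )


@pytest.fixture
def small_trajectory():
    return make_trajectory()
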