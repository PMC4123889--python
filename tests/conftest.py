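import numpy as np
import pandas as pd
import pytest

import spfmlm as sf


@pytest.fixture(scope="session")
def queen_5x5():
    return sf.make_lattice_weights(5, 5, "queen")


@pytest.fixture(scope="session")
def rook_4x4():
    return sf.make_lattice_weights(4, 4, "rook")


def random_weights(rng: np.random.Generator, n: int) -> sf.SpatialWeights:
    """Random connected-ish symmetric binary weights for oracle checks."""
    m = np.triu((rng.random((n, n)) < 0.4).astype(float), k=1)
    # guarantee no empty matrix: wire a ring
    for i in range(n):
        m[min(i, (i + 1) % n), max(i, (i + 1) % n)] = 1.0
    m = m + m.T
    ids = tuple(f"a{i:02d}" for i in range(n))
    return sf.SpatialWeights(ids, m)


@pytest.fixture(scope="session")
def balanced_two_level():
    """Balanced random-intercept data with known generating values."""
    rng = np.random.default_rng(0)
    j, n = 200, 50
    ids = [f"a{k:03d}" for k in range(j)]
    u0 = rng.normal(0, 1.0, j)  # tau00 = 1
    y = 10.0 + np.repeat(u0, n) + rng.normal(0, 2.0, j * n)  # sigma2 = 4
    ind = pd.DataFrame({"area_id": np.repeat(ids, n), "outcome": y})
    nbh = pd.DataFrame({"area_id": ids})
    return sf.TwoLevelData(ind, nbh), {"tau00": 1.0, "sigma2": 4.0, "mu": 10.0, "n_per_area": n}


@pytest.fixture(scope="session")
def planted_pipeline_run():
    """One pipeline run on an 8x8 Queen lattice with a planted eigenvector signal.

    Shared across pipeline tests; the signal (eigenvector index 1) is
    independent of all covariates.
    """
    weights = sf.make_lattice_weights(8, 8, "queen")
    coef = sf.eigen_coefficient(1062.0, 64, 0.8)
    cfg = sf.SyntheticConfig(
        rows=8,
        cols=8,
        n_per_area=40,
        spatial_signal={"kind": "eigenvector", "indices": [1], "coefficients": [coef]},
        seed=11,
    )
    data, truth = sf.simulate(cfg)
    pcfg = sf.PipelineConfig(
        fixed_individual=("female", "income", "unemployed", "low_stress"),
        fixed_neighborhood=("deprivation", "doctors_per_1000", "lgfi"),
        random_slope="income",
        seed=11,
    )
    report = sf.run_pipeline(data, weights, pcfg)
    return data, weights, cfg, pcfg, truth, report
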