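import numpy as np
import pandas as pd
import pytest

from crt_effects.core import ClusterRecord, CRTData
from crt_effects.dgp import DGPConfig, generate_sim1, generate_sim2


def build_trial(
    rng: np.random.Generator,
    J: int = 12,
    sizes=None,
    n_w: int = 2,
    pair_ids: bool = False,
) -> CRTData:
    """Small random trial with binary outcomes; arms balanced by construction."""
    sizes = sizes if sizes is not None else rng.integers(5, 40, size=J)
    arms = np.array([1, 0] * (J // 2))
    clusters = []
    for j in range(J):
        n = int(sizes[j])
        W = pd.DataFrame({f"W{k + 1}": rng.normal(size=n) for k in range(n_w)})
        p = 0.2 + 0.5 / (1 + np.exp(-W["W1"].to_numpy()))
        Y = (rng.random(n) < p).astype(float)
        clusters.append(
            ClusterRecord(
                cluster_id=f"c{j}",
                arm=int(arms[j]),
                covariates={"E1": float(rng.normal()), "E2": float(rng.normal())},
                W=W,
                Y=Y,
                pair_id=f"p{j // 2}" if pair_ids else None,
            )
        )
    return CRTData(clusters)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_trial(rng):
    return build_trial(rng)


@pytest.fixture(scope="session")
def sim1_trial():
    return generate_sim1(DGPConfig(study="sim1", J=20, seed=11))


@pytest.fixture(scope="session")
def sim2_trial():
    return generate_sim2(DGPConfig(study="sim2", J=20, seed=11))


def toy_trial(single_arm: bool = True) -> CRTData:
    """Five clusters with event counts (2,2,2,2,7500), sizes (10,10,10,10,10000).

    A textbook illustration of how cluster-level and individual-level
    summaries diverge when cluster sizes vary wildly.
    """
    sizes = [10, 10, 10, 10, 10000]
    events = [2, 2, 2, 2, 7500]
    clusters = []
    for j, (n, d) in enumerate(zip(sizes, events)):
        Y = np.concatenate([np.ones(d), np.zeros(n - d)])
        clusters.append(
            ClusterRecord(
                cluster_id=f"t{j}",
                arm=0 if single_arm else int(j % 2),
                covariates={},
                W=pd.DataFrame(index=range(n)),
                Y=Y,
            )
        )
    return CRTData(clusters)


@pytest.fixture
def toy():
    return toy_trial()
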