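"""Synthetic data-generating processes for the two simulation studies.

Both emulate a pair-matched CRT with J=20 clusters of widely varying size.

* **Study 1** — clusters of mean size 150 (SD 80, floor 30). Two latent
  cluster factors drive four individual covariates; the binary outcome
  depends on treatment, W1, W2, E1, and a treatment-by-W2 interaction, so
  W1/W2 (and their cluster means) are the useful adjustment covariates
  while W3/W4 are pure noise. Cluster size does not enter the outcome, so
  cluster-level and individual-level effects coincide.
* **Study 2** — informative cluster size: clusters of mean size 400
  (SD 250, floor 30); the outcome risk decreases with the scaled cluster
  size N/150, and the treatment effect is stronger in larger clusters,
  driving the cluster-level and individual-level effects apart.

Throughout, ``Norm(a, b)`` is read as mean ``a`` and *standard deviation*
``b``. Cluster sizes are clamped at a minimum of 30 and rounded to the
nearest integer. Clusters are pair-matched on E2 by exact minimum-cost
non-bipartite matching, and one cluster per pair is randomized to
treatment. Under the null variant every treatment term in the outcome
model is set to zero, so coupled counterfactuals are identical and the
true ratios equal 1 exactly.

True effect values are computed from counterfactual outcomes on a large
generated population (2500 clusters for study 1, 1000 for study 2), using
a shared uniform draw per individual under both treatment levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ClusterRecord, CRTData

__all__ = ["DGPConfig", "TruthTable", "generate_sim1", "generate_sim2", "pair_match", "compute_truth"]

MIN_CLUSTER_SIZE = 30
_POP_DEFAULT = {"sim1": 2500, "sim2": 1000}


@dataclass
class DGPConfig:
    """Configuration of one simulated trial or truth population."""

    study: Literal["sim1", "sim2"] = "sim1"
    J: int = 20
    null_effect: bool = False
    seed: int = 0
    population_size: int | None = None

    def pop(self) -> int:
        return self.population_size or _POP_DEFAULT[self.study]


@dataclass(frozen=True)
class TruthTable:
    """Finite-population true effects computed from counterfactuals."""

    cluster_ratio: float
    individual_ratio: float
    geometric_ratio: float
    cluster_mean1: float
    cluster_mean0: float
    individual_mean1: float
    individual_mean0: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def for_level(self, level: str, geometric: bool = False) -> float:
        if geometric:
            return self.geometric_ratio
        return self.cluster_ratio if level == "cluster" else self.individual_ratio


def _draw_clusters(study: str, n: int, rng: np.random.Generator) -> dict:
    """Cluster-level covariates, sizes, latent factors; flat individual draws."""
    if study == "sim1":
        E1 = rng.normal(2.0, 1.0, n)
        E2 = rng.normal(0.0, 1.0, n)
        N = np.maximum(rng.normal(150.0, 80.0, n), MIN_CLUSTER_SIZE)
        N = np.rint(N).astype(int)
        UE1 = rng.uniform(-0.2, 1.5, n)
        UE2 = rng.uniform(-0.5, 0.5, n)
        rep = np.repeat(np.arange(n), N)
        nt = int(N.sum())
        W = {
            "W1": rng.normal(2.0 * UE1[rep], 0.35),
            "W2": rng.normal(4.0 * UE1[rep], 0.9),
            "W3": rng.normal(UE2[rep], 0.5),
            "W4": rng.normal(UE2[rep], 0.5),
        }
    elif study == "sim2":
        E1 = rng.normal(0.0, 1.0, n)
        E2 = rng.normal(0.0, 1.0, n)
        N = np.maximum(rng.normal(400.0, 250.0, n), MIN_CLUSTER_SIZE)
        N = np.rint(N).astype(int)
        UE1 = rng.uniform(-1.0, 1.0, n)
        UE2 = rng.uniform(-1.0, 1.0, n)
        UE3 = rng.uniform(-1.0, 1.0, n)
        rep = np.repeat(np.arange(n), N)
        nt = int(N.sum())
        W = {
            "W1": rng.normal(UE1[rep], 0.5),
            "W2": rng.normal(UE2[rep], 0.5),
            "W3": rng.normal(UE3[rep], 0.5),
        }
    else:
        raise ValueError(f"unknown study {study!r}")
    U = rng.uniform(0.0, 1.0, nt)
    return {"E1": E1, "E2": E2, "N": N, "rep": rep, "W": W, "U": U, "study": study}


def _outcome_prob(d: dict, a, null_effect: bool):
    """Success probability per individual under treatment level ``a``.

    ``a`` may be a scalar (counterfactual) or a per-individual array.
    Under the null every treatment term is zeroed.
    """
    rep = d["rep"]
    W = d["W"]
    a_term = 0.0 if null_effect else a
    if d["study"] == "sim1":
        lp = (
            -0.75
            - 0.35 * a_term
            + 0.8 * W["W1"]
            + 0.4 * W["W2"]
            - 0.3 * d["E1"][rep]
            - 0.2 * a_term * W["W2"]
        )
    else:
        n_scaled = d["N"][rep] / 150.0
        lp = (
            0.5
            + W["W1"] / 6.0
            + W["W2"] / 2.0
            + W["W3"] / 4.0
            + d["E1"][rep] / 5.0
            + d["E2"][rep] / 5.0
            - n_scaled / 8.0
            - a_term * n_scaled / 5.0
        )
    return expit(lp)


def pair_match(clusters: Sequence, on: str = "E2") -> list[tuple[int, int]]:
    """Pair an even number of clusters minimizing total |difference| in ``on``.

    ``clusters`` may be :class:`~crt_effects.core.ClusterRecord` objects (the
    named covariate is read from each) or a plain sequence of numbers.
    Exact minimum-weight perfect matching (blossom algorithm) is used up to
    200 clusters; beyond that, sorted adjacent pairing — which is also the
    exact optimum for a single matching variable.
    """
    if len(clusters) and isinstance(clusters[0], ClusterRecord):
        values = np.array([c.covariates[on] for c in clusters], dtype=float)
    else:
        values = np.asarray(clusters, dtype=float)
    n = len(values)
    if n % 2:
        raise ValueError(f"cannot pair an odd number of clusters ({n})")
    if n > 200:
        order = np.argsort(values, kind="stable")
        return [(int(order[i]), int(order[i + 1])) for i in range(0, n, 2)]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            G.add_edge(i, j, weight=abs(values[i] - values[j]))
    matching = nx.min_weight_matching(G, weight="weight")
    return sorted(tuple(sorted(e)) for e in matching)


def _assemble(d: dict, arms: np.ndarray, pair_ids: list, Y: np.ndarray) -> CRTData:
    n = len(d["N"])
    starts = np.concatenate([[0], np.cumsum(d["N"])])
    wnames = list(d["W"])
    clusters = []
    width = len(str(n))
    for j in range(n):
        sl = slice(starts[j], starts[j + 1])
        W = pd.DataFrame({name: d["W"][name][sl] for name in wnames})
        clusters.append(
            ClusterRecord(
                cluster_id=f"c{j + 1:0{width}d}",
                arm=int(arms[j]),
                covariates={"E1": float(d["E1"][j]), "E2": float(d["E2"][j])},
                W=W,
                Y=Y[sl].astype(float),
                pair_id=pair_ids[j],
            )
        )
    return CRTData(clusters)


def _generate(config: DGPConfig) -> CRTData:
    if config.J % 2:
        raise ValueError(f"pair-matching requires an even number of clusters, got J={config.J}")
    rng = np.random.default_rng(config.seed)
    d = _draw_clusters(config.study, config.J, rng)
    pairs = pair_match(d["E2"])
    arms = np.zeros(config.J, dtype=int)
    pair_ids: list = [None] * config.J
    for p, (i, j) in enumerate(pairs):
        first_treated = rng.random() < 0.5
        arms[i], arms[j] = (1, 0) if first_treated else (0, 1)
        pair_ids[i] = pair_ids[j] = f"p{p + 1:02d}"
    a_ind = arms[d["rep"]]
    Y = (d["U"] < _outcome_prob(d, a_ind, config.null_effect)).astype(float)
    return _assemble(d, arms, pair_ids, Y)


def generate_sim1(config: DGPConfig) -> CRTData:
    """One pair-matched trial from the Study-1 process."""
    if config.study != "sim1":
        raise ValueError("config.study must be 'sim1'")
    return _generate(config)


def generate_sim2(config: DGPConfig) -> CRTData:
    """One pair-matched trial from the informative-cluster-size process."""
    if config.study != "sim2":
        raise ValueError("config.study must be 'sim2'")
    return _generate(config)


def compute_truth(config: DGPConfig) -> TruthTable:
    """Finite-population true effects from coupled counterfactuals.

    Simulates ``population_size`` clusters, draws one uniform per
    individual, and evaluates the outcome under both treatment levels.
    Returns the ratio of equally weighted cluster-mean counterfactuals, the
    pooled individual-level ratio, and the ratio of geometric means of the
    cluster-level counterfactual outcomes (clusters with a zero proportion
    are excluded from the geometric mean with a warning).
    """
    rng = np.random.default_rng(config.seed)
    n = config.pop()
    d = _draw_clusters(config.study, n, rng)
    y1 = (d["U"] < _outcome_prob(d, 1.0, config.null_effect)).astype(float)
    y0 = (d["U"] < _outcome_prob(d, 0.0, config.null_effect)).astype(float)
    N = d["N"]
    rep = d["rep"]
    c1 = np.bincount(rep, weights=y1, minlength=n) / N
    c0 = np.bincount(rep, weights=y0, minlength=n) / N
    ok = (c1 > 0) & (c0 > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} clusters with zero counterfactual proportion "
            "excluded from the geometric mean",
            stacklevel=2,
        )
    geometric = float(np.exp(np.mean(np.log(c1[ok])) - np.mean(np.log(c0[ok]))))
    return TruthTable(
        cluster_ratio=float(c1.mean() / c0.mean()),
        individual_ratio=float(y1.mean() / y0.mean()),
        geometric_ratio=geometric,
        cluster_mean1=float(c1.mean()),
        cluster_mean0=float(c0.mean()),
        individual_mean1=float(y1.mean()),
        individual_mean0=float(y0.mean()),
    )
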