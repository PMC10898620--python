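"""Domain types and outcome aggregation for two-arm cluster randomized trials.

A trial consists of J clusters (communities, clinics, facilities); treatment
``A`` is randomized at the cluster level, covariates and binary outcomes are
measured on individuals. Cluster-level summaries are weighted sums
``Yc_j = sum_i alpha_ij * Y_ij``; the default weight ``alpha_ij = 1/N_j``
makes ``Yc_j`` the within-cluster outcome proportion. The choice of weights,
together with the target level (cluster vs individual), determines which
effect an analysis estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "ClusterRecord",
    "CRTData",
    "WeightScheme",
    "EstimandSpec",
    "aggregate_outcome",
    "pooled_individual_mean",
    "validate",
]


@dataclass(frozen=True)
class IndividualRecord:
    """One participant: named real-valued covariates and a binary outcome."""

    covariates: Mapping[str, float]
    outcome: float


@dataclass
class ClusterRecord:
    """One cluster: arm, cluster covariates, and its participants.

    Parameters
    ----------
    cluster_id
        Opaque key; ordering never carries meaning.
    arm
        Treatment indicator, 0 or 1, shared by every participant.
    covariates
        Named cluster-level covariates E (the cluster size is also carried
        separately as ``size``).
    W
        Individual-level covariate matrix, one row per participant.
    Y
        Individual-level outcome vector, same length as ``W``.
    pair_id
        Optional matched-pair key from a pair-matched design.
    """

    cluster_id: str
    arm: int
    covariates: dict[str, float]
    W: pd.DataFrame
    Y: np.ndarray
    pair_id: str | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)

    @property
    def size(self) -> int:
        return len(self.Y)

    @property
    def individuals(self) -> Iterator[IndividualRecord]:
        for i in range(self.size):
            yield IndividualRecord(self.W.iloc[i].to_dict(), float(self.Y[i]))


@dataclass
class CRTData:
    """A full trial: a list of clusters with derived totals."""

    clusters: list[ClusterRecord]

    @property
    def J(self) -> int:
        return len(self.clusters)

    @property
    def NT(self) -> int:
        return int(sum(c.size for c in self.clusters))

    @property
    def covariate_names(self) -> list[str]:
        w = list(self.clusters[0].W.columns) if self.clusters else []
        e = list(self.clusters[0].covariates) if self.clusters else []
        return w + e

    def arms(self) -> np.ndarray:
        return np.array([c.arm for c in self.clusters], dtype=int)

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=int)

    def individual_frame(self) -> pd.DataFrame:
        """Pooled one-row-per-participant frame.

        Columns: ``cluster_id``, ``pair_id``, ``A``, ``Y``, the individual
        covariates, the cluster covariates (repeated within cluster) and the
        cluster size ``N``.
        """
        parts = []
        for c in self.clusters:
            df = c.W.copy()
            df.insert(0, "cluster_id", c.cluster_id)
            df.insert(1, "pair_id", c.pair_id)
            df.insert(2, "A", c.arm)
            df.insert(3, "Y", c.Y)
            for name, val in c.covariates.items():
                df[name] = val
            df["N"] = c.size
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    def cluster_frame(self, weights: "WeightScheme | None" = None) -> pd.DataFrame:
        """One-row-per-cluster frame with aggregated outcome and covariates.

        The aggregated outcome ``Yc`` uses the weight scheme's ``alpha``;
        individual covariates are aggregated with the same weights and named
        with a ``c`` suffix (``W1`` becomes ``W1c``).
        """
        weights = weights or WeightScheme()
        rows = []
        for c in self.clusters:
            a = weights.alpha_for(c)
            row: dict[str, object] = {
                "cluster_id": c.cluster_id,
                "pair_id": c.pair_id,
                "A": c.arm,
                "Yc": float(a @ c.Y),
                "N": c.size,
            }
            for name in c.W.columns:
                row[name + "c"] = float(a @ c.W[name].to_numpy())
            row.update(c.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class WeightScheme:
    """Individual aggregation weights ``alpha_ij`` and the target level.

    ``alpha`` maps a cluster id to that cluster's weight vector; ``None``
    means the default ``alpha_ij = 1/N_j``, under which the cluster summary
    is the within-cluster mean. The target level induces the analysis
    weights ``J/NT * 1/alpha_ij`` used by cluster-level estimators when an
    individual-level effect is wanted: with the default alpha this is
    ``J*N_j/NT`` per cluster. Under a cluster-level target all analysis
    weights are 1.
    """

    target: Literal["cluster", "individual"] = "cluster"
    alpha: dict[str, np.ndarray] | None = None

    def alpha_for(self, cluster: ClusterRecord) -> np.ndarray:
        if self.alpha is None:
            return np.full(cluster.size, 1.0 / cluster.size)
        try:
            a = np.asarray(self.alpha[cluster.cluster_id], dtype=float)
        except KeyError:
            raise KeyError(f"no weights defined for cluster {cluster.cluster_id!r}")
        if len(a) != cluster.size:
            raise ValueError(
                f"cluster {cluster.cluster_id!r}: {len(a)} weights for "
                f"{cluster.size} individuals"
            )
        if np.any(a < 0):
            i = int(np.flatnonzero(a < 0)[0])
            raise ValueError(
                f"negative weight for individual {i} in cluster {cluster.cluster_id!r}"
            )
        return a

    def cluster_analysis_weights(self, data: CRTData) -> np.ndarray:
        """Per-cluster analysis weights, normalized to mean 1.

        For an individual-level target the weight for cluster j is
        ``J/NT * 1/alpha_ij``, which must be constant within the cluster
        (it is for the default ``alpha_ij = 1/N_j``, giving ``J*N_j/NT``).
        """
        if self.target == "cluster":
            return np.ones(data.J)
        w = np.empty(data.J)
        for k, c in enumerate(data.clusters):
            a = self.alpha_for(c)
            if np.any(a <= 0):
                raise ValueError(
                    f"cluster {c.cluster_id!r}: individual-level targeting requires "
                    "strictly positive alpha weights"
                )
            inv = 1.0 / a
            if not np.allclose(inv, inv[0], rtol=1e-10):
                raise ValueError(
                    f"cluster {c.cluster_id!r}: alpha varies within the cluster; "
                    "cluster-level analysis weights are undefined"
                )
            w[k] = inv[0]
        w *= data.J / data.NT
        return w / w.mean()

    def individual_analysis_weights(self, data: CRTData) -> np.ndarray:
        """Per-individual weights for pooled (hierarchical) analyses.

        Cluster-level target: ``alpha_ij`` (each cluster contributes total
        weight 1); individual-level target: constant ``J/NT`` (each
        participant contributes equally). Returned normalized to mean 1,
        concatenated in cluster order.
        """
        if self.target == "individual":
            return np.ones(data.NT)
        w = np.concatenate([self.alpha_for(c) for c in data.clusters])
        return w / w.mean()


@dataclass(frozen=True)
class EstimandSpec:
    """What to estimate: target level, contrast scale, matched-pair handling.

    ``level='cluster'`` contrasts equally weighted means of cluster-level
    outcomes; ``level='individual'`` contrasts pooled participant-level
    means. ``matching='keep'`` treats the randomization pair as the
    independent unit during inference; ``'break'`` treats each cluster as
    independent.
    """

    level: Literal["cluster", "individual"] = "cluster"
    scale: Literal["ratio", "difference"] = "ratio"
    matching: Literal["break", "keep"] = "break"

    def weight_scheme(self) -> WeightScheme:
        return WeightScheme(target=self.level)


def aggregate_outcome(cluster: ClusterRecord, weights: WeightScheme | None = None) -> float:
    """Weighted cluster-level outcome ``sum_i alpha_ij * Y_ij``.

    With the default weights this is the cluster's empirical outcome
    proportion, in [0, 1] for a binary outcome.
    """
    weights = weights or WeightScheme()
    a = weights.alpha_for(cluster)
    return float(a @ cluster.Y)


def pooled_individual_mean(data: CRTData, arm: int) -> float:
    """Pooled participant-level outcome mean within one arm."""
    num = 0.0
    den = 0
    for c in data.clusters:
        if c.arm == arm:
            num += float(c.Y.sum())
            den += c.size
    if den == 0:
        raise ValueError(f"no clusters in arm {arm}")
    return num / den


def validate(data: CRTData) -> list[str]:
    """Check trial invariants; returns human-readable violations (never raises).

    Checks: at least 4 clusters, both arms non-empty, binary arms and
    outcomes, positive cluster sizes, W/Y length agreement, consistent
    covariate names across clusters, and pair ids shared by exactly two
    clusters with opposite arms.
    """
    out: list[str] = []
    if data.J < 4:
        out.append(f"only {data.J} clusters; at least 4 required")
    arms = {c.arm for c in data.clusters}
    if not arms <= {0, 1}:
        out.append(f"non-binary arm values {sorted(arms - {0, 1})}")
    for a in (0, 1):
        if a not in arms:
            out.append(f"arm {a} is empty")
    wnames = None
    enames = None
    for c in data.clusters:
        if c.size < 1:
            out.append(f"cluster {c.cluster_id!r}: empty cluster")
        if len(c.W) != len(c.Y):
            out.append(
                f"cluster {c.cluster_id!r}: {len(c.W)} covariate rows for "
                f"{len(c.Y)} outcomes"
            )
        bad = ~np.isin(c.Y, (0.0, 1.0))
        if bad.any():
            out.append(
                f"cluster {c.cluster_id!r}: non-binary outcomes at positions "
                f"{np.flatnonzero(bad)[:5].tolist()}"
            )
        if wnames is None:
            wnames, enames = tuple(c.W.columns), tuple(sorted(c.covariates))
        else:
            if tuple(c.W.columns) != wnames:
                out.append(f"cluster {c.cluster_id!r}: covariate names differ from first cluster")
            if tuple(sorted(c.covariates)) != enames:
                out.append(
                    f"cluster {c.cluster_id!r}: cluster covariate names differ from first cluster"
                )
    pairs: dict[str, list[ClusterRecord]] = {}
    for c in data.clusters:
        if c.pair_id is not None:
            pairs.setdefault(c.pair_id, []).append(c)
    for pid, members in pairs.items():
        if len(members) != 2:
            out.append(f"pair {pid!r} has {len(members)} clusters (expected 2)")
        elif members[0].arm + members[1].arm != 1:
            out.append(f"pair {pid!r} does not have one cluster per arm")
    return out
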