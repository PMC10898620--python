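"""Readers and writers for the package's CSV dialects and result JSON.

Individual-level CSV: one row per participant with columns ``cluster_id``,
optional ``pair_id``, ``A``, ``Y``, individual covariates prefixed ``W.``
and cluster covariates prefixed ``E.`` (constant within cluster).
Cluster-level CSV: one row per cluster with ``cluster_id``, optional
``pair_id``, ``A``, ``Yc``, ``N`` and ``E.*`` columns. Both use a header
row, UTF-8, and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClusterRecord, CRTData

__all__ = [
    "read_individual_csv",
    "write_individual_csv",
    "read_cluster_csv",
    "write_cluster_csv",
    "write_result_json",
]


def _check_binary_column(df: pd.DataFrame, col: str, path) -> None:
    bad = ~df[col].isin([0, 1])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # header is line 1
        raise ValueError(f"{path}: non-binary {col} values at lines {rows}")


def read_individual_csv(path) -> CRTData:
    """Read one-row-per-participant data into a :class:`CRTData`."""
    df = pd.read_csv(path)
    required = {"cluster_id", "A", "Y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    wcols = [c for c in df.columns if c.startswith("W.")]
    ecols = [c for c in df.columns if c.startswith("E.")]
    known = required | {"pair_id"} | set(wcols) | set(ecols)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(
            f"{path}: unknown columns {unknown}; covariates must be prefixed 'W.' or 'E.'"
        )
    _check_binary_column(df, "A", path)
    _check_binary_column(df, "Y", path)
    clusters = []
    for cid, sub in df.groupby("cluster_id", sort=False):
        for col in ecols + ["A"]:
            if sub[col].nunique() > 1:
                raise ValueError(
                    f"{path}: column {col} is not constant within cluster {cid!r}"
                )
        pair = None
        if "pair_id" in sub.columns and not sub["pair_id"].isna().all():
            pair = str(sub["pair_id"].iloc[0])
        W = sub[wcols].rename(columns=lambda c: c[2:]).reset_index(drop=True)
        clusters.append(
            ClusterRecord(
                cluster_id=str(cid),
                arm=int(sub["A"].iloc[0]),
                covariates={c[2:]: float(sub[c].iloc[0]) for c in ecols},
                W=W.astype(float),
                Y=sub["Y"].to_numpy(dtype=float),
                pair_id=pair,
            )
        )
    return CRTData(clusters)


def write_individual_csv(data: CRTData, path) -> None:
    frame = data.individual_frame()
    wnames = list(data.clusters[0].W.columns)
    enames = list(data.clusters[0].covariates)
    out = frame[["cluster_id", "pair_id", "A", "Y"] + wnames + enames].rename(
        columns={**{w: f"W.{w}" for w in wnames}, **{e: f"E.{e}" for e in enames}}
    )
    out.to_csv(path, index=False)


def read_cluster_csv(path) -> CRTData:
    """Read cluster-level-only data (no individual rows available).

    Each cluster's aggregate outcome ``Yc`` must lie in [0, 1] but need
    not correspond to an integral event count. The returned trial carries
    synthetic constant individual outcomes reproducing each cluster's
    aggregate (binary where ``Yc*N`` is integral), so only cluster-level
    estimators — possibly with individual-level target weights — are
    meaningful on it.
    """
    df = pd.read_csv(path)
    required = {"cluster_id", "A", "Yc", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    _check_binary_column(df, "A", path)
    if ((df["Yc"] < 0) | (df["Yc"] > 1)).any():
        raise ValueError(f"{path}: Yc outside [0, 1]")
    ecols = [c for c in df.columns if c.startswith("E.")]
    clusters = []
    for _, row in df.iterrows():
        n = int(row["N"])
        yc = float(row["Yc"])
        events = yc * n
        if abs(events - round(events)) < 1e-9:
            k = int(round(events))
            y = np.concatenate([np.ones(k), np.zeros(n - k)])
        else:
            y = np.full(n, yc)
        pair = None
        if "pair_id" in df.columns and not pd.isna(row.get("pair_id")):
            pair = str(row["pair_id"])
        clusters.append(
            ClusterRecord(
                cluster_id=str(row["cluster_id"]),
                arm=int(row["A"]),
                covariates={c[2:]: float(row[c]) for c in ecols},
                W=pd.DataFrame(index=range(n)),
                Y=y,
                pair_id=pair,
            )
        )
    return CRTData(clusters)


def write_cluster_csv(data: CRTData, path) -> None:
    frame = data.cluster_frame()
    enames = list(data.clusters[0].covariates)
    out = frame[["cluster_id", "pair_id", "A", "Yc", "N"] + enames].rename(
        columns={e: f"E.{e}" for e in enames}
    )
    out.to_csv(path, index=False)


def write_result_json(result: dict, path, provenance: dict | None = None) -> None:
    """Write a result dict with reproducibility metadata attached.

    The provenance block records the package version, the full run
    configuration, and a short hash of that configuration — enough to
    reproduce the run from the same inputs.
    """
    import hashlib

    from . import __version__

    payload = dict(result)
    payload["provenance"] = {"package": "crt-effects", "version": __version__}
    if provenance:
        payload["provenance"].update(provenance)
    digest = hashlib.sha256(
        json.dumps(payload["provenance"], sort_keys=True, default=_json_default).encode()
    ).hexdigest()[:12]
    payload["provenance"]["config_hash"] = digest
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
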