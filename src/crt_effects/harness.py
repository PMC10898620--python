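"""Replication engine: run estimators over many simulated trials and
summarize operating characteristics (bias, variability, coverage, power).

Metric conventions follow the usual simulation-table layout: the mean
point estimate ``pt`` and bias are on the ratio scale; the variability of
the estimator (``sigma``) and the average estimated SE (``sigma_hat``)
are on the log scale; coverage is the share of 95% CIs containing the
truth; ``reject`` is the share of replicates with p < 0.05 (power under
an effect, Type-I error under the null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptive_prespec import CandidateLibrary, adaptive_tmle
from .classic import aug_gee, care, gee, geometric_ttest, unadjusted_contrast
from .core import CRTData, EstimandSpec, WeightScheme
from .dgp import DGPConfig, TruthTable, generate_sim1, generate_sim2
from .tmle import RegressionSpec, cluster_tmle, hierarchical_tmle, hybrid_tmle

__all__ = ["SimulationSummary", "run_study", "selection_frequencies", "make_estimator"]


@dataclass
class SimulationSummary:
    """Per-estimator operating characteristics over replicates."""

    table: pd.DataFrame
    replicates: pd.DataFrame
    traces: dict[str, list[dict]]
    truth: TruthTable | None
    R: int

    def __repr__(self) -> str:
        return f"SimulationSummary(R={self.R})\n{self.table.round(3)}"


def make_estimator(name: str, **opts) -> Callable[[CRTData], object]:
    """Build a named estimator closure for :func:`run_study`.

    Names: ``unadj``, ``ttest`` (geometric log t-test), ``care``, ``gee``,
    ``auggee``, ``ctmle``, ``htmle``, ``hybrid``; append ``-ap`` to a TMLE
    name for Adaptive Prespecification (requires ``candidates=...``,
    a list of covariate names). Options: ``level`` ('cluster' or
    'individual'), ``adjust`` / ``ps_adjust`` (fixed adjustment sets),
    ``matching``, ``candidates``, ``cv``.
    """
    level = opts.get("level", "cluster")
    matching = opts.get("matching", "break")
    spec = EstimandSpec(level=level, scale="ratio", matching=matching)
    weights = WeightScheme(target=level)
    adjust = tuple(opts.get("adjust", ()))
    ps_adjust = tuple(opts.get("ps_adjust", ()))

    base = name[:-3] if name.endswith("-ap") else name
    adaptive = name.endswith("-ap")
    reg_level = "individual" if base in ("htmle", "hybrid") else "cluster"

    if adaptive:
        candidates = opts["candidates"]
        cv = opts.get("cv", "leave_one_pair_out" if matching == "keep" else "leave_one_cluster_out")
        library = CandidateLibrary.singletons(candidates, reg_level, cv=cv)
        estimator_key = {"ctmle": "cluster_tmle", "htmle": "hierarchical_tmle", "hybrid": "hybrid_tmle"}[base]

        def fn(data: CRTData):
            return adaptive_tmle(data, library, estimator_key, spec, weights)

        return fn

    if base == "unadj":
        return lambda data: unadjusted_contrast(data, weights, spec)
    if base == "ttest":
        return lambda data: geometric_ttest(data)
    if base == "care":
        return lambda data: care(data, adjust)
    if base == "gee":
        return lambda data: gee(data, adjust, working=opts.get("working", "independence"))
    if base == "auggee":
        return lambda data: aug_gee(data, adjust)
    if base in ("ctmle", "htmle", "hybrid"):
        fns = {"ctmle": cluster_tmle, "htmle": hierarchical_tmle, "hybrid": hybrid_tmle}
        outcome = RegressionSpec("outcome", reg_level, adjust)
        ps_level = "cluster" if base in ("ctmle", "hybrid") else "individual"
        ps = RegressionSpec("propensity", ps_level, ps_adjust)
        return lambda data: fns[base](data, weights, spec, outcome, ps)
    raise ValueError(f"unknown estimator {name!r}")


def run_study(
    dgp: DGPConfig,
    estimators: Mapping[str, Callable[[CRTData], object]],
    R: int,
    truth: TruthTable | None = None,
    targets: Mapping[str, float] | None = None,
) -> SimulationSummary:
    """Run ``R`` replicates of a DGP and aggregate operating characteristics.

    Replicate ``r`` uses seed ``dgp.seed + r``, so results are
    reproducible bit-for-bit from the base seed. ``targets`` maps
    estimator names to their true effect values; if omitted, each
    estimator is scored against ``truth`` (cluster ratio by default, or
    1.0 when no truth is given, as under a null process). Estimator
    failures in a replicate are recorded and excluded from the aggregates.
    """
    if R < 2:
        raise ValueError("need at least 2 replicates")
    gen = {"sim1": generate_sim1, "sim2": generate_sim2}[dgp.study]
    records = []
    traces: dict[str, list[dict]] = {name: [] for name in estimators}
    for r in range(R):
        cfg = DGPConfig(
            study=dgp.study, J=dgp.J, null_effect=dgp.null_effect, seed=dgp.seed + 1 + r
        )
        data = gen(cfg)
        for name, fn in estimators.items():
            row = {"replicate": r, "estimator": name}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = fn(data)
                lo, hi = res.ci if isinstance(res.ci, tuple) else (res.ci_lo, res.ci_hi)
                row.update(estimate=res.estimate, p=res.p, ci_lo=lo, ci_hi=hi, se=res.se, failed=False)
                sel = getattr(res, "selection", None)
                if sel:
                    traces[name].append(sel)
            except Exception as exc:  # noqa: BLE001 -- a failed replicate is data
                row.update(estimate=np.nan, p=np.nan, ci_lo=np.nan, ci_hi=np.nan, se=np.nan, failed=True)
                row["error"] = str(exc)
            records.append(row)
    reps = pd.DataFrame(records)

    rows = []
    for name in estimators:
        sub = reps[(reps.estimator == name) & (~reps.failed.astype(bool))]
        n_fail = int((reps.estimator == name).sum() - len(sub))
        if targets and name in targets:
            tv = targets[name]
        elif truth is not None:
            tv = truth.cluster_ratio
        else:
            tv = 1.0
        est = sub.estimate.to_numpy(dtype=float)
        rows.append(
            {
                "estimator": name,
                "truth": tv,
                "pt": est.mean() if len(est) else np.nan,
                "bias": est.mean() - tv if len(est) else np.nan,
                "sigma": np.log(est).std(ddof=1) if len(est) > 1 else np.nan,
                "sigma_hat": sub.se.mean() if len(sub) else np.nan,
                "coverage": ((sub.ci_lo <= tv) & (tv <= sub.ci_hi)).mean() if len(sub) else np.nan,
                "reject": (sub.p < 0.05).mean() if len(sub) else np.nan,
                "n_replicates": len(sub),
                "n_failed": n_fail,
            }
        )
    table = pd.DataFrame(rows).set_index("estimator")
    return SimulationSummary(table=table, replicates=reps, traces=traces, truth=truth, R=R)


def selection_frequencies(traces: Sequence[Mapping]) -> pd.DataFrame:
    """Share of replicates in which each candidate was selected, per stage.

    Accepts the ``selection`` dicts collected by :func:`run_study` (or
    :class:`~crt_effects.adaptive_prespec.SelectionTrace` objects).
    Shares sum to 1 within each stage.
    """
    rows = []
    for tr in traces:
        d = tr.to_dict() if hasattr(tr, "to_dict") else tr
        out = d.get("outcome_adjustment")
        ps = d.get("ps_adjustment")
        rows.append(
            {
                "outcome": "+".join(out) if out else "unadjusted",
                "propensity": "+".join(ps) if ps else "unadjusted",
            }
        )
    if not rows:
        return pd.DataFrame(columns=["stage", "candidate", "share"])
    df = pd.DataFrame(rows)
    parts = []
    for stage in ("outcome", "propensity"):
        share = df[stage].value_counts(normalize=True)
        parts.append(
            pd.DataFrame({"stage": stage, "candidate": share.index, "share": share.to_numpy()})
        )
    return pd.concat(parts, ignore_index=True)
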