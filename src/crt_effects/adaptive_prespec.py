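"""Adaptive Prespecification: data-adaptive selection among prespecified
candidate adjustment regressions.

The analyst prespecifies a small library of candidate generalized linear
models for the outcome regression and for the propensity score (each list
must contain the unadjusted candidate) together with a cross-validation
scheme — leave-one-cluster-out for small trials, or leave-one-pair-out when
the randomization pairs are kept as the independent unit. Selection
proceeds in two stages with the squared influence function of the contrast
as loss:

1. each outcome candidate is evaluated with the *known* propensity score
   (0.5 by design) and the candidate minimizing the cross-validated mean
   squared held-out IF is chosen;
2. holding that winner fixed, each propensity candidate is evaluated the
   same way and the minimizer chosen.

Because the unadjusted candidate is always available, selection can never
force harmful adjustment; ties are broken toward the smaller adjustment set
and then lexicographically. Selection is deterministic given the data: the
folds are defined by cluster (or pair) identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._logistic import SeparationError, clip_probability, expit, fit_logistic, logit
from .core import CRTData, EstimandSpec, WeightScheme
from .inference import ContrastResult
from .tmle import (
    PS_BOUNDS,
    EffectEstimate,
    RegressionSpec,
    cluster_tmle,
    hierarchical_tmle,
    hybrid_tmle,
)

__all__ = ["CandidateLibrary", "SelectionTrace", "select", "adaptive_tmle"]


@dataclass
class CandidateLibrary:
    """Prespecified candidate regressions and the cross-validation scheme."""

    outcome: list[RegressionSpec]
    propensity: list[RegressionSpec]
    cv: Literal["leave_one_cluster_out", "leave_one_pair_out"] = "leave_one_cluster_out"

    def __post_init__(self) -> None:
        if not any(not c.adjustment for c in self.outcome):
            raise ValueError("outcome candidates must include the unadjusted model")
        if not any(not c.adjustment for c in self.propensity):
            raise ValueError("propensity candidates must include the known-0.5 model")

    @classmethod
    def singletons(
        cls,
        covariates: Sequence[str],
        level: Literal["cluster", "individual"],
        cv: Literal["leave_one_cluster_out", "leave_one_pair_out"] = "leave_one_cluster_out",
    ) -> "CandidateLibrary":
        """Unadjusted plus one single-covariate candidate per name, for both
        the outcome regression and the propensity score."""
        outcome = [RegressionSpec("outcome", level)] + [
            RegressionSpec("outcome", level, (c,)) for c in covariates
        ]
        ps = [RegressionSpec("propensity", level)] + [
            RegressionSpec("propensity", level, (c,)) for c in covariates
        ]
        return cls(outcome=outcome, propensity=ps, cv=cv)


@dataclass
class SelectionTrace:
    """Cross-validated losses and the chosen candidate per stage."""

    outcome_losses: dict[str, float]
    propensity_losses: dict[str, float]
    outcome_spec: RegressionSpec
    ps_spec: RegressionSpec
    cv: str

    def to_dict(self) -> dict:
        return {
            "cv": self.cv,
            "outcome_losses": self.outcome_losses,
            "propensity_losses": self.propensity_losses,
            "outcome_adjustment": list(self.outcome_spec.adjustment),
            "ps_adjustment": list(self.ps_spec.adjustment),
        }


class _Level:
    """Flat numpy view of the data at the fitting level, with everything the
    fold loop needs: response, arm, covariate columns, analysis weights, and
    the mapping from rows to independent evaluation units (clusters)."""

    def __init__(self, data: CRTData, estimator: str, weights: WeightScheme):
        self.J = data.J
        if estimator == "cluster_tmle":
            frame = data.cluster_frame(weights)
            self.y = frame["Yc"].to_numpy(dtype=float)
            self.arm = frame["A"].to_numpy(dtype=float)
            self.w = weights.cluster_analysis_weights(data)
            self.row_cluster = np.arange(data.J)
            self.cluster_w = None  # rows are clusters
            self.cols = {
                c: frame[c].to_numpy(dtype=float)
                for c in frame.columns
                if c not in ("cluster_id", "pair_id")
            }
            self.if_scale = 1.0
        elif estimator == "hierarchical_tmle":
            frame = data.individual_frame()
            self.y = frame["Y"].to_numpy(dtype=float)
            self.arm = frame["A"].to_numpy(dtype=float)
            self.w = weights.individual_analysis_weights(data)
            codes = {c.cluster_id: k for k, c in enumerate(data.clusters)}
            self.row_cluster = frame["cluster_id"].map(codes).to_numpy(dtype=int)
            self.cols = {
                c: frame[c].to_numpy(dtype=float)
                for c in frame.columns
                if c not in ("cluster_id", "pair_id")
            }
            self.if_scale = data.J / data.NT
        else:
            raise ValueError(f"unsupported estimator for selection: {estimator!r}")
        self.pair_of_cluster = [c.pair_id for c in data.clusters]

    def design(self, adjustment: Sequence[str], arm: np.ndarray, rows: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(rows)), arm]
        for name in adjustment:
            if name not in self.cols:
                raise KeyError(f"candidate covariate {name!r} not found in data")
            cols.append(self.cols[name][rows])
        return np.column_stack(cols)

    def ps_design(self, adjustment: Sequence[str], rows: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [np.ones(len(rows))] + [self.cols[name][rows] for name in adjustment]
        )


def _folds(data: CRTData, cv: str) -> list[np.ndarray]:
    """Held-out cluster index sets, one per fold."""
    if cv == "leave_one_cluster_out":
        return [np.array([k]) for k in range(data.J)]
    if cv == "leave_one_pair_out":
        groups: dict[str, list[int]] = {}
        for k, c in enumerate(data.clusters):
            if c.pair_id is None:
                raise ValueError("leave-one-pair-out requires pair ids on every cluster")
            groups.setdefault(c.pair_id, []).append(k)
        return [np.array(v) for _, v in sorted(groups.items(), key=lambda kv: str(kv[0]))]
    raise ValueError(f"unknown cv scheme {cv!r}")


def _heldout_sq_if(
    lv: _Level,
    train_rows: np.ndarray,
    val_rows: np.ndarray,
    val_clusters: np.ndarray,
    beta: np.ndarray,
    outcome_adj: tuple[str, ...],
    pi_fn,
) -> float:
    """Squared held-out IF of the log-ratio for one fold.

    Fits the fluctuation on the training rows, then evaluates the
    cluster-aggregated IF contribution of the held-out unit(s).
    """
    # training predictions and fluctuation
    arm_tr = lv.arm[train_rows]
    mu1_tr = expit(lv.design(outcome_adj, np.ones(len(train_rows)), train_rows) @ beta)
    mu0_tr = expit(lv.design(outcome_adj, np.zeros(len(train_rows)), train_rows) @ beta)
    pi_tr = pi_fn(train_rows)
    h1 = arm_tr / pi_tr
    h0 = (1.0 - arm_tr) / (1.0 - pi_tr)
    mu_obs = np.where(arm_tr == 1, mu1_tr, mu0_tr)
    offset = logit(clip_probability(mu_obs, 1e-6, 1.0 - 1e-6))
    w_tr = lv.w[train_rows]
    eps = fit_logistic(np.column_stack([h1, h0]), lv.y[train_rows], weights=w_tr, offset=offset)

    def targeted(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pi = pi_fn(rows)
        m1 = expit(
            logit(clip_probability(expit(lv.design(outcome_adj, np.ones(len(rows)), rows) @ beta), 1e-6, 1 - 1e-6))
            + eps[0] / pi
        )
        m0 = expit(
            logit(clip_probability(expit(lv.design(outcome_adj, np.zeros(len(rows)), rows) @ beta), 1e-6, 1 - 1e-6))
            + eps[1] / (1.0 - pi)
        )
        return m1, m0, pi

    m1_tr, m0_tr, _ = targeted(train_rows)
    psi1 = float(np.sum(w_tr * m1_tr) / np.sum(w_tr))
    psi0 = float(np.sum(w_tr * m0_tr) / np.sum(w_tr))
    if psi1 <= 0 or psi0 <= 0:
        raise SeparationError("non-positive targeted arm mean in training fold")
    # held-out IF contributions, aggregated to cluster level
    m1_v, m0_v, pi_v = targeted(val_rows)
    arm_v = lv.arm[val_rows]
    y_v = lv.y[val_rows]
    w_v = lv.w[val_rows]
    d1 = w_v * (arm_v / pi_v * (y_v - m1_v) + m1_v - psi1)
    d0 = w_v * ((1.0 - arm_v) / (1.0 - pi_v) * (y_v - m0_v) + m0_v - psi0)
    # the held-out unit (one cluster, or a pair) contributes the square of
    # its summed cluster-level log-ratio IF
    d_log = lv.if_scale * (d1 / psi1 - d0 / psi0)
    return float(d_log.sum()) ** 2


def _tie_key(spec: RegressionSpec) -> tuple[int, str]:
    return (len(spec.adjustment), spec.label)


def select(
    data: CRTData,
    library: CandidateLibrary,
    estimator: str = "cluster_tmle",
    spec: EstimandSpec | None = None,
    weights: WeightScheme | None = None,
) -> SelectionTrace:
    """Two-stage cross-validated selection of the adjustment regressions.

    Returns a :class:`SelectionTrace` with the per-candidate CV losses
    (mean squared held-out IF of the log-ratio contrast) and the winners.
    """
    spec = spec or EstimandSpec()
    weights = weights or WeightScheme(target=spec.level)
    estimator = _canonical(estimator)
    lv = _Level(data, estimator, weights)
    folds = _folds(data, library.cv)
    all_rows = np.arange(len(lv.y))

    fold_rows = []
    for val_clusters in folds:
        val_mask = np.isin(lv.row_cluster, val_clusters)
        fold_rows.append((all_rows[~val_mask], all_rows[val_mask], val_clusters))

    known_pi = lambda rows: np.full(len(rows), 0.5)

    # stage 1: outcome candidates under the known propensity
    outcome_losses: dict[str, float] = {}
    beta_cache: dict[tuple[str, int], np.ndarray] = {}
    for cand in library.outcome:
        losses = []
        try:
            for f, (train, val, val_clusters) in enumerate(fold_rows):
                X = lv.design(cand.adjustment, lv.arm[train], train)
                beta = fit_logistic(X, lv.y[train], weights=lv.w[train])
                beta_cache[(cand.label, f)] = beta
                losses.append(
                    _heldout_sq_if(lv, train, val, val_clusters, beta, cand.adjustment, known_pi)
                )
        except (SeparationError, np.linalg.LinAlgError):
            warnings.warn(
                f"outcome candidate {cand.label!r} failed on a training fold; excluded",
                stacklevel=2,
            )
            continue
        outcome_losses[cand.label] = float(np.mean(losses))
    if not outcome_losses:
        raise RuntimeError("every outcome candidate failed cross-validation")
    by_label = {c.label: c for c in library.outcome}
    best_outcome = min(
        (by_label[lab] for lab in outcome_losses),
        key=lambda c: (outcome_losses[c.label], _tie_key(c)),
    )

    # stage 2: propensity candidates, holding the stage-1 winner fixed
    ps_losses: dict[str, float] = {}
    for cand in library.propensity:
        losses = []
        try:
            for f, (train, val, val_clusters) in enumerate(fold_rows):
                beta = beta_cache[(best_outcome.label, f)]
                if cand.adjustment:
                    Xp = lv.ps_design(cand.adjustment, train)
                    gamma = fit_logistic(Xp, lv.arm[train], weights=lv.w[train])

                    def pi_fn(rows, _g=gamma, _adj=cand.adjustment):
                        return np.clip(expit(lv.ps_design(_adj, rows) @ _g), *PS_BOUNDS)

                else:
                    pi_fn = known_pi
                losses.append(
                    _heldout_sq_if(
                        lv, train, val, val_clusters, beta, best_outcome.adjustment, pi_fn
                    )
                )
        except (SeparationError, np.linalg.LinAlgError):
            warnings.warn(
                f"propensity candidate {cand.label!r} failed on a training fold; excluded",
                stacklevel=2,
            )
            continue
        ps_losses[cand.label] = float(np.mean(losses))
    if not ps_losses:
        raise RuntimeError("every propensity candidate failed cross-validation")
    ps_by_label = {c.label: c for c in library.propensity}
    best_ps = min(
        (ps_by_label[lab] for lab in ps_losses),
        key=lambda c: (ps_losses[c.label], _tie_key(c)),
    )
    return SelectionTrace(
        outcome_losses=outcome_losses,
        propensity_losses=ps_losses,
        outcome_spec=best_outcome,
        ps_spec=best_ps,
        cv=library.cv,
    )


_ALIASES = {
    "ctmle": "cluster_tmle",
    "cluster_tmle": "cluster_tmle",
    "htmle": "hierarchical_tmle",
    "hierarchical_tmle": "hierarchical_tmle",
    "hybrid": "hybrid_tmle",
    "hybrid_tmle": "hybrid_tmle",
}


def _canonical(name: str) -> str:
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(f"unknown estimator {name!r}") from None


def adaptive_tmle(
    data: CRTData,
    library: CandidateLibrary,
    estimator: str = "cluster_tmle",
    spec: EstimandSpec | None = None,
    weights: WeightScheme | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Run Adaptive Prespecification, then the chosen TMLE on the full data.

    The returned estimate carries the full :class:`SelectionTrace` in its
    ``selection`` field. For the hybrid TMLE, selection is carried out with
    the hierarchical machinery (individual-level candidates) and the chosen
    outcome regression is combined with a cluster-level propensity.
    """
    spec = spec or EstimandSpec()
    weights = weights or WeightScheme(target=spec.level)
    estimator = _canonical(estimator)
    sel_estimator = "hierarchical_tmle" if estimator == "hybrid_tmle" else estimator
    trace = select(data, library, sel_estimator, spec, weights)
    fns = {
        "cluster_tmle": cluster_tmle,
        "hierarchical_tmle": hierarchical_tmle,
        "hybrid_tmle": hybrid_tmle,
    }
    ps_spec = trace.ps_spec
    if estimator == "hybrid_tmle":
        ps_spec = RegressionSpec("propensity", "cluster", trace.ps_spec.adjustment)
    est = fns[estimator](
        data,
        weights=weights,
        spec=spec,
        outcome_reg=trace.outcome_spec,
        ps_reg=ps_spec,
        alpha=alpha,
    )
    est.selection = trace.to_dict()
    if spec.scale == "ratio":
        _apply_cv_variance(est, trace, data, spec, alpha)
    return est


def _apply_cv_variance(
    est: EffectEstimate,
    trace: SelectionTrace,
    data: CRTData,
    spec: EstimandSpec,
    alpha: float,
) -> None:
    """Replace the contrast SE with the cross-validated variance estimate.

    The full-sample IF variance of a *selected* fit is optimistic: the
    same data chose the candidate and judge its spread. The held-out
    squared-IF loss of the winning candidate pair is an honest estimate of
    the per-unit IF variance of the log-ratio, so the selected TMLE's
    inference uses it instead: se^2 = loss / n for leave-one-cluster-out
    folds (the held-out unit is one cluster), and loss / (4 * n_pairs) for
    leave-one-pair-out (the fold value is the squared pair *sum* while the
    pair-level IF convention is the pair average).
    """
    import numpy as np
    from scipy import stats as _stats

    loss = trace.propensity_losses[trace.ps_spec.label]
    if trace.cv == "leave_one_pair_out":
        n = data.J // 2
        var = loss / (4.0 * n)
    else:
        n = data.J
        var = loss / n
    se = float(np.sqrt(var))
    c = est.contrast
    log_est = np.log(c.estimate)
    t_stat = log_est / se if se > 0 else np.nan
    p = float(2 * _stats.t.sf(abs(t_stat), c.df)) if se > 0 else np.nan
    crit = _stats.t.ppf(1 - alpha / 2, c.df)
    est.contrast = ContrastResult(
        estimate=c.estimate,
        se=se,
        ci_lo=float(np.exp(log_est - crit * se)),
        ci_hi=float(np.exp(log_est + crit * se)),
        t=float(t_stat),
        df=c.df,
        p=p,
        scale="ratio",
    )
    est.selection["cv_se_log"] = se
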