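"""Targeted maximum likelihood estimators (TMLEs) for cluster randomized trials.

Three variants are provided, all double robust plug-in estimators with
influence-function inference:

* :func:`cluster_tmle` — aggregates data to the cluster level, fits a
  cluster-level outcome regression and propensity score, and targets via a
  logistic fluctuation with two "clever covariates" (inverse-propensity
  indicators).
* :func:`hierarchical_tmle` — pools participant-level data, fits
  individual-level regressions and fluctuates at the individual level, then
  aggregates the influence function to the cluster (the independent unit)
  for variance estimation.
* :func:`hybrid_tmle` — fits the individual-level outcome regression,
  aggregates its predictions to cluster-level initial estimates, and then
  proceeds exactly like the cluster-level TMLE.

Each can target the cluster-level effect (clusters weighted equally) or the
individual-level effect (participants weighted equally) by carrying the
analysis weights ``J/NT * 1/alpha_ij`` through every step: the initial
fits, the fluctuation, the final average, and the influence function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._logistic import SeparationError, clip_probability, expit, fit_logistic, logit
from .core import CRTData, EstimandSpec, WeightScheme
from .inference import ContrastResult, delta_difference, delta_ratio, paired_if

__all__ = [
    "RegressionSpec",
    "FluctuationFit",
    "EffectEstimate",
    "cluster_tmle",
    "hierarchical_tmle",
    "hybrid_tmle",
]

PS_BOUNDS = (0.05, 0.95)


@dataclass(frozen=True)
class RegressionSpec:
    """A candidate working regression: role, data level, adjustment set.

    An empty adjustment set is the unadjusted candidate: for the outcome
    role a logistic model in treatment only; for the propensity role the
    known design value 0.5 (no estimation). Cluster-level specs may adjust
    for cluster covariates (``E1``, ``N``, ...) or aggregated individual
    covariates (``W1c``, ...); individual-level specs for individual
    (``W1``) or cluster (``E1``) covariates on the pooled rows.
    """

    role: Literal["outcome", "propensity"]
    level: Literal["cluster", "individual"]
    adjustment: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "adjustment", tuple(self.adjustment))

    @property
    def label(self) -> str:
        return "unadjusted" if not self.adjustment else "+".join(self.adjustment)


@dataclass(frozen=True)
class FluctuationFit:
    """Coefficients of the two clever covariates and the residual scores.

    ``score1``/``score0`` are the weighted fluctuation score equations
    ``sum_u w_u H_u(a) (Y_u - mu*_u)``; both are ~0 at the MLE.
    """

    eps1: float
    eps0: float
    converged: bool
    score1: float = 0.0
    score0: float = 0.0


@dataclass
class EffectEstimate:
    """Arm-specific targeted means, their contrast, and IF-based inference."""

    estimator: str
    psi1: float
    psi0: float
    contrast: ContrastResult
    if1: np.ndarray
    if0: np.ndarray
    fluctuation: FluctuationFit
    estimand: EstimandSpec
    outcome_spec: RegressionSpec | None = None
    ps_spec: RegressionSpec | None = None
    selection: dict = field(default_factory=dict)

    @property
    def estimate(self) -> float:
        return self.contrast.estimate

    @property
    def p(self) -> float:
        return self.contrast.p

    @property
    def se(self) -> float:
        """SE of the contrast (log scale for ratio contrasts)."""
        return self.contrast.se

    @property
    def ci(self) -> tuple[float, float]:
        return (self.contrast.ci_lo, self.contrast.ci_hi)

    def to_dict(self) -> dict:
        c = self.contrast
        return {
            "estimator": self.estimator,
            "psi1": self.psi1,
            "psi0": self.psi0,
            "scale": c.scale,
            "estimate": c.estimate,
            "se": c.se,
            "ci_lo": c.ci_lo,
            "ci_hi": c.ci_hi,
            "t": c.t,
            "df": c.df,
            "p": c.p,
            "level": self.estimand.level,
            "matching": self.estimand.matching,
            "outcome_adjustment": list(self.outcome_spec.adjustment) if self.outcome_spec else None,
            "ps_adjustment": list(self.ps_spec.adjustment) if self.ps_spec else None,
            "selection": self.selection,
            "if_values_log_ratio": (
                (self.if1 / self.psi1 - self.if0 / self.psi0).tolist()
                if c.scale == "ratio"
                else (self.if1 - self.if0).tolist()
            ),
        }


def _design(frame: pd.DataFrame, a_col: np.ndarray, adjustment: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(frame)), a_col]
    for name in adjustment:
        if name not in frame.columns:
            raise KeyError(f"adjustment covariate {name!r} not found in data")
        cols.append(frame[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _fit_outcome(
    frame: pd.DataFrame,
    y: np.ndarray,
    arm: np.ndarray,
    weights: np.ndarray,
    spec: RegressionSpec,
) -> tuple[np.ndarray, np.ndarray, RegressionSpec]:
    """Initial outcome regression; returns predictions at a=1 and a=0.

    Falls back to the unadjusted (treatment-only) model with a warning if
    the adjusted fit is degenerate.
    """
    adjustment = spec.adjustment
    while True:
        X = _design(frame, arm.astype(float), adjustment)
        try:
            beta = fit_logistic(X, y, weights=weights)
            break
        except SeparationError:
            if not adjustment:
                raise
            warnings.warn(
                f"outcome regression with adjustment {adjustment} is degenerate; "
                "falling back to the unadjusted candidate",
                stacklevel=3,
            )
            adjustment = ()
    X1 = _design(frame, np.ones(len(frame)), adjustment)
    X0 = _design(frame, np.zeros(len(frame)), adjustment)
    used = RegressionSpec(role="outcome", level=spec.level, adjustment=adjustment)
    return expit(X1 @ beta), expit(X0 @ beta), used


def _fit_propensity(
    frame: pd.DataFrame,
    arm: np.ndarray,
    weights: np.ndarray,
    spec: RegressionSpec,
) -> tuple[np.ndarray, RegressionSpec]:
    """Propensity of treatment; empty adjustment means the known 0.5."""
    n = len(frame)
    if not spec.adjustment:
        return np.full(n, 0.5), spec
    cols = [np.ones(n)] + [frame[c].to_numpy(dtype=float) for c in spec.adjustment]
    X = np.column_stack(cols)
    try:
        beta = fit_logistic(X, arm.astype(float), weights=weights)
    except SeparationError:
        warnings.warn(
            f"propensity fit with adjustment {spec.adjustment} is degenerate; "
            "using the known design value 0.5",
            stacklevel=3,
        )
        return np.full(n, 0.5), RegressionSpec("propensity", spec.level, ())
    pi1 = expit(X @ beta)
    if np.any(pi1 < PS_BOUNDS[0]) or np.any(pi1 > PS_BOUNDS[1]):
        warnings.warn(
            f"estimated propensity outside {PS_BOUNDS}; truncating", stacklevel=3
        )
        pi1 = np.clip(pi1, *PS_BOUNDS)
    return pi1, spec


def _fluctuate(
    y: np.ndarray,
    arm: np.ndarray,
    mu1: np.ndarray,
    mu0: np.ndarray,
    pi1: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, FluctuationFit]:
    """Single weighted logistic MLE with both clever covariates and offset.

    Returns the targeted predictions at a=1 and a=0 and the fitted epsilons.
    """
    h1 = arm / pi1
    h0 = (1.0 - arm) / (1.0 - pi1)
    mu_obs = np.where(arm == 1, mu1, mu0)
    offset = logit(clip_probability(mu_obs, 1e-6, 1.0 - 1e-6))
    X = np.column_stack([h1, h0])
    try:
        eps = fit_logistic(X, y, weights=weights, offset=offset)
        converged = True
    except SeparationError:
        warnings.warn("fluctuation did not converge; keeping initial fit", stacklevel=3)
        eps = np.zeros(2)
        converged = False
    lo, hi = 1e-6, 1.0 - 1e-6
    mu1_t = expit(logit(clip_probability(mu1, lo, hi)) + eps[0] / pi1)
    mu0_t = expit(logit(clip_probability(mu0, lo, hi)) + eps[1] / (1.0 - pi1))
    mu_obs_t = np.where(arm == 1, mu1_t, mu0_t)
    s1 = float(np.sum(weights * h1 * (y - mu_obs_t)))
    s0 = float(np.sum(weights * h0 * (y - mu_obs_t)))
    return mu1_t, mu0_t, FluctuationFit(float(eps[0]), float(eps[1]), converged, s1, s0)


def _contrast(
    psi1: float,
    psi0: float,
    d1: np.ndarray,
    d0: np.ndarray,
    data: CRTData,
    spec: EstimandSpec,
    alpha: float = 0.05,
) -> tuple[ContrastResult, np.ndarray, np.ndarray]:
    """Route per-cluster IF contributions through break/keep-match inference."""
    if spec.matching == "keep":
        pair_ids = [c.pair_id for c in data.clusters]
        d1 = paired_if(d1, pair_ids)
        d0 = paired_if(d0, pair_ids)
        df = len(d1) - 1
    else:
        df = data.J - 2
    fn = delta_ratio if spec.scale == "ratio" else delta_difference
    return fn(psi1, psi0, d1, d0, df, alpha=alpha), d1, d0


def _cluster_core(
    data: CRTData,
    frame: pd.DataFrame,
    w: np.ndarray,
    mu1: np.ndarray,
    mu0: np.ndarray,
    ps_reg: RegressionSpec,
    spec: EstimandSpec,
    alpha: float,
) -> tuple[float, float, np.ndarray, np.ndarray, FluctuationFit, RegressionSpec, ContrastResult, np.ndarray, np.ndarray]:
    """Steps shared by the cluster-level and hybrid TMLEs: propensity,
    fluctuation, weighted averaging, and the cluster-level IF."""
    y = frame["Yc"].to_numpy(dtype=float)
    arm = frame["A"].to_numpy(dtype=float)
    pi1, ps_used = _fit_propensity(frame, arm, w, ps_reg)
    mu1_t, mu0_t, fluct = _fluctuate(y, arm, mu1, mu0, pi1, w)
    psi1 = float(np.sum(w * mu1_t) / np.sum(w))
    psi0 = float(np.sum(w * mu0_t) / np.sum(w))
    d1 = w * (arm / pi1 * (y - mu1_t) + mu1_t - psi1)
    d0 = w * ((1.0 - arm) / (1.0 - pi1) * (y - mu0_t) + mu0_t - psi0)
    contrast, u1, u0 = _contrast(psi1, psi0, d1, d0, data, spec, alpha)
    return psi1, psi0, d1, d0, fluct, ps_used, contrast, u1, u0


def cluster_tmle(
    data: CRTData,
    weights: WeightScheme | None = None,
    spec: EstimandSpec | None = None,
    outcome_reg: RegressionSpec | None = None,
    ps_reg: RegressionSpec | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Cluster-level TMLE of the cluster- or individual-level effect.

    Aggregates outcomes to the cluster level, fits a weighted logistic
    outcome regression of ``Yc`` on treatment plus the adjustment set,
    estimates (or uses the known 0.5) propensity, fluctuates on the logit
    scale with the two inverse-propensity clever covariates, and averages
    the targeted predictions with the analysis weights implied by the
    target level. With empty adjustment sets this reduces exactly to the
    unadjusted contrast of (weighted) arm means.
    """
    spec = spec or EstimandSpec()
    weights = weights or WeightScheme(target=spec.level)
    outcome_reg = outcome_reg or RegressionSpec("outcome", "cluster")
    ps_reg = ps_reg or RegressionSpec("propensity", "cluster")
    if outcome_reg.level != "cluster" or ps_reg.level != "cluster":
        raise ValueError("cluster_tmle requires cluster-level regression specs")
    _check_binary(data)
    frame = data.cluster_frame(weights)
    w = weights.cluster_analysis_weights(data)
    y = frame["Yc"].to_numpy(dtype=float)
    arm = frame["A"].to_numpy(dtype=float)
    mu1, mu0, outcome_used = _fit_outcome(frame, y, arm, w, outcome_reg)
    psi1, psi0, d1, d0, fluct, ps_used, contrast, u1, u0 = _cluster_core(
        data, frame, w, mu1, mu0, ps_reg, spec, alpha
    )
    return EffectEstimate(
        estimator="cluster_tmle",
        psi1=psi1,
        psi0=psi0,
        contrast=contrast,
        if1=u1,
        if0=u0,
        fluctuation=fluct,
        estimand=spec,
        outcome_spec=outcome_used,
        ps_spec=ps_used,
    )


def hierarchical_tmle(
    data: CRTData,
    weights: WeightScheme | None = None,
    spec: EstimandSpec | None = None,
    outcome_reg: RegressionSpec | None = None,
    ps_reg: RegressionSpec | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Hierarchical TMLE: pooled individual-level fits, cluster-level inference.

    The outcome regression, propensity score, and fluctuation are fitted on
    the pooled participant rows (weighted by the per-individual analysis
    weights of the target level); targeted predictions are then averaged —
    within clusters first for a cluster-level target — and the
    individual-level influence function is aggregated to the cluster, the
    independent unit, for variance estimation.
    """
    spec = spec or EstimandSpec(level="individual")
    weights = weights or WeightScheme(target=spec.level)
    outcome_reg = outcome_reg or RegressionSpec("outcome", "individual")
    ps_reg = ps_reg or RegressionSpec("propensity", "individual")
    if outcome_reg.level != "individual" or ps_reg.level != "individual":
        raise ValueError("hierarchical_tmle requires individual-level regression specs")
    _check_binary(data)
    frame = data.individual_frame()
    omega = weights.individual_analysis_weights(data)
    y = frame["Y"].to_numpy(dtype=float)
    arm = frame["A"].to_numpy(dtype=float)
    mu1, mu0, outcome_used = _fit_outcome(frame, y, arm, omega, outcome_reg)
    pi1, ps_used = _fit_propensity(frame, arm, omega, ps_reg)
    mu1_t, mu0_t, fluct = _fluctuate(y, arm, mu1, mu0, pi1, omega)
    psi1 = float(np.sum(omega * mu1_t) / np.sum(omega))
    psi0 = float(np.sum(omega * mu0_t) / np.sum(omega))
    # individual-level IF, aggregated to clusters with the analysis weights
    d1_ind = omega * (arm / pi1 * (y - mu1_t) + mu1_t - psi1)
    d0_ind = omega * ((1.0 - arm) / (1.0 - pi1) * (y - mu0_t) + mu0_t - psi0)
    cluster_ids = frame["cluster_id"].to_numpy()
    scale = data.J / data.NT
    d1 = np.empty(data.J)
    d0 = np.empty(data.J)
    for k, c in enumerate(data.clusters):
        mask = cluster_ids == c.cluster_id
        d1[k] = scale * d1_ind[mask].sum()
        d0[k] = scale * d0_ind[mask].sum()
    contrast, u1, u0 = _contrast(psi1, psi0, d1, d0, data, spec, alpha)
    return EffectEstimate(
        estimator="hierarchical_tmle",
        psi1=psi1,
        psi0=psi0,
        contrast=contrast,
        if1=u1,
        if0=u0,
        fluctuation=fluct,
        estimand=spec,
        outcome_spec=outcome_used,
        ps_spec=ps_used,
    )


def hybrid_tmle(
    data: CRTData,
    weights: WeightScheme | None = None,
    spec: EstimandSpec | None = None,
    outcome_reg: RegressionSpec | None = None,
    ps_reg: RegressionSpec | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Hybrid TMLE: individual-level outcome regression, cluster-level targeting.

    The pooled individual-level outcome regression is fitted first and its
    predictions are aggregated with the alpha weights to cluster-level
    initial estimates ``muc_j(a) = sum_i alpha_ij mu(a, E_j, W_ij)``; the
    propensity fit, fluctuation, averaging, and influence function then
    proceed exactly as in the cluster-level TMLE.
    """
    spec = spec or EstimandSpec()
    weights = weights or WeightScheme(target=spec.level)
    outcome_reg = outcome_reg or RegressionSpec("outcome", "individual")
    ps_reg = ps_reg or RegressionSpec("propensity", "cluster")
    if outcome_reg.level != "individual":
        raise ValueError("hybrid_tmle requires an individual-level outcome regression")
    if ps_reg.level != "cluster":
        raise ValueError("hybrid_tmle requires a cluster-level propensity regression")
    _check_binary(data)
    ind = data.individual_frame()
    omega = weights.individual_analysis_weights(data)
    y_ind = ind["Y"].to_numpy(dtype=float)
    arm_ind = ind["A"].to_numpy(dtype=float)
    mu1_ind, mu0_ind, outcome_used = _fit_outcome(ind, y_ind, arm_ind, omega, outcome_reg)
    cluster_ids = ind["cluster_id"].to_numpy()
    frame = data.cluster_frame(weights)
    mu1 = np.empty(data.J)
    mu0 = np.empty(data.J)
    for k, c in enumerate(data.clusters):
        mask = cluster_ids == c.cluster_id
        a = weights.alpha_for(c)
        mu1[k] = float(a @ mu1_ind[mask])
        mu0[k] = float(a @ mu0_ind[mask])
    w = weights.cluster_analysis_weights(data)
    psi1, psi0, d1, d0, fluct, ps_used, contrast, u1, u0 = _cluster_core(
        data, frame, w, mu1, mu0, ps_reg, spec, alpha
    )
    return EffectEstimate(
        estimator="hybrid_tmle",
        psi1=psi1,
        psi0=psi0,
        contrast=contrast,
        if1=u1,
        if0=u0,
        fluctuation=fluct,
        estimand=spec,
        outcome_spec=outcome_used,
        ps_spec=ps_used,
    )


def _check_binary(data: CRTData) -> None:
    """The logistic fluctuation is defined for outcomes bounded in [0, 1].

    Binary outcomes and cluster-level proportions qualify; unbounded
    continuous outcomes are rejected with a clear error.
    """
    for c in data.clusters:
        if np.any(c.Y < 0.0) or np.any(c.Y > 1.0):
            raise ValueError(
                f"cluster {c.cluster_id!r} has outcomes outside [0, 1]; the logistic "
                "fluctuation supports binary or bounded-proportion outcomes only"
            )
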