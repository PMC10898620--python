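"""Classical CRT estimators: unadjusted contrasts, geometric-mean log
t-test, covariate-adjusted residuals (CARE), GEE, and augmented GEE.

These are the comparators commonly used in practice. The unadjusted
contrast and the log t-test use only cluster-level summaries; CARE, GEE
and Aug-GEE pool individual-level data. They differ in which effect they
naturally target: the unadjusted contrast targets the cluster-level ratio
of arithmetic means (or, with size weights, the individual-level ratio);
the log t-test and CARE target the ratio of *geometric* means of cluster
outcomes; GEE and Aug-GEE with a log link target the individual-level
relative risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core import CRTData, EstimandSpec, WeightScheme
from .inference import ContrastResult, delta_difference, delta_ratio, paired_if
from .tmle import EffectEstimate, FluctuationFit, RegressionSpec

__all__ = ["unadjusted_contrast", "geometric_ttest", "care", "gee", "aug_gee", "GEEFit", "CAREFit"]


def unadjusted_contrast(
    data: CRTData,
    weights: WeightScheme | None = None,
    spec: EstimandSpec | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Contrast of (analysis-weighted) arm-specific means of cluster outcomes.

    On the ratio scale, inference is by the delta method on the log ratio
    with the per-cluster influence function ``w_j * 1(A_j=a)/0.5 *
    (Yc_j - mean_a)``; this coincides exactly with the cluster-level TMLE
    under empty adjustment sets. On the difference scale with a
    cluster-level target, a Student t-test on the cluster outcomes is used.
    """
    spec = spec or EstimandSpec()
    weights = weights or WeightScheme(target=spec.level)
    frame = data.cluster_frame(weights)
    w = weights.cluster_analysis_weights(data)
    y = frame["Yc"].to_numpy(dtype=float)
    arm = frame["A"].to_numpy(dtype=int)
    m1 = float(np.sum(w * (arm == 1) * y) / np.sum(w * (arm == 1)))
    m0 = float(np.sum(w * (arm == 0) * y) / np.sum(w * (arm == 0)))
    if spec.scale == "ratio" and (m1 <= 0 or m0 <= 0):
        raise ValueError("zero arm mean; the ratio contrast is undefined")
    d1 = w * 2.0 * (arm == 1) * (y - m1)
    d0 = w * 2.0 * (arm == 0) * (y - m0)
    if spec.matching == "keep":
        pair_ids = [c.pair_id for c in data.clusters]
        d1 = paired_if(d1, pair_ids)
        d0 = paired_if(d0, pair_ids)
        df = len(d1) - 1
    else:
        df = data.J - 2
    if spec.scale == "ratio":
        contrast = delta_ratio(m1, m0, d1, d0, df, alpha=alpha)
    elif spec.level == "cluster" and spec.matching == "break":
        # classic two-sample Student t-test on the cluster outcomes
        y1, y0 = y[arm == 1], y[arm == 0]
        n1, n0 = len(y1), len(y0)
        sp2 = ((n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1)) / (n1 + n0 - 2)
        se = float(np.sqrt(sp2 * (1 / n1 + 1 / n0)))
        est = m1 - m0
        t_stat = est / se if se > 0 else np.nan
        df = n1 + n0 - 2
        p = float(2 * stats.t.sf(abs(t_stat), df)) if se > 0 else np.nan
        crit = stats.t.ppf(1 - alpha / 2, df)
        contrast = ContrastResult(est, se, est - crit * se, est + crit * se, t_stat, df, p, "difference")
    else:
        contrast = delta_difference(m1, m0, d1, d0, df, alpha=alpha)
    return EffectEstimate(
        estimator="unadjusted",
        psi1=m1,
        psi0=m0,
        contrast=contrast,
        if1=d1,
        if0=d0,
        fluctuation=FluctuationFit(0.0, 0.0, True),
        estimand=spec,
        outcome_spec=RegressionSpec("outcome", "cluster"),
        ps_spec=RegressionSpec("propensity", "cluster"),
    )


def _two_sample_t(x1: np.ndarray, x0: np.ndarray, alpha: float, welch: bool) -> ContrastResult:
    n1, n0 = len(x1), len(x0)
    diff = float(x1.mean() - x0.mean())
    v1, v0 = x1.var(ddof=1), x0.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v0 / n0
        df = (
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
            if se2 > 0
            else n1 + n0 - 2
        )
    else:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se2 = sp2 * (1 / n1 + 1 / n0)
        df = n1 + n0 - 2
    se = float(np.sqrt(se2))
    if se == 0:
        warnings.warn("zero variance in t-test; p-value undefined", stacklevel=3)
        t_stat, p = np.nan, np.nan
    else:
        t_stat = diff / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return ContrastResult(
        estimate=float(np.exp(diff)),
        se=se,
        ci_lo=float(np.exp(diff - crit * se)),
        ci_hi=float(np.exp(diff + crit * se)),
        t=float(t_stat),
        df=float(df),
        p=p,
        scale="ratio",
    )


def geometric_ttest(data: CRTData, alpha: float = 0.05) -> EffectEstimate:
    """Ratio of geometric means of cluster outcomes via a log-scale t-test.

    Cluster outcomes are log-transformed, averaged within arm, and the
    difference of arm means is tested with a Welch t-test; exponentiating
    recovers the geometric mean ratio — a different estimand from the ratio
    of arithmetic means.
    """
    frame = data.cluster_frame()
    y = frame["Yc"].to_numpy(dtype=float)
    arm = frame["A"].to_numpy(dtype=int)
    if np.any(y <= 0):
        bad = frame.loc[y <= 0, "cluster_id"].tolist()
        raise ValueError(
            f"clusters with non-positive outcome {bad}: the geometric mean is "
            "undefined; consider the arithmetic-mean ratio instead"
        )
    logs = np.log(y)
    contrast = _two_sample_t(logs[arm == 1], logs[arm == 0], alpha, welch=True)
    g1 = float(np.exp(logs[arm == 1].mean()))
    g0 = float(np.exp(logs[arm == 0].mean()))
    return EffectEstimate(
        estimator="geometric_ttest",
        psi1=g1,
        psi0=g0,
        contrast=contrast,
        if1=np.zeros(data.J),
        if0=np.zeros(data.J),
        fluctuation=FluctuationFit(0.0, 0.0, True),
        estimand=EstimandSpec(level="cluster", scale="ratio"),
    )


@dataclass
class CAREFit:
    """Per-cluster observed/expected events and the log-residual t-test."""

    observed: np.ndarray
    expected: np.ndarray
    ratio_residuals: np.ndarray
    estimate: EffectEstimate


def care(data: CRTData, adjustment: Sequence[str] = (), alpha: float = 0.05) -> EffectEstimate:
    """Covariate-adjusted residuals estimator (ratio residuals, log scale).

    Fits a pooled logistic regression of the individual outcome on the
    adjustment covariates — never on the treatment — sums the fitted
    probabilities to expected cluster event counts ``e_j``, forms ratio
    residuals ``R_j = d_j/e_j`` against the observed counts, and compares
    arm means of ``log R_j`` with a two-sample Student t-test. After
    exponentiation this targets the ratio of geometric means.
    """
    if "A" in adjustment:
        raise ValueError("CARE adjusts for covariates only, never the treatment")
    frame = data.individual_frame()
    y = frame["Y"].to_numpy(dtype=float)
    X = sm.add_constant(
        frame[list(adjustment)].to_numpy(dtype=float)
        if adjustment
        else np.empty((len(frame), 0)),
        has_constant="add",
    )
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    mu = np.asarray(fit.fittedvalues)
    cluster_ids = frame["cluster_id"].to_numpy()
    d = np.empty(data.J)
    e = np.empty(data.J)
    for k, c in enumerate(data.clusters):
        mask = cluster_ids == c.cluster_id
        d[k] = y[mask].sum()
        e[k] = mu[mask].sum()
    if np.any(d == 0):
        bad = [data.clusters[k].cluster_id for k in np.flatnonzero(d == 0)]
        raise ValueError(
            f"clusters with zero observed events {bad}: the log ratio residual "
            "is undefined; an arithmetic-residual analysis would be required"
        )
    r = d / e
    arm = data.arms()
    contrast = _two_sample_t(np.log(r[arm == 1]), np.log(r[arm == 0]), alpha, welch=False)
    est = EffectEstimate(
        estimator="care",
        psi1=float(np.exp(np.log(r[arm == 1]).mean())),
        psi0=float(np.exp(np.log(r[arm == 0]).mean())),
        contrast=contrast,
        if1=np.zeros(data.J),
        if0=np.zeros(data.J),
        fluctuation=FluctuationFit(0.0, 0.0, True),
        estimand=EstimandSpec(level="cluster", scale="ratio"),
        outcome_spec=RegressionSpec("outcome", "individual", tuple(adjustment)),
    )
    est.selection = {"care_adjustment": list(adjustment)}
    return est


@dataclass
class GEEFit:
    """Log-link GEE fit with small-sample-corrected robust inference."""

    params: np.ndarray
    names: list[str]
    beta_a: float
    se_beta_a: float
    se_beta_a_uncorrected: float
    working: str
    df: int
    alpha: float = 0.05
    estimator: str = "gee"

    @property
    def estimate(self) -> float:
        return float(np.exp(self.beta_a))

    @property
    def t(self) -> float:
        return self.beta_a / self.se_beta_a

    @property
    def p(self) -> float:
        return float(2 * stats.t.sf(abs(self.t), self.df))

    @property
    def ci(self) -> tuple[float, float]:
        crit = stats.t.ppf(1 - self.alpha / 2, self.df)
        return (
            float(np.exp(self.beta_a - crit * self.se_beta_a)),
            float(np.exp(self.beta_a + crit * self.se_beta_a)),
        )

    @property
    def ci_lo(self) -> float:
        return self.ci[0]

    @property
    def ci_hi(self) -> float:
        return self.ci[1]

    @property
    def se(self) -> float:
        """Log-scale SE of the treatment contrast."""
        return self.se_beta_a

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "coefficients": dict(zip(self.names, self.params.tolist())),
            "working_correlation": self.working,
            "estimate": self.estimate,
            "se": self.se_beta_a,
            "se_uncorrected": self.se_beta_a_uncorrected,
            "ci_lo": self.ci[0],
            "ci_hi": self.ci[1],
            "t": self.t,
            "df": self.df,
            "p": self.p,
        }


_FG_BOUND = 0.75  # bound b on the leverage in the Fay-Graubard multiplier


def _fg_sandwich(
    X: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    groups: np.ndarray,
    extra_scores: dict[int, np.ndarray] | None = None,
    extra_bread: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust sandwich covariance with Fay-Graubard small-sample correction.

    Log-link, independence working correlation, Poisson-type variance
    ``v(mu)=mu``, so ``D_j' V_j^{-1} = X_j'`` and the per-cluster score is
    ``g_j = X_j'(y_j - mu_j)``. The correction inflates each cluster's
    score by ``diag{(1 - min(b, Q_j,kk))^{-1/2}}`` with
    ``Q_j = X_j' W_j X_j M^{-1}``; the multiplier never deflates, so the
    corrected variance dominates the naive sandwich. Returns (corrected,
    uncorrected) covariance matrices.
    """
    p = X.shape[1]
    M = (X * mu[:, None]).T @ X
    if extra_bread is not None:
        M = M + extra_bread
    Minv = np.linalg.inv(M)
    meat = np.zeros((p, p))
    meat_naive = np.zeros((p, p))
    for j in np.unique(groups):
        rows = groups == j
        Xj = X[rows]
        gj = Xj.T @ (y[rows] - mu[rows])
        if extra_scores is not None:
            gj = gj + extra_scores[int(j)]
        Qj = (Xj * mu[rows][:, None]).T @ Xj @ Minv
        mult = (1.0 - np.minimum(_FG_BOUND, np.diag(Qj))) ** -0.5
        gj_c = mult * gj
        meat += np.outer(gj_c, gj_c)
        meat_naive += np.outer(gj, gj)
    return Minv @ meat @ Minv.T, Minv @ meat_naive @ Minv.T


def _pooled_design(frame: pd.DataFrame, adjustment: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    names = ["const", "A"] + list(adjustment)
    cols = [np.ones(len(frame)), frame["A"].to_numpy(dtype=float)]
    cols += [frame[c].to_numpy(dtype=float) for c in adjustment]
    return np.column_stack(cols), names


def gee(
    data: CRTData,
    adjustment: Sequence[str] = (),
    working: str = "independence",
    alpha: float = 0.05,
) -> GEEFit:
    """Log-link GEE for the individual-level relative effect.

    The mean model is ``log mu = b0 + bA*A (+ covariates)``; ``exp(bA)``
    is the relative effect. Point estimation uses statsmodels' GEE with a
    Poisson-type variance (the standard log-link relative-risk working
    model for a binary outcome); inference uses the robust sandwich with
    the Fay-Graubard small-sample correction and a t(J-2) reference.
    """
    frame = data.individual_frame()
    X, names = _pooled_design(frame, adjustment)
    y = frame["Y"].to_numpy(dtype=float)
    codes = {c.cluster_id: k for k, c in enumerate(data.clusters)}
    groups = frame["cluster_id"].map(codes).to_numpy(dtype=int)
    cov = {"independence": sm.cov_struct.Independence(), "exchangeable": sm.cov_struct.Exchangeable()}
    if working not in cov:
        raise ValueError(f"unsupported working correlation {working!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=groups, family=sm.families.Poisson(), cov_struct=cov[working])
        res = model.fit(maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("GEE did not converge to finite coefficients")
    params = np.asarray(res.params)
    mu = np.exp(X @ params)
    cov_c, cov_n = _fg_sandwich(X, y, mu, groups)
    return GEEFit(
        params=params,
        names=names,
        beta_a=float(params[1]),
        se_beta_a=float(np.sqrt(cov_c[1, 1])),
        se_beta_a_uncorrected=float(np.sqrt(cov_n[1, 1])),
        working=working,
        df=data.J - 2,
        alpha=alpha,
        estimator="gee",
    )


def aug_gee(
    data: CRTData,
    adjustment: Sequence[str] = (),
    alpha: float = 0.05,
) -> GEEFit:
    """Augmented GEE: marginal log-link model with an augmentation term.

    Solves the marginal (treatment-only) GEE score minus
    ``sum_a [1(A_j=a) - 0.5] * gamma_aj`` where ``gamma_aj`` contrasts a
    pooled conditional outcome regression (logistic in treatment plus the
    adjustment covariates) with the marginal model, restoring the marginal
    interpretation of ``exp(bA)`` while adjusting for covariates. The
    propensity 0.5 is known by design. With no adjustment covariates the
    augmentation vanishes and the estimator reduces to :func:`gee`.
    """
    frame = data.individual_frame()
    y = frame["Y"].to_numpy(dtype=float)
    a = frame["A"].to_numpy(dtype=float)
    codes = {c.cluster_id: k for k, c in enumerate(data.clusters)}
    groups = frame["cluster_id"].map(codes).to_numpy(dtype=int)
    X = np.column_stack([np.ones(len(y)), a])

    # conditional outcome regression (logistic, includes treatment)
    Xc, _ = _pooled_design(frame, adjustment)
    cond = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    beta_c = np.asarray(cond.params)
    X1 = Xc.copy()
    X1[:, 1] = 1.0
    X0 = Xc.copy()
    X0[:, 1] = 0.0
    m1 = 1.0 / (1.0 + np.exp(-(X1 @ beta_c)))
    m0 = 1.0 / (1.0 + np.exp(-(X0 @ beta_c)))

    arms = data.arms().astype(float)
    n_per = np.array([c.size for c in data.clusters], dtype=float)
    sum_m1 = np.bincount(groups, weights=m1, minlength=data.J)
    sum_m0 = np.bincount(groups, weights=m0, minlength=data.J)
    sum_y = np.bincount(groups, weights=y, minlength=data.J)

    def estfun(beta: np.ndarray) -> np.ndarray:
        mu1 = np.exp(beta[0] + beta[1])
        mu0 = np.exp(beta[0])
        mu_obs = np.where(arms == 1, mu1, mu0)
        # GEE part: sum_j X_j'(Y_j - mu_j), collapsed to cluster sums
        g0 = np.sum(sum_y - n_per * mu_obs)
        g1 = np.sum(arms * (sum_y - n_per * mu_obs))
        # augmentation: sum_a (1(A_j=a) - 0.5) gamma_aj with
        # gamma_1j = [sum_i(m1 - mu1); sum_i(m1 - mu1)], gamma_0j = [sum_i(m0 - mu0); 0]
        s = arms - 0.5
        aug0 = np.sum(s * ((sum_m1 - n_per * mu1) - (sum_m0 - n_per * mu0)))
        aug1 = np.sum(s * (sum_m1 - n_per * mu1))
        return np.array([g0 - aug0, g1 - aug1])

    start = gee(data).params[:2]
    sol = optimize.root(estfun, start, method="hybr")
    if not sol.success:
        raise RuntimeError(f"augmented GEE did not converge: {sol.message}")
    beta = sol.x
    mu1 = np.exp(beta[0] + beta[1])
    mu0 = np.exp(beta[0])
    mu = np.exp(X @ beta)

    # per-cluster augmentation scores and their beta-derivative for the bread
    s = arms - 0.5
    extra_scores = {}
    for j in range(data.J):
        aug0 = s[j] * ((sum_m1[j] - n_per[j] * mu1) - (sum_m0[j] - n_per[j] * mu0))
        aug1 = s[j] * (sum_m1[j] - n_per[j] * mu1)
        extra_scores[j] = -np.array([aug0, aug1])
    # d(-sum (1(A=a)-pi) gamma_a)/dbeta: derivative of -gamma through mu(a)
    b00 = float(np.sum(s * n_per) * (mu1 - mu0))
    b01 = float(np.sum(s * n_per) * mu1)
    b10 = float(np.sum(s * n_per) * mu1)
    b11 = float(np.sum(s * n_per) * mu1)
    extra_bread = -np.array([[b00, b01], [b10, b11]])
    cov_c, cov_n = _fg_sandwich(X, y, mu, groups, extra_scores=extra_scores, extra_bread=extra_bread)
    return GEEFit(
        params=beta,
        names=["const", "A"],
        beta_a=float(beta[1]),
        se_beta_a=float(np.sqrt(cov_c[1, 1])),
        se_beta_a_uncorrected=float(np.sqrt(cov_n[1, 1])),
        working="independence",
        df=data.J - 2,
        alpha=alpha,
        estimator="aug_gee",
    )
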