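"""Shared inference kernel: influence-function variance, delta-method
contrasts, t-based intervals, and matched-pair-preserving variance.

Every estimator in the package reduces to a vector of per-independent-unit
influence-function (IF) contributions; the variance estimate is the sample
variance of those contributions divided by the number of independent units
(clusters, or pairs when the randomization matches are kept). Confidence
intervals and tests use the t-distribution with user-supplied degrees of
freedom — J-2 when matches are broken, J/2-1 when kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ContrastResult", "delta_ratio", "delta_difference", "paired_if"]


@dataclass(frozen=True)
class ContrastResult:
    """Point estimate with IF-based t inference.

    For a ratio contrast the SE is on the log scale and the CI is the
    exponential of a symmetric log-scale interval.
    """

    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    t: float
    df: int
    p: float
    scale: str = "ratio"


def _if_se(if_values: np.ndarray) -> float:
    n = len(if_values)
    return float(np.sqrt(np.var(if_values, ddof=1) / n))


def delta_ratio(
    psi1: float,
    psi0: float,
    if1: Sequence[float],
    if0: Sequence[float],
    df: int,
    alpha: float = 0.05,
) -> ContrastResult:
    """Delta-method inference for the ratio ``psi1/psi0``.

    The per-unit IF of the log ratio is ``if1/psi1 - if0/psi0``; the SE is
    the sample SD of those contributions over sqrt(n). The CI is obtained
    by exponentiating a symmetric t interval on the log scale.
    """
    if1 = np.asarray(if1, dtype=float)
    if0 = np.asarray(if0, dtype=float)
    if if1.shape != if0.shape:
        raise ValueError("if1 and if0 must have the same length")
    n = len(if1)
    if n < 3:
        raise ValueError(f"need at least 3 independent units, got {n}")
    if psi1 <= 0 or psi0 <= 0:
        raise ValueError("ratio contrast requires strictly positive arm means")
    if_log = if1 / psi1 - if0 / psi0
    se = _if_se(if_log)
    est = psi1 / psi0
    log_est = np.log(est)
    if se == 0.0 and log_est == 0.0:
        # degenerate but unambiguous: the estimate sits exactly at the null
        t_stat, p = 0.0, 1.0
    elif se == 0.0:
        warnings.warn("zero IF variance; p-value undefined", stacklevel=2)
        t_stat, p = np.nan, np.nan
    else:
        t_stat = log_est / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return ContrastResult(
        estimate=float(est),
        se=se,
        ci_lo=float(np.exp(log_est - crit * se)),
        ci_hi=float(np.exp(log_est + crit * se)),
        t=float(t_stat),
        df=int(df),
        p=p,
        scale="ratio",
    )


def delta_difference(
    psi1: float,
    psi0: float,
    if1: Sequence[float],
    if0: Sequence[float],
    df: int,
    alpha: float = 0.05,
) -> ContrastResult:
    """IF-based t inference for the difference ``psi1 - psi0``."""
    if1 = np.asarray(if1, dtype=float)
    if0 = np.asarray(if0, dtype=float)
    if if1.shape != if0.shape:
        raise ValueError("if1 and if0 must have the same length")
    n = len(if1)
    if n < 3:
        raise ValueError(f"need at least 3 independent units, got {n}")
    if_diff = if1 - if0
    se = _if_se(if_diff)
    est = psi1 - psi0
    if se == 0.0 and est == 0.0:
        t_stat, p = 0.0, 1.0
    elif se == 0.0:
        warnings.warn("zero IF variance; p-value undefined", stacklevel=2)
        t_stat, p = np.nan, np.nan
    else:
        t_stat = est / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return ContrastResult(
        estimate=float(est),
        se=se,
        ci_lo=float(est - crit * se),
        ci_hi=float(est + crit * se),
        t=float(t_stat),
        df=int(df),
        p=p,
        scale="difference",
    )


def paired_if(if_values: Sequence[float], pair_ids: Sequence[object]) -> np.ndarray:
    """Collapse per-cluster IF contributions to per-pair contributions.

    When the matched pairs used for randomization are kept in analysis, the
    pair is the independent unit: its IF contribution is the average of its
    two clusters' contributions (each pair stands for two clusters, so the
    estimator is the mean over pairs of these averages). Downstream
    variance then uses n = J/2 units and df = J/2 - 1; when the two
    clusters of a pair have negatively correlated contributions — the point
    of matching on outcome predictors — the paired variance is smaller
    than the one treating clusters as independent.
    """
    if_values = np.asarray(if_values, dtype=float)
    if len(if_values) != len(pair_ids):
        raise ValueError("one pair id required per IF value")
    groups: dict[object, list[float]] = {}
    for pid, v in zip(pair_ids, if_values):
        if pid is None:
            raise ValueError("cluster without a pair id; pairing is incomplete")
        groups.setdefault(pid, []).append(float(v))
    bad = [pid for pid, vals in groups.items() if len(vals) != 2]
    if bad:
        raise ValueError(f"pairs without exactly 2 clusters: {bad}")
    return np.array([0.5 * sum(groups[pid]) for pid in sorted(groups, key=str)])
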