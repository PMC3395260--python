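"""Nonparametric (empirical) ROC estimation.

The empirical ROC curve uses every distinct observed value as a cutoff,
classifying a subject positive when Y >= c.  The area under the step curve
equals the Mann-Whitney statistic with ties scored 1/2, and its variance
uses the tie-corrected exceedance components Q1 and Q2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .binormal import wald_ci
from .curves import RocCurve
from .data import SampleData


@dataclass(frozen=True)
class EmpiricalEstimate:
    curve: RocCurve
    auc: float
    q1: float
    q2: float
    var_auc: float
    se_auc: float
    ci_low: float
    ci_high: float
    ci_level: float


def empirical_roc_curve(sample: SampleData) -> RocCurve:
    """Empirical ROC step curve.

    One (FPR, TPR) point per distinct observed value used as cutoff
    (positive when Y >= c), preceded by the (0, 0) anchor at c = +inf.
    The overall minimum cutoff yields the (1, 1) anchor.
    """
    y1, y0 = sample.diseased, sample.nondiseased
    n1, n0 = sample.n1, sample.n0
    cuts = np.unique(np.concatenate([y1, y0]))[::-1]  # descending
    y1s = np.sort(y1)
    y0s = np.sort(y0)
    # s(c) = #{Y >= c}: count of sorted values at or above each cutoff
    tpr = (n1 - np.searchsorted(y1s, cuts, side="left")) / n1
    fpr = (n0 - np.searchsorted(y0s, cuts, side="left")) / n0
    thresholds = np.concatenate([[np.inf], cuts])
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    return RocCurve(thresholds, fpr, tpr)


def empirical_auc(sample: SampleData) -> float:
    """Mann-Whitney AUC: mean over all n1*n0 pairs of the kernel
    psi(Y1, Y0) = 1, 1/2, 0 for Y1 >, =, < Y0.

    Computed via midranks, which reproduces the pairwise kernel sum exactly
    and equals the trapezoidal area under the empirical step curve.
    """
    y1, y0 = sample.diseased, sample.nondiseased
    n1, n0 = sample.n1, sample.n0
    ranks = rankdata(np.concatenate([y1, y0]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _tie_counts(values: np.ndarray, other_sorted: np.ndarray):
    """For each distinct value y of `values`: (count of y, #other > y,
    #other == y, #other < y)."""
    uniq, counts = np.unique(values, return_counts=True)
    lo = np.searchsorted(other_sorted, uniq, side="left")
    hi = np.searchsorted(other_sorted, uniq, side="right")
    n_other = other_sorted.size
    return uniq, counts, n_other - hi, hi - lo, lo


def empirical_auc_variance(sample: SampleData) -> tuple[float, float, float]:
    """Variance of the empirical AUC via the Mann-Whitney components.

    Returns ``(q1, q2, var)`` where

        Q1 = 1/(n0 n1^2) * sum over nondiseased values y of
             n0^{=y} [ (n1^{>y})^2 + n1^{>y} n1^{=y} + (n1^{=y})^2 / 3 ]
        Q2 = 1/(n0^2 n1) * sum over diseased values y of
             n1^{=y} [ (n0^{<y})^2 + n0^{<y} n0^{=y} + (n0^{=y})^2 / 3 ]

        V  = [ A(1-A) + (n1-1)(Q1 - A^2) + (n0-1)(Q2 - A^2) ] / (n1 n0)

    On tie-free data Q1 is the probability that two random diseased
    subjects both exceed one random nondiseased subject, and V reduces to
    the classic Hanley-McNeil variance.
    """
    n1, n0 = sample.n1, sample.n0
    if n1 < 2 or n0 < 2:
        raise ValueError("AUC variance requires at least 2 subjects per group")
    auc = empirical_auc(sample)
    y1s = np.sort(sample.diseased)
    y0s = np.sort(sample.nondiseased)
    _, c0, n1_gt, n1_eq, _ = _tie_counts(sample.nondiseased, y1s)
    q1 = float((c0 * (n1_gt**2 + n1_gt * n1_eq + n1_eq**2 / 3.0)).sum() / (n0 * n1**2))
    _, c1, _, n0_eq, n0_lt = _tie_counts(sample.diseased, y0s)
    q2 = float((c1 * (n0_lt**2 + n0_lt * n0_eq + n0_eq**2 / 3.0)).sum() / (n0**2 * n1))
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return q1, q2, max(var, 0.0)


def fit_empirical(sample: SampleData, ci_level: float = 0.95) -> EmpiricalEstimate:
    """Empirical ROC curve, Mann-Whitney AUC, variance and Wald interval."""
    curve = empirical_roc_curve(sample)
    auc = empirical_auc(sample)
    q1, q2, var = empirical_auc_variance(sample)
    se = math.sqrt(var)
    ci_low, ci_high = wald_ci(auc, se, ci_level)
    return EmpiricalEstimate(
        curve=curve,
        auc=auc,
        q1=q1,
        q2=q2,
        var_auc=var,
        se_auc=se,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
    )
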