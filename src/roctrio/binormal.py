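"""Parametric (binormal) ROC estimation.

The binormal model assumes the test results are normal in each group,
Y1 ~ N(mu1, sigma1^2) and Y0 ~ N(mu0, sigma0^2), giving the smooth curve
ROC(t) = Phi(a + b Phi^-1(t)) with intercept a = (mu1 - mu0)/sigma1 and
slope b = sigma0/sigma1, and AUC = Phi(a / sqrt(1 + b^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import SampleData


@dataclass(frozen=True)
class BinormalEstimate:
    """Moment plug-in binormal fit with delta-method inference for the AUC."""

    mu1: float
    mu0: float
    sigma1: float
    sigma0: float
    a_hat: float
    b_hat: float
    var_a: float
    var_b: float
    cov_ab: float
    auc: float
    se_auc: float
    ci_low: float
    ci_high: float
    ci_level: float


def binormal_auc(a: float, b: float) -> float:
    """AUC implied by binormal parameters: Phi(a / sqrt(1 + b^2)).

    ``b`` must be strictly positive (it is a ratio of standard deviations).
    """
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    return float(norm.cdf(a / math.sqrt(1.0 + b * b)))


def binormal_param_variances(
    a: float, b: float, n1: int, n0: int
) -> tuple[float, float, float]:
    """Closed-form sampling variances of the plug-in (a_hat, b_hat):

        V(a_hat) = [n1 (a^2 + 2) + 2 n0 b^2] / (2 n0 n1)
        V(b_hat) = (n1 + n0) b^2 / (2 n0 n1)

    plus cov(a_hat, b_hat) = a*b / (2 n1), induced by the shared
    diseased-group scale estimate (both a_hat and b_hat carry sigma1_hat
    in the denominator, and Var(sigma1_hat) ~ sigma1^2 / (2 n1)).
    """
    if n1 < 2 or n0 < 2:
        raise ValueError("variances require at least 2 subjects per group")
    var_a = (n1 * (a * a + 2.0) + 2.0 * n0 * b * b) / (2.0 * n0 * n1)
    var_b = (n1 + n0) * b * b / (2.0 * n0 * n1)
    cov_ab = a * b / (2.0 * n1)
    return var_a, var_b, cov_ab


def binormal_auc_se(
    a: float,
    b: float,
    var_a: float,
    var_b: float,
    cov_ab: float = 0.0,
) -> float:
    """Delta-method standard error of the binormal AUC.

    With u = a / sqrt(1 + b^2) the gradient of AUC = Phi(u) is
    phi(u) * (g_a, g_b) where g_a = 1/sqrt(1+b^2) and
    g_b = -a*b / (1+b^2)^(3/2).
    """
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be nonnegative")
    s = 1.0 + b * b
    g_a = 1.0 / math.sqrt(s)
    g_b = -a * b / s**1.5
    inner = g_a * g_a * var_a + g_b * g_b * var_b + 2.0 * g_a * g_b * cov_ab
    # tiny negative values can arise from an inconsistent covariance input
    inner = max(inner, 0.0)
    return float(abs(norm.pdf(a / math.sqrt(s))) * math.sqrt(inner))


def wald_ci(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval point +/- z * se, deliberately not clipped to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    return float(point - z * se), float(point + z * se)


def fit_binormal(sample: SampleData, ci_level: float = 0.95) -> BinormalEstimate:
    """Fit the binormal model by moment plug-in.

    Group means and standard deviations (denominator n-1) are substituted
    into the (a, b) definitions.  Parameter variances are

        V(a_hat) = [n1 (a_hat^2 + 2) + 2 n0 b_hat^2] / (2 n0 n1)
        V(b_hat) = (n1 + n0) b_hat^2 / (2 n0 n1)

    and the AUC standard error follows by the delta method, including the
    covariance cov(a_hat, b_hat) = a_hat * b_hat / (2 n1) induced by the
    shared diseased-group scale estimate.
    """
    n1, n0 = sample.n1, sample.n0
    if n1 < 2 or n0 < 2:
        raise ValueError("binormal fit requires at least 2 subjects per group")
    mu1 = float(sample.diseased.mean())
    mu0 = float(sample.nondiseased.mean())
    sigma1 = float(sample.diseased.std(ddof=1))
    sigma0 = float(sample.nondiseased.std(ddof=1))
    if sigma1 == 0.0 or sigma0 == 0.0:
        raise ValueError(
            "degenerate group with zero variance: binormal slope b is unidentifiable"
        )
    a_hat = (mu1 - mu0) / sigma1
    b_hat = sigma0 / sigma1
    var_a, var_b, cov_ab = binormal_param_variances(a_hat, b_hat, n1, n0)
    auc = binormal_auc(a_hat, b_hat)
    se_auc = binormal_auc_se(a_hat, b_hat, var_a, var_b, cov_ab)
    ci_low, ci_high = wald_ci(auc, se_auc, ci_level)
    return BinormalEstimate(
        mu1=mu1,
        mu0=mu0,
        sigma1=sigma1,
        sigma0=sigma0,
        a_hat=a_hat,
        b_hat=b_hat,
        var_a=var_a,
        var_b=var_b,
        cov_ab=cov_ab,
        auc=auc,
        se_auc=se_auc,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
    )
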