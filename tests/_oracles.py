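"""Independent brute-force oracles used to validate the package's
estimators.  These deliberately share no code with the implementation:
pairwise double loops for the Mann-Whitney statistics, a literal
transcription of the tie-corrected variance components, and a
from-scratch Newton-Raphson probit maximum-likelihood fit."""

import numpy as np
from scipy.stats import norm


def pairwise_auc_brute(y1, y0) -> float:
    """Mean of the kernel psi(Y1, Y0) = 1, 1/2, 0 over all pairs."""
    total = 0.0
    for yi in y1:
        for yj in y0:
            if yi > yj:
                total += 1.0
            elif yi == yj:
                total += 0.5
    return total / (len(y1) * len(y0))


def auc_variance_brute(y1, y0):
    """Literal transcription of the tie-corrected Mann-Whitney variance.

    Q1 sums, over each distinct nondiseased value y (weighted by its
    multiplicity), (n1>y)^2 + (n1>y)(n1=y) + (n1=y)^2/3, normalized by
    n0*n1^2; Q2 is the symmetric sum over diseased values with the roles
    swapped; the variance combines them with the AUC.
    """
    y1, y0 = list(y1), list(y0)
    n1, n0 = len(y1), len(y0)
    auc = pairwise_auc_brute(y1, y0)
    q1 = 0.0
    for y in sorted(set(y0)):
        n0_eq = sum(1 for v in y0 if v == y)
        n1_gt = sum(1 for v in y1 if v > y)
        n1_eq = sum(1 for v in y1 if v == y)
        q1 += n0_eq * (n1_gt**2 + n1_gt * n1_eq + n1_eq**2 / 3.0)
    q1 /= n0 * n1**2
    q2 = 0.0
    for y in sorted(set(y1)):
        n1_eq = sum(1 for v in y1 if v == y)
        n0_lt = sum(1 for v in y0 if v < y)
        n0_eq = sum(1 for v in y0 if v == y)
        q2 += n1_eq * (n0_lt**2 + n0_lt * n0_eq + n0_eq**2 / 3.0)
    q2 /= n0**2 * n1
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    return q1, q2, var


def q1_triple_loop(y1, y0) -> float:
    """P(two random diseased subjects both exceed one random nondiseased),
    by exhaustive triple loop (tie-free data)."""
    count = 0
    for yi in y1:
        for yk in y1:
            for yj in y0:
                if yi > yj and yk > yj:
                    count += 1
    return count / (len(y1) ** 2 * len(y0))


def probit_ml_newton(y, x, tol=1e-12, max_iter=200):
    """From-scratch Newton-Raphson probit ML on binary rows.

    y is a 0/1 outcome vector, x the (n, p) design matrix.  Maximizes
    sum y*log(Phi(eta)) + (1-y)*log(1-Phi(eta)) using the analytic
    gradient and Hessian.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        p = norm.cdf(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        phi = norm.pdf(eta)
        # gradient of the log-likelihood
        w = phi * (y / p - (1 - y) / (1 - p))
        grad = x.T @ w
        # observed information (negative Hessian)
        lam1 = phi * (phi + eta * p) / p**2
        lam0 = phi * (phi - eta * (1 - p)) / (1 - p) ** 2
        wts = y * lam1 + (1 - y) * lam0
        hess = x.T @ (x * wts[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
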