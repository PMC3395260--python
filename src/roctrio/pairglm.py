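"""Semiparametric ROC estimation via probit binary regression on pairs.

Every diseased/nondiseased pair (i, j) contributes a binary indicator
U_ij = I[Y_i1 >= Y_j0], and each nondiseased subject contributes its
placement false-positive rate t_j = FP(Y_j0) in {1/n0, ..., n0/n0}.
Regressing U on (1, Phi^-1(t)) with a probit link,

    E(U_ij) = Phi(beta1 + beta2 * Phi^-1(t_j)),

recovers smooth ROC parameters (beta1, beta2) analogous to the binormal
(a, b) without any distributional assumption on the raw values, and
AUC = Phi(beta1 / sqrt(1 + beta2^2)).  The n1*n0 indicators share
subjects, so the GLM is fit under working independence and all inference
comes from a subject-level stratified bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .binormal import wald_ci
from .data import SampleData


@dataclass(frozen=True)
class SemiparametricModelSpec:
    """The ROC-GLM model specification: probit link with basis (1, Phi^-1(t))."""

    link: str = "probit"
    n_basis: int = 2

    def __post_init__(self) -> None:
        if self.link != "probit" or self.n_basis != 2:
            raise ValueError("only the probit link with basis (1, probit(t)) is supported")


@dataclass(frozen=True)
class PairedDesign:
    """Pairwise indicator design for the ROC-GLM.

    ``u`` and ``t`` cover all n1*n0 pairs in j-major order; rows whose
    placement value is exactly 1 (the minimal nondiseased value, where
    Phi^-1(t) is infinite) are excluded from the regression.  ``probit_t``
    holds the transformed regressor for the retained rows only.

    The pair-level arrays are expanded on demand from the per-subject
    data; fitting uses the binomial aggregation (``t_levels``,
    ``successes``, ``trials``, one row per distinct retained placement
    value), which has an identical likelihood and keeps the design
    memory-light even for large groups.
    """

    t_j: np.ndarray  # placement value per nondiseased subject
    n_dropped: int
    n1: int
    n0: int
    # binomial aggregation of the retained rows, one row per distinct t
    t_levels: np.ndarray = field(repr=False)
    successes: np.ndarray = field(repr=False)
    trials: np.ndarray = field(repr=False)
    # raw group values, kept for on-demand pair expansion
    diseased: np.ndarray = field(repr=False)
    nondiseased: np.ndarray = field(repr=False)

    @property
    def u(self) -> np.ndarray:
        """All n1*n0 pairwise indicators I[Y_i1 >= Y_j0], j-major."""
        return (self.diseased[None, :] >= self.nondiseased[:, None]).astype(np.uint8).ravel()

    @property
    def t(self) -> np.ndarray:
        """Placement value of each pair's nondiseased member, j-major."""
        return np.repeat(self.t_j, self.n1)

    @property
    def probit_t(self) -> np.ndarray:
        """Phi^-1(t) for the retained (t < 1) rows."""
        return norm.ppf(np.repeat(self.t_j[self.t_j < 1.0], self.n1))


@dataclass(frozen=True)
class SemiparametricEstimate:
    beta1: float
    beta2: float
    auc: float
    se_beta1: float
    se_beta2: float
    se_auc: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    n_failed: int
    converged: bool


def build_pair_design(sample: SampleData) -> PairedDesign:
    """Construct all n1*n0 pairwise indicators and placement values.

    t_j = (#{k : Y_k0 >= Y_j0}) / n0, so the minimal nondiseased value(s)
    attain t = 1 and are dropped from the regression (n1 rows per such
    subject).
    """
    y1, y0 = sample.diseased, sample.nondiseased
    n1, n0 = sample.n1, sample.n0
    y0s = np.sort(y0)
    t_j = (n0 - np.searchsorted(y0s, y0, side="left")) / n0
    keep_j = t_j < 1.0
    if not np.any(keep_j):
        raise ValueError("no usable design rows: every nondiseased value is minimal")
    n_dropped = int(n1 * np.count_nonzero(~keep_j))
    y1s = np.sort(y1)
    # successes among diseased for each retained nondiseased subject
    succ_j = n1 - np.searchsorted(y1s, y0[keep_j], side="left")
    t_levels, inv = np.unique(t_j[keep_j], return_inverse=True)
    successes = np.bincount(inv, weights=succ_j).astype(float)
    trials = np.bincount(inv).astype(float) * n1
    return PairedDesign(
        t_j=t_j,
        n_dropped=n_dropped,
        n1=n1,
        n0=n0,
        t_levels=t_levels,
        successes=successes,
        trials=trials,
        diseased=y1,
        nondiseased=y0,
    )


def fit_semiparametric(
    design: PairedDesign,
    spec: SemiparametricModelSpec | None = None,
) -> tuple[float, float, bool]:
    """Probit ML fit of the pairwise indicators on (1, Phi^-1(t)).

    Fit by IRLS on the binomially aggregated design (convergence tolerance
    1e-12 on the deviance — well below 1e-8 on the coefficients — and at
    most 100 iterations).  Returns
    ``(beta1, beta2, converged)``; a separated or otherwise non-converged
    fit returns the last iterate with ``converged=False``.
    """
    if spec is None:
        spec = SemiparametricModelSpec()
    if design.t_levels.size < 2:
        raise ValueError("need at least 2 distinct placement values to fit the ROC-GLM")
    exog = np.column_stack([np.ones_like(design.t_levels), norm.ppf(design.t_levels)])
    endog = np.column_stack([design.successes, design.trials - design.successes])
    model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-12)
    beta1, beta2 = (float(v) for v in res.params)
    separated = design.successes.sum() in (0.0, design.trials.sum())
    converged = bool(res.converged) and np.isfinite([beta1, beta2]).all() and not separated
    return beta1, beta2, converged


def semiparametric_auc(beta1: float, beta2: float) -> float:
    """AUC implied by the ROC-GLM coefficients: Phi(beta1 / sqrt(1 + beta2^2)).

    A negative beta2 signals a degenerate fit; it is passed through
    unchanged rather than rejected.
    """
    return float(norm.cdf(beta1 / math.sqrt(1.0 + beta2 * beta2)))


def bootstrap_semiparametric(
    sample: SampleData,
    n_boot: int = 200,
    seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> SemiparametricEstimate:
    """ROC-GLM point estimate with stratified-bootstrap standard errors.

    Subjects are resampled with replacement within each disease group
    (preserving n1 and n0), the pair design is rebuilt and refit per
    resample, and the standard errors are the sample SDs of the bootstrap
    replicates.  The interval is Wald around the original-sample point
    estimate.  Non-convergent resamples are dropped; more than 10% of them
    is an error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    point = fit_semiparametric(build_pair_design(sample))
    beta1, beta2, converged = point
    auc = semiparametric_auc(beta1, beta2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    n_failed = 0
    for _ in range(n_boot):
        idx1 = rng.integers(0, sample.n1, sample.n1)
        idx0 = rng.integers(0, sample.n0, sample.n0)
        resample = SampleData(sample.diseased[idx1], sample.nondiseased[idx0])
        try:
            b1, b2, ok = fit_semiparametric(build_pair_design(resample))
        except ValueError:
            ok = False
        if not ok:
            n_failed += 1
            continue
        reps.append((b1, b2, semiparametric_auc(b1, b2)))
    if n_failed > 0.1 * n_boot:
        raise ValueError(
            f"{n_failed}/{n_boot} bootstrap resamples failed to converge (>10%)"
        )
    reps_arr = np.array(reps)
    se_beta1, se_beta2, se_auc = reps_arr.std(axis=0, ddof=1)
    ci_low, ci_high = wald_ci(auc, float(se_auc), ci_level)
    return SemiparametricEstimate(
        beta1=beta1,
        beta2=beta2,
        auc=auc,
        se_beta1=float(se_beta1),
        se_beta2=float(se_beta2),
        se_auc=float(se_auc),
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        n_boot=n_boot,
        n_failed=n_failed,
        converged=converged,
    )
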