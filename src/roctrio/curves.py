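"""ROC curve container and smooth-curve evaluation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve as ordered (FPR, TPR) coordinates.

    ``thresholds`` is the descending sequence of cutoffs that produced the
    points (``+inf`` for the (0, 0) anchor, ``nan`` for grid points of a
    smooth curve).  Points are sorted so ``fpr`` and ``tpr`` are
    nondecreasing, and the curve always carries explicit (0, 0) and (1, 1)
    anchors so trapezoidal integration needs no special cases.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if not (len(thr) == len(fpr) == len(tpr)):
            raise ValueError("thresholds, fpr and tpr must have equal length")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("fpr and tpr must be nondecreasing")
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    def trapezoidal_area(self) -> float:
        """Area under the curve by the trapezoidal rule."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def to_tsv(self) -> str:
        """Serialize as a 3-column TSV (threshold, fpr, tpr) with header."""
        lines = ["threshold\tfpr\ttpr"]
        for c, x, y in zip(self.thresholds, self.fpr, self.tpr):
            lines.append(f"{c:.12g}\t{x:.12g}\t{y:.12g}")
        return "\n".join(lines) + "\n"


def default_t_grid(step: float = 0.001) -> np.ndarray:
    """Interior FPR grid used for exporting smooth curves (0.001 ... 0.999)."""
    n = int(round(1.0 / step)) - 1
    return np.linspace(step, 1.0 - step, n)


def smooth_roc(a: float, b: float, t: np.ndarray | None = None) -> RocCurve:
    """Smooth ROC curve ROC(t) = Phi(a + b * Phi^-1(t)) on an interior grid.

    Used for both the binormal fit (a_hat, b_hat) and the semiparametric
    probit-GLM fit (beta1, beta2), which share this functional form.
    """
    if t is None:
        t = default_t_grid()
    t = np.asarray(t, dtype=float)
    roc = norm.cdf(a + b * norm.ppf(t))
    fpr = np.concatenate([[0.0], t, [1.0]])
    tpr = np.concatenate([[0.0], roc, [1.0]])
    thr = np.full(fpr.shape, np.nan)
    thr[0] = np.inf
    return RocCurve(thr, fpr, tpr)
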