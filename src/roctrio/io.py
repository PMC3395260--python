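"""Reading labeled datasets, descriptive statistics, the three-method
report, and the synthetic skewed-biomarker fixture generator."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binormal import fit_binormal
from .curves import RocCurve, default_t_grid, smooth_roc
from .data import LabeledDataset
from .empirical import fit_empirical
from .pairglm import bootstrap_semiparametric

logger = logging.getLogger(__name__)

# Defaults for the synthetic skewed-biomarker fixture: lognormal groups
# whose medians approximate a strongly right-skewed cardiac-biomarker
# setting (diseased median ~104, nondiseased ~34, mean well above median
# in both groups).
FIXTURE_DEFAULTS = dict(
    log_mean1=math.log(104.0),
    log_sd1=1.0,
    log_mean0=math.log(33.95),
    log_sd0=0.9,
)


def read_labeled_csv(
    path,
    value_column: str,
    status_column: str,
    positive_label: str,
) -> LabeledDataset:
    """Read a delimited text file (comma or tab, autodetected, header
    required) into a :class:`LabeledDataset`.

    Rows with a missing value or status are dropped with a logged count.
    The status column must contain exactly two levels, one of which is
    ``positive_label``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (value_column, status_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    values = pd.to_numeric(df[value_column], errors="coerce")
    status_raw = df[status_column].astype("string").str.strip()
    keep = values.notna() & status_raw.notna() & (status_raw != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing value or status", n_dropped)
    values, status_raw = values[keep], status_raw[keep]
    levels = sorted(status_raw.unique())
    if positive_label not in levels:
        raise ValueError(
            f"positive label {positive_label!r} not present; levels found: {levels}"
        )
    if len(levels) == 1:
        raise ValueError(f"only one status level present: {levels[0]!r}")
    if len(levels) > 2:
        unknown = [lv for lv in levels if lv != positive_label]
        raise ValueError(f"unknown status level(s): {unknown}")
    negative_label = next(lv for lv in levels if lv != positive_label)
    return LabeledDataset(
        values=values.to_numpy(float),
        status=(status_raw == positive_label).to_numpy(),
        positive_label=positive_label,
        negative_label=negative_label,
    )


def write_labeled_csv(data: LabeledDataset, path) -> None:
    """Write a LabeledDataset as a 2-column CSV (value, status).

    Values are formatted with 12 significant digits so a written file
    reads back value-for-value identical at that precision.
    """
    with open(path, "w") as fh:
        fh.write("value,status\n")
        for v, s in zip(data.values, data.status):
            label = data.positive_label if s else data.negative_label
            fh.write(f"{v:.12g},{label}\n")


def describe_groups(data: LabeledDataset) -> pd.DataFrame:
    """Per-group descriptive statistics: n, mean, SD (n-1), median
    (midpoint convention), min, max."""
    rows = []
    for label, vals in (
        (data.positive_label, data.values[data.status]),
        (data.negative_label, data.values[~data.status]),
    ):
        rows.append(
            {
                "group": label,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else math.nan,
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def make_skewed_fixture(
    n1: int = 62,
    n0: int = 20,
    log_mean1: float = FIXTURE_DEFAULTS["log_mean1"],
    log_sd1: float = FIXTURE_DEFAULTS["log_sd1"],
    log_mean0: float = FIXTURE_DEFAULTS["log_mean0"],
    log_sd0: float = FIXTURE_DEFAULTS["log_sd0"],
    seed: int | None = 0,
) -> LabeledDataset:
    """Synthetic right-skewed biomarker dataset (lognormal per group).

    A stand-in for a real skewed clinical biomarker sample; group
    location/spread are configurable on the log scale.
    """
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    y1 = np.exp(rng.normal(log_mean1, log_sd1, n1))
    y0 = np.exp(rng.normal(log_mean0, log_sd0, n0))
    return LabeledDataset(
        values=np.concatenate([y1, y0]),
        status=np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)]),
        positive_label="diseased",
        negative_label="nondiseased",
    )


@dataclass(frozen=True)
class MethodReport:
    """Three-method analysis of one labeled dataset.

    ``rows`` maps method tag (P/S/N) to a flat dict of estimates;
    ``curves`` maps method tag to its ROC curve (step curve for N, smooth
    probit-form curves for P and S on an interior t grid).
    """

    n1: int
    n0: int
    positive_label: str
    negative_label: str
    descriptives: pd.DataFrame
    rows: dict[str, dict[str, float]]
    curves: dict[str, RocCurve]
    ci_level: float
    n_boot: int
    seed: int | None

    def to_json_dict(self) -> dict:
        return {
            "n1": self.n1,
            "n0": self.n0,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "descriptives": self.descriptives.reset_index().to_dict(orient="records"),
            "methods": self.rows,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), indent=2, **kwargs)

    def to_markdown(self) -> str:
        def fmt(x):
            return "—" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.3f}"

        lines = [
            f"# ROC report ({self.positive_label} vs {self.negative_label}, "
            f"n1:n0 = {self.n1} : {self.n0})",
            "",
            "## Descriptive statistics",
            "",
            "| group | n | mean | SD | median | min | max |",
            "|---|---|---|---|---|---|---|",
        ]
        for group, r in self.descriptives.iterrows():
            lines.append(
                f"| {group} | {int(r['n'])} | {r['mean']:.2f} | {r['sd']:.2f} "
                f"| {r['median']:.2f} | {r['min']:.2f} | {r['max']:.2f} |"
            )
        pct = f"{self.ci_level:.0%}"
        lines += [
            "",
            "## ROC estimates",
            "",
            f"| method | â/β̂₁ | SE | b̂/β̂₂ | SE | AUC | SE(AUC) | {pct} CI |",
            "|---|---|---|---|---|---|---|---|",
        ]
        names = {"P": "Parametric", "S": "Semiparametric", "N": "Nonparametric"}
        for tag in ("P", "S", "N"):
            r = self.rows[tag]
            ci = (
                "—"
                if math.isnan(r["ci_low"])
                else f"{r['ci_low']:.3f}–{r['ci_high']:.3f}"
            )
            lines.append(
                f"| {names[tag]} | {fmt(r['a'])} | {fmt(r['se_a'])} | {fmt(r['b'])} "
                f"| {fmt(r['se_b'])} | {fmt(r['auc'])} | {fmt(r['se_auc'])} | {ci} |"
            )
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        """Write report.md, report.json and per-method curve TSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(self.to_markdown())
        (out / "report.json").write_text(self.to_json())
        for tag, curve in self.curves.items():
            (out / f"roc_curve_{tag}.tsv").write_text(curve.to_tsv())


def run_report(
    data: LabeledDataset,
    n_boot: int = 200,
    seed: int | None = 0,
    ci_level: float = 0.95,
    t_grid: np.ndarray | None = None,
) -> MethodReport:
    """Apply the parametric, semiparametric and nonparametric estimators
    to a labeled dataset and assemble a report with ROC coordinates."""
    sample = data.to_sample()
    if t_grid is None:
        t_grid = default_t_grid()
    rows: dict[str, dict[str, float]] = {}
    curves: dict[str, RocCurve] = {}
    try:
        p = fit_binormal(sample, ci_level)
    except ValueError as err:
        raise ValueError(f"parametric (P) estimator failed: {err}") from err
    rows["P"] = dict(
        a=p.a_hat, se_a=math.sqrt(p.var_a), b=p.b_hat, se_b=math.sqrt(p.var_b),
        auc=p.auc, se_auc=p.se_auc, ci_low=p.ci_low, ci_high=p.ci_high,
    )
    curves["P"] = smooth_roc(p.a_hat, p.b_hat, t_grid)
    try:
        s = bootstrap_semiparametric(sample, n_boot, seed, ci_level)
    except ValueError as err:
        raise ValueError(f"semiparametric (S) estimator failed: {err}") from err
    rows["S"] = dict(
        a=s.beta1, se_a=s.se_beta1, b=s.beta2, se_b=s.se_beta2,
        auc=s.auc, se_auc=s.se_auc, ci_low=s.ci_low, ci_high=s.ci_high,
    )
    curves["S"] = smooth_roc(s.beta1, s.beta2, t_grid)
    try:
        e = fit_empirical(sample, ci_level)
    except ValueError as err:
        raise ValueError(f"nonparametric (N) estimator failed: {err}") from err
    rows["N"] = dict(
        a=math.nan, se_a=math.nan, b=math.nan, se_b=math.nan,
        auc=e.auc, se_auc=e.se_auc, ci_low=e.ci_low, ci_high=e.ci_high,
    )
    curves["N"] = e.curve
    return MethodReport(
        n1=sample.n1,
        n0=sample.n0,
        positive_label=data.positive_label,
        negative_label=data.negative_label,
        descriptives=describe_groups(data),
        rows=rows,
        curves=curves,
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
    )


def estimate_to_json(estimate) -> str:
    """Flat key-value JSON export for any estimate dataclass."""
    from dataclasses import asdict, is_dataclass

    if not is_dataclass(estimate):
        raise TypeError("expected an estimate dataclass")
    flat = {
        k: v
        for k, v in asdict(estimate).items()
        if isinstance(v, (int, float, str, bool))
    }
    return json.dumps(flat, indent=2)
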