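# roctrio

Parametric, nonparametric and semiparametric ROC analysis for continuous
diagnostic tests, with a Monte-Carlo engine for benchmarking the three
estimators against each other.

## The problem

A continuous diagnostic test (a serum biomarker, say) is measured in a
diseased group Y₁ and a nondiseased group Y₀. Calling a subject positive
when Y ≥ c traces out, over all cutoffs c, the ROC curve — true-positive
rate against false-positive rate — whose area (AUC) equals
P(Y₁ > Y₀), the probability that a random diseased subject out-scores a
random nondiseased one. Three estimation strategies coexist, and they can
disagree badly on skewed data:

- **Parametric (binormal).** Assume Y₁ ~ N(μ₁, σ₁²), Y₀ ~ N(μ₀, σ₀²).
  Then ROC(t) = Φ(a + b Φ⁻¹(t)) with a = (μ₁−μ₀)/σ₁, b = σ₀/σ₁, and
  AUC = Φ(a/√(1+b²)). Estimated by moment plug-in; parameter variances
  have closed forms and the AUC standard error follows by the delta
  method. Smooth curve, but wrong when normality fails.
- **Nonparametric (empirical).** The step curve through every observed
  cutoff; its area is the Mann–Whitney statistic with ties scored ½, and
  its variance uses the tie-corrected exceedance components Q₁, Q₂.
  Assumption-free and rank-invariant, but jagged.
- **Semiparametric (ROC-GLM).** For every diseased/nondiseased pair form
  the indicator U_ij = I[Y_i1 ≥ Y_j0] and the nondiseased subject's
  placement value t_j = FP(Y_j0); probit regression
  E(U) = Φ(β₁ + β₂ Φ⁻¹(t)) recovers smooth-ROC parameters (β₁, β₂) —
  analogues of (a, b) — with no distributional assumption on the raw
  values, and AUC = Φ(β₁/√(1+β₂²)). The pairs share subjects, so the GLM
  is fit under working independence and all inference comes from a
  stratified subject-level bootstrap.

The package implements all three, plus the simulation study that compares
their bias, SEs, RMSE and confidence intervals under normal, lognormal
(skewed) and uniform (monotone) data, and a CLI for applying all three to
a user dataset.

## Worked example

```python
import numpy as np
from roctrio import SampleData, fit_binormal, fit_empirical, bootstrap_semiparametric

rng = np.random.default_rng(0)
# right-skewed data: lognormal groups, 62 diseased vs 20 nondiseased
sample = SampleData(np.exp(rng.normal(1.56, 1.11, 62)),
                    np.exp(rng.normal(0.00, 1.00, 20)))

p = fit_binormal(sample)
e = fit_empirical(sample)
s = bootstrap_semiparametric(sample, n_boot=200, seed=0)
print(f"parametric     AUC {p.auc:.3f} (SE {p.se_auc:.3f})")
print(f"semiparametric AUC {s.auc:.3f} (SE {s.se_auc:.3f})")
print(f"empirical      AUC {e.auc:.3f} (SE {e.se_auc:.3f})")
```

prints

```
parametric     AUC 0.744 (SE 0.078)
semiparametric AUC 0.783 (SE 0.067)
empirical      AUC 0.805 (SE 0.056)
```

The binormal AUC sits well below the two distribution-free estimates:
the lognormal skew violates its normality assumption, while the empirical
and ROC-GLM estimators see only ranks and placement values. On normal
data the three agree closely (the simulation tables quantify this).

The same analysis runs from the shell on a delimited file with a value
column and a status column:

```sh
roc fixture --n1 62 --n0 20 --seed 1 --out marker.csv
roc report --input marker.csv --value-col value --status-col status \
    --positive-label diseased --out report/
roc simulate --config study.cfg --out results/
```

## Analysis drivers

- `analysis/01_simulation_tables.py` — the full benchmark: three
  families × four sample sizes, one table per family plus a JSON summary
  under `results/`.
- `analysis/02_biomarker_report.py` — the application: the three methods
  on a synthetic right-skewed biomarker dataset (62:20), with ROC
  coordinates for plotting under `results/application/`.

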