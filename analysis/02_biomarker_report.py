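#!/usr/bin/env python
"""Three-method ROC analysis of a skewed biomarker dataset.

The motivating application is a right-skewed serum biomarker measured in
62 diseased and 20 nondiseased subjects; the original clinical data are
not distributable, so this driver analyzes the package's synthetic
lognormal stand-in with matching group sizes and medians.  It writes the
dataset, a Table-style report (descriptives + the three fits) and the
three ROC curves' coordinates to results/application/.

Expected pattern on skewed data: the binormal AUC falls below both the
semiparametric ROC-GLM and the empirical AUC, because the normality
assumption is violated on the raw scale while the other two estimators
see only ranks/placements.
"""

import argparse
from pathlib import Path

from roctrio import make_skewed_fixture, run_report, write_labeled_csv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n1", type=int, default=62)
    parser.add_argument("--n0", type=int, default=20)
    parser.add_argument("--n-boot", type=int, default=200)
    parser.add_argument("--seed", type=int, default=20120628)
    parser.add_argument("--out", type=Path, default=Path("results/application"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    data = make_skewed_fixture(n1=args.n1, n0=args.n0, seed=args.seed)
    write_labeled_csv(data, args.out / "synthetic_biomarker.csv")
    report = run_report(data, n_boot=args.n_boot, seed=args.seed)
    report.write(args.out)
    print(report.to_markdown())

    p, s, n = (report.rows[m]["auc"] for m in ("P", "S", "N"))
    if p < min(s, n):
        print(f"As expected under skew, the binormal AUC ({p:.3f}) falls below "
              f"the semiparametric ({s:.3f}) and empirical ({n:.3f}) estimates.")
    else:
        print(f"Note: the binormal AUC ({p:.3f}) did NOT fall below the other "
              f"two ({s:.3f}, {n:.3f}) for this seed.")
    print(f"wrote dataset, report and ROC coordinates to {args.out}/")


if __name__ == "__main__":
    main()
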