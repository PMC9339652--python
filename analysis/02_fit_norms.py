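#!/usr/bin/env python
"""Fit 12-month change norms on the simulated reference cohort.

Regresses each test's 12-month score on its baseline score (timed tests on
the -log10 seconds scale) and writes the fitted norm table next to the
published one for comparison. The fitted slopes should sit well inside
(0, 1): practice effects raise the intercept while measurement error and
regression to the mean attenuate the slope.
"""
import argparse
from pathlib import Path

from npdecline.io import read_cohort
from npdecline.model import TestId
from npdecline.norms import fit_norm_table, published_norms, write_norm_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/reference_cohort.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.cohort)
    fitted = fit_norm_table(cohort, label=f"fitted on {args.cohort}")
    fitted_path = write_norm_table(fitted, args.out_dir / "fitted_norms.txt")
    published_path = write_norm_table(
        published_norms(), args.out_dir / "published_norms.txt"
    )

    print(f"{'test':<18} {'intercept':>10} {'slope':>7} {'see':>8}   (fitted, n={len(cohort)})")
    for t in TestId:
        eq = fitted[t]
        print(f"{t.value:<18} {eq.intercept:>10.4f} {eq.slope:>7.4f} {eq.see:>8.4f}")
    print(f"fitted table -> {fitted_path}; published table -> {published_path}")


if __name__ == "__main__":
    main()
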