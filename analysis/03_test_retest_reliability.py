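#!/usr/bin/env python
"""Test-retest reliability of each sway metric across the three trials.

For every (device, metric, condition, direction) cell, estimates the
single-measure consistency ICC from a two-way mixed-effects ANOVA (subjects
random, trials fixed) with its 95% F-pivot CI and the standard classification
bands (poor < 0.5 <= moderate < 0.75 <= good <= 0.90 < excellent).  Writes
results/reliability.csv and prints the table in the condition x direction by
device x metric layout.
"""

import argparse
from pathlib import Path

import pandas as pd

from swayval import reliability_table
from swayval.pipeline import _icc_report_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--metrics", type=Path, default=ROOT / "results" / "metrics.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "reliability.csv")
    parser.add_argument("--form", choices=["single", "average"], default="single")
    args = parser.parse_args()

    rel = reliability_table(pd.read_csv(args.metrics), form=args.form)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    rel.to_csv(args.out, index=False, float_format="%.10g")
    print(f"wrote {len(rel)} ICC cells to {args.out}\n")
    print(_icc_report_table(rel).to_markdown())
    print("\nclassification counts:", rel.classification.value_counts().to_dict())


if __name__ == "__main__":
    main()
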