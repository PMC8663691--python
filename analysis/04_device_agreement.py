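#!/usr/bin/env python
"""Between-device agreement: COP metrics regressed on headset metrics.

For each metric x condition x direction cell, and for both first-trial values
and 3-trial averages, fits COP ~ headset by OLS and reports R^2 with the
regression F-test significance tier.  Writes results/agreement.csv and prints
the metric x aggregation by condition x direction layout.  On the default
cohort the NPL rows sit far below the RMS and P2P rows: the headset tracks
sway amplitude but not path length.
"""

import argparse
from pathlib import Path

import pandas as pd

from swayval import agreement_table
from swayval.pipeline import _agreement_report_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--metrics", type=Path, default=ROOT / "results" / "metrics.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "agreement.csv")
    args = parser.parse_args()

    agr = agreement_table(pd.read_csv(args.metrics))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    agr.to_csv(args.out, index=False, float_format="%.10g")
    print(f"wrote {len(agr)} regression cells to {args.out}\n")
    print(_agreement_report_table(agr).to_markdown())
    print("\nmean R^2 by metric:", agr.groupby("metric").r2.mean().round(3).to_dict())


if __name__ == "__main__":
    main()
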