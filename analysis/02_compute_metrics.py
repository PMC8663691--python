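#!/usr/bin/env python
"""Compute NPL, RMS, and P2P for every trace of the stored cohort.

Each trace is analyzed at its native rate (COP at 200 Hz, headset at 10 Hz).
Writes results/metrics.csv and prints per-device condition means, which show
the two signatures the downstream analyses rest on: eyes-closed sway exceeds
eyes-open, and the force plate accumulates far more path length (NPL) than the
10 Hz headset while the amplitude measures are comparable.
"""

import argparse
from pathlib import Path

from swayval import load_cohort
from swayval.sway_metrics import metrics_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "metrics.csv")
    args = parser.parse_args()

    manifest = load_cohort(args.cohort / "manifest.csv")
    metrics = metrics_table(manifest)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(args.out, index=False, float_format="%.10g")
    print(f"wrote {len(metrics)} rows to {args.out}\n")
    print(
        metrics.groupby(["device", "condition"])[["npl_cm_per_s", "rms_cm", "p2p_cm"]]
        .mean()
        .round(3)
    )


if __name__ == "__main__":
    main()
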