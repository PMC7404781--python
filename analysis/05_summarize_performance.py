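#!/usr/bin/env python
"""Collect the per-run metrics into one performance table.

Reads the metrics written by 03/04 and produces
results/performance_summary.csv with one row per classifier, preset and
validation set — the synthetic analogue of a final results table.
"""

import sys
from pathlib import Path

import pandas as pd


def main() -> int:
    rows = []
    for run_dir in sorted(Path("results").glob("*_*")):
        metrics = run_dir / "metrics.csv"
        if not metrics.exists():
            continue
        classifier, preset = run_dir.name.rsplit("_", 1)
        df = pd.read_csv(metrics)
        df.insert(0, "classifier", classifier)
        df.insert(1, "preset", preset)
        rows.append(df)
    if not rows:
        print("no run metrics found; run 03/04 first", file=sys.stderr)
        return 1
    summary = pd.concat(rows, ignore_index=True)
    summary.to_csv(Path("results") / "performance_summary.csv", index=False)
    print(summary.to_string(index=False))
    by = summary.groupby(["classifier", "preset"])["accuracy_pct"]
    print("\naccuracy range per run:")
    print(by.agg(["min", "max"]).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
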