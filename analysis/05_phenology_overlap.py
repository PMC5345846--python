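#!/usr/bin/env python
"""Overlay pest activity windows on the protection windows.

Accumulates degree-days from the weather series to place the seedcorn maggot
larval window, takes the preset activity windows for western corn rootworm
(onset from field scouting), white grub, and wireworm, and computes for each
protection window the days of covered pest activity and the unprotected
tail.  Writes results/phenology.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nstwindow.report import phenology_table
from nstwindow.trial_io import read_weather

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--windows", type=Path, default=ROOT / "windows.csv")
    ap.add_argument("--weather", type=Path, default=ROOT / "data" / "weather.csv")
    args = ap.parse_args()

    windows = pd.read_csv(args.windows)
    weather = read_weather(args.weather)
    table = phenology_table(windows, weather)
    table.to_csv(ROOT / "phenology.csv", index=False)

    print(f"phenology overlaps -> {ROOT / 'phenology.csv'}")
    root = table[(table.region == "root")
                 & (table.method == "contrast_convergence")]
    for r in root.itertuples():
        print(f"  {r.treatment:>5} root protection to {r.protection_end_dpp:.0f} DPP"
              f" vs {r.pest} [{r.activity_start:.0f}, {r.activity_end:.0f}]:"
              f" {r.overlap_days:.0f} d covered, {r.unprotected_days:.0f} d exposed")


if __name__ == "__main__":
    main()
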