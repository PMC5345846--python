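#!/usr/bin/env python
"""Economic-injury-level scenarios and leaching-risk scores.

Calibrates the value x yield-loss product V*b from the published anchor
(EIL 0.245 node-injury at $17.5/ha control cost, V = $14.96/100 kg, K = 1),
evaluates the EIL over the control-cost range at 2014-15 and 2012 commodity
values, inverts the observed (simulated) mean root ratings to break-even
control costs, estimates the efficacy coefficient K from untreated vs
treated damage, and computes GUS leaching scores for clothianidin and
thiamethoxam.  Writes results/economics.csv.
"""

import argparse
from pathlib import Path

from nstwindow.report import economics_table
from nstwindow.trial_io import read_ratings

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--ratings", type=Path, default=ROOT / "data" / "ratings.csv")
    args = ap.parse_args()

    ratings = read_ratings(args.ratings)
    table = economics_table(ratings)
    table.to_csv(ROOT / "economics.csv", index=False)
    print(f"economics scenarios -> {ROOT / 'economics.csv'}")

    eil = table[table.kind == "eil"]
    lo = eil[(eil.control_cost == 17.5) & (eil.commodity_value == 14.96)]
    hi = eil[(eil.control_cost == 55.0) & (eil.commodity_value == 14.96)]
    print(f"  EIL range at $14.96/100 kg: {lo.value.item():.3f}-"
          f"{hi.value.item():.3f} node-injury over $17.5-55/ha")
    be = table[table.kind == "break_even"]
    for r in be[be.commodity_value == 14.96].itertuples():
        print(f"  break-even cost {r.year} {r.treatment:>9}: ${r.value:.1f}/ha")
    for r in table[table.kind == "efficacy"].itertuples():
        print(f"  {r.year} {r.treatment:>5} {r.quantity}: {r.value:.3f}")
    for r in table[table.kind == "gus"].itertuples():
        print(f"  GUS {r.treatment}: {r.value:.2f} ({r.quantity.removeprefix('gus_')})")


if __name__ == "__main__":
    main()
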