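#!/usr/bin/env python
"""Resolve receipts into meals and apply the trial's exclusion cascade.

Writes results/meals.csv (all assembled meals), results/meals_filtered.csv
(the analysis set) and results/ledger.txt (the flow-chart accounting), and
prints the ledger.
"""

import argparse
from pathlib import Path

from nutriscore_catering import exclusion_filters as xf, io, meal_assembly as ma

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

receipts = io.read_receipts(args.data / "receipts.csv")
offers = io.read_offers(args.data / "offers.csv")
compositions = io.read_compositions(args.data / "compositions.csv")

meals = ma.assemble_meals(receipts, offers, compositions)
io.write_table(meals, args.out / "meals.csv")

kept, ledger = xf.apply_all(meals)
io.write_table(kept, args.out / "meals_filtered.csv")
(args.out / "ledger.txt").write_text(ledger.as_text() + "\n")

print(ledger.as_text())
print(f"\nanalysis set: {len(kept)} meals -> {args.out / 'meals_filtered.csv'}")
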