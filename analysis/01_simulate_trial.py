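#!/usr/bin/env python
"""Generate the synthetic two-site trial at full study scale.

Writes compositions.csv, offers.csv and receipts.csv under results/data/.
The defaults mirror the motivating trial's conditions: 1268 + 795
participants, 62 Mon-Fri service days from 2019-12-16, label switch at the
start of week 8, ~11% undetailed fixed-price-menu receipts.
"""

import argparse
from pathlib import Path

from nutriscore_catering import io, synthetic_data as sd

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = sd.SimulationConfig(seed=args.seed)
offers, compositions = sd.generate_offers(cfg)
receipts = sd.simulate_receipts(cfg, offers, compositions)

io.write_table(compositions, args.out / "compositions.csv")
io.write_table(offers, args.out / "offers.csv")
io.write_table(receipts, args.out / "receipts.csv")

n_meals = receipts.groupby(["badge_id", "site", "date"]).ngroups
print(f"simulated {len(compositions)} items, "
      f"{offers.groupby('date').ngroups} service days, "
      f"{len(receipts)} receipt lines forming {n_meals} meals "
      f"-> {args.out}")
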