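#!/usr/bin/env python
"""Site-level and site x period descriptive tables of the analysis set.

Writes results/table_sites.csv and results/table_outcomes.csv (mean +/- SD
of each outcome with participants aggregated before averaging, so N counts
participants, not meals).
"""

import argparse
from pathlib import Path

from nutriscore_catering import inference as inf, io, meal_assembly as ma
from nutriscore_catering.synthetic_data import SimulationConfig

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = SimulationConfig()
kept = io.read_meals(args.out / "meals_filtered.csv")
offers = io.read_offers(args.data / "offers.csv")
compositions = io.read_compositions(args.data / "compositions.csv")

quality = ma.offer_quality_by_day(offers, compositions)
panel = inf.build_panel(kept, switch_day=cfg.switch_day,
                        offer_quality=quality, start_date=cfg.start_date)
io.write_table(panel, args.out / "panel.csv")

tables = inf.descriptives(panel)
tables["sites"].to_csv(args.out / "table_sites.csv")
tables["outcomes"].to_csv(args.out / "table_outcomes.csv")

print("per-site summary:")
print(tables["sites"].round(2).to_string())
print("\nmeal score by site x period (participant-level mean +/- SD):")
cols = ["n_participants", "meal_fsam_mean", "meal_fsam_sd",
        "energy_kcal_mean", "energy_kcal_sd"]
print(tables["outcomes"][cols].round(2).to_string())
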