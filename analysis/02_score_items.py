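#!/usr/bin/env python
"""Score every item on offer with the FSAm-NPS and grade it A-E.

Reads results/data/compositions.csv, writes results/items_scored.csv and
prints the letter distribution -- a sanity check that the synthetic offer
spans the full quality range the way a real cafeteria counter does.
"""

import argparse
from pathlib import Path

from nutriscore_catering import io, nutrient_profile as npf

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

compositions = io.read_compositions(args.data / "compositions.csv")
scored = npf.score_table(compositions)
io.write_table(scored, args.out / "items_scored.csv")

print(f"scored {len(scored)} items; score range "
      f"[{scored['score'].min()}, {scored['score'].max()}]")
print("letter distribution:")
print(scored["letter"].value_counts().sort_index().to_string())
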