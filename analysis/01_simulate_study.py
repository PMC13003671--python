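#!/usr/bin/env python
"""Generate the baseline synthetic study.

Draws a full citizen-science season — 22 gardens, ~150 study plants,
event-level flowering and fruiting, per-type gardener visit schedules,
both harvest-reporting conventions, comments and data-entry errors — and
writes the observation sheets, the garden covariate table and the ground
truth under results/data/.
"""

import argparse
from pathlib import Path

from gardenset import simulate
from gardenset.sheets import write_garden_table, write_observation_sheets

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()

config = simulate.SimulationConfig(n_gardens=22, plants_per_garden=7, seed=args.seed)
study = simulate.simulate_study(config)

args.outdir.mkdir(parents=True, exist_ok=True)
write_observation_sheets(study.sheets, args.outdir / "sheets.csv")
write_garden_table(study.gardens, args.outdir / "gardens.csv")
simulate.truth_to_csv(study.truth, args.outdir / "truth.csv")

n_corrupt = len(study.corruption_log)
print(f"simulated {len(study.sheets)} observation series in {len(study.gardens)} gardens")
print(f"injected {n_corrupt} data-entry corruptions: "
      f"{sorted(set(study.corruption_log.values()))}")
print(f"wrote sheets.csv, gardens.csv, truth.csv under {args.outdir}")
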