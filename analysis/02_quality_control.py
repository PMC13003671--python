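#!/usr/bin/env python
"""Quality control and fruit-set reconstruction.

Reads the observation sheets, applies the five sequential quality criteria
(listed crop, >=3 measurements, no initial fruit, plausibility, garden
replication), reconstructs per-plant fruit set for the passing series, and
writes the exclusion ledger plus the per-plant results.
"""

import argparse
from pathlib import Path

from gardenset import fruitset as fs
from gardenset.sheets import read_observation_sheets, write_results

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

read = read_observation_sheets(args.data / "sheets.csv")
reports = fs.apply_quality_criteria(read.series)
fruit = fs.fruit_set_table(read.series, reports)
exclusions = fs.exclusion_table(reports)

write_results({"qc_exclusions": exclusions, "fruit_set": fruit}, args.outdir)

n_pass = sum(r.passed for r in reports)
print(f"{len(read.series)} series read; {n_pass} passed all five criteria")
print(exclusions.to_string(index=False))
for group, sub in fruit.groupby("plant_group"):
    print(
        f"{group}: n={len(sub)}, fruit set "
        f"{sub['fruit_set_pct'].mean():.1f}% (+/- {sub['fruit_set_pct'].std():.1f} SD), "
        f"range {sub['fruit_set_pct'].min():.1f}-{sub['fruit_set_pct'].max():.1f}%"
    )
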