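#!/usr/bin/env python
"""Participation typology, long breaks and comment coding.

Classifies every contribution by duration (>= 56 days is long) and
measurement frequency (<= 4 days per measurement is high), flags breaks of
more than ten days, codes the free-text comments into challenge
categories, and writes the per-type summary plus one type-by-comment
contingency table per category.
"""

import argparse
from pathlib import Path

from gardenset import participation as part
from gardenset.sheets import read_observation_sheets, write_results

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

read = read_observation_sheets(args.data / "sheets.csv")
profiles = [part.participation_profile(s) for s in read.series]
codes = [part.code_comments(s) for s in read.series]

tables = {
    "participation": part.profiles_table(profiles),
    "participation_summary": part.type_summary(profiles),
}
for cat in part.CHALLENGE_CATEGORIES:
    tables[f"contingency_{cat}"] = part.challenge_contingency(
        profiles, codes, cat
    ).reset_index()
write_results(tables, args.outdir)

n_once = sum(p.type == "once" for p in profiles)
n_breaks = sum(p.has_break_gt10 for p in profiles)
print(f"{len(profiles)} contributions; {n_once} single-visit, "
      f"{n_breaks} with a break of more than ten days")
print(tables["participation_summary"].to_string(index=False))
with_comment = sum(c.has_comment for c in codes)
print(f"comments on {with_comment} contributions; per category: "
      + ", ".join(
          f"{cat}={sum(c.flags[cat] for c in codes)}"
          for cat in part.CHALLENGE_CATEGORIES
      ))
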