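#!/usr/bin/env python
"""Statistical analysis of the reconstructed fruit set.

Fits the two mixed-model structures (richness x imperviousness and
richness x temperature interactions, garden random intercept) on the full
data set and separately per plant group, runs the one-way ANOVA of fruit
set across participation types with Tukey follow-up, Fisher's exact tests
on the challenge categories, and the richness-abundance rank correlation.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gardenset import inference as inf
from gardenset import participation as part
from gardenset.errors import ValidationError
from gardenset.sheets import read_garden_table, read_observation_sheets, write_results

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

fruit = pd.read_csv(args.results / "fruit_set.csv")
gardens = read_garden_table(args.data / "gardens.csv")
merged = inf.build_model_frame(fruit, gardens)
merged, scaling = inf.scale_predictors(merged)

# --- mixed models ---------------------------------------------------------
fits = {}
for subset in ("all", "Cucurbitaceae", "Solanaceae"):
    sub = merged if subset == "all" else merged[merged["plant_group"] == subset]
    for structure, inter in (("I", "imperviousness"), ("II", "temperature")):
        spec = inf.ModelSpec(
            interaction_with=inter, include_plant_group=(subset == "all")
        )
        try:
            fits[f"{subset}_{structure}"] = inf.fit_lmm(sub, spec)
        except ValidationError as exc:
            print(f"model {subset}/{structure} skipped: {exc}")

coef = inf.coefficient_table(fits)
write_results({"model_coefficients": coef, "scaling": scaling}, args.results)
for label, fit in fits.items():
    inter_term = "z_rich:z_imp" if label.endswith("I") and not label.endswith("II") else "z_rich:z_temp"
    row = fit.coefficients.set_index("term")
    if inter_term in row.index:
        est, p = row.loc[inter_term, ["estimate", "p"]]
        print(f"{label}: interaction {inter_term} = {est:+.2f} (p={p:.3f}), "
              f"R2c={fit.r2_conditional:.2f}, n={fit.n_obs} plants/{fit.n_gardens} gardens")

# --- ANOVA across participation types ------------------------------------
sheets = read_observation_sheets(args.data / "sheets.csv")
profiles = part.profiles_table(
    [part.participation_profile(s) for s in sheets.series]
)
anova_frame = merged.merge(
    profiles[["plant_id", "participation_type"]], on="plant_id", how="left"
)
rows = []
for subset in ("all", "Cucurbitaceae", "Solanaceae"):
    sub = anova_frame if subset == "all" else anova_frame[anova_frame["plant_group"] == subset]
    try:
        res = inf.anova_participation(sub)
    except ValidationError as exc:
        print(f"ANOVA {subset} skipped: {exc}")
        continue
    rows.append({"subset": subset, "F": res.f_statistic, "p": res.p_value,
                 "levene_p": res.levene_p,
                 "letters": json.dumps(res.letters) if res.letters else ""})
    verdict = "significant" if res.p_value < 0.05 else "not significant"
    print(f"ANOVA {subset}: F={res.f_statistic:.2f} "
          f"({res.df_between},{res.df_within}), p={res.p_value:.3f} ({verdict})")
    if res.letters:
        print(f"  letters: {res.letters}")
write_results({"anova": pd.DataFrame(rows)}, args.results)

# --- Fisher tests on challenge categories ---------------------------------
codes = [part.code_comments(s) for s in sheets.series]
profs = [part.participation_profile(s) for s in sheets.series]
tables = {
    cat: part.challenge_contingency(profs, codes, cat)
    for cat in part.CHALLENGE_CATEGORIES
}
fisher = inf.fisher_challenges(tables)
for cat, res in fisher.items():
    followup = "pairwise follow-up run" if res.pairwise is not None else "no follow-up"
    print(f"Fisher {cat}: p={res.p_value:.3f} ({followup})")
write_results(
    {"fisher": pd.DataFrame(
        [{"category": c, "p": r.p_value, "pairwise_run": r.pairwise is not None}
         for c, r in fisher.items()]
    )},
    args.results,
)

rho, p = inf.spearman_rich_abund(gardens)
print(f"Spearman richness~abundance: rho={rho:.2f}, p={p:.2g}")
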