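# gardenset

Fruit-set reconstruction, quality control and inference for
citizen-science crop pollination surveys in urban community gardens.

Community gardeners monitor a marked crop plant (cucumber, zucchini,
pumpkin, strawberry, tomato, pepper, pepperoni, chili) every few days over
a growing season, recording four counts per visit: open flowers, faded
flowers, fruits on the plant, and fruits harvested since the last visit.
From these interval censuses the package reconstructs each plant's
**fruit set** — the percentage of flowers that developed into fruits, a
standard proxy for pollination service:

    fruit set (%) = 100 · total fruits / total flowers bloomed

Neither total is observed directly.  New fruits per interval are
`max(0, R_t + H_t − R_{t−1})` (both harvest-reporting conventions,
count-first and harvest-first, reduce to this one formula), and flowers
are counted by unit conservation over `U_t = O_t + F_t + C_t`, which adds
flowers whose stages were missed, never double-counts persisting ones, and
subtracts unverifiable last-visit arrivals.  On top of the reconstruction
sit:

* the five sequential **data-quality criteria** (listed crop, ≥3
  measurements, no initial fruit, plausibility, ≥3 plants per garden-year)
  with first-fail attribution;
* the **participation typology** (duration ≥ 56 days = long, ≤ 4
  days/measurement = high frequency, breaks > 10 days flagged) and keyword
  coding of gardener comments into challenge categories;
* the **inference stages**: REML linear mixed models of fruit set on
  standardized bee richness/abundance, landscape imperviousness,
  temperature and garden size with one interaction per model and a garden
  random intercept (Nakagawa–Schielzeth R², VIF/Shapiro diagnostics);
  one-way ANOVA across participation types with Tukey HSD and compact
  letters; exact r×2 Fisher tests on challenge categories with
  Holm-corrected follow-ups;
* a **synthetic garden-season simulator** (event-level flowering,
  fruiting, loss, per-type visit schedules, reporting conventions,
  injected data-entry errors) that provides ground truth for every stage.

It is aimed at ecologists running or evaluating pollination
citizen-science projects, and at anyone who needs a tested reference
implementation of this reconstruction-and-QC protocol.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_study.py --seed 1   # synthetic season -> results/data/
python analysis/02_quality_control.py           # QC + fruit set -> results/
python analysis/03_participation.py             # typology + comments
python analysis/04_inference.py                 # mixed models, ANOVA, Fisher
python analysis/05_validation.py                # ground-truth validation
```

With seed 1 the simulated study has 154 observation series in 22 gardens;
quality control prints

```
154 series read; 75 passed all five criteria
criterion                                             description  excluded
        1       observed plant is one of the eight selected crops         4
        2 observation series includes at least three measurements        11
        3                       no fruit at the first measurement        51
        4      observation series is plausible and without errors         9
        5         at least three study plants per garden and year         4
    total                                            all criteria        79
Cucurbitaceae: n=38, fruit set 33.9% (+/- 11.6 SD), range 8.1-66.7%
Solanaceae: n=37, fruit set 59.3% (+/- 12.7 SD), range 33.3-82.7%
```

i.e. most exclusions come from series that started after the first fruit
had formed, and the insect-dependent cucurbits set fruit at roughly half
the rate of the self-pollinating group — the per-criterion ledger and the
group contrast a field study of this design produces.  The model stage
then reports, per fit, the interaction estimate on the percent scale, its
normal-approximation p-value and the conditional R², e.g.

```
Cucurbitaceae_I: interaction z_rich:z_imp = +7.27 (p=0.076), R2c=0.70, n=38 plants/15 gardens
```

meaning: one standard deviation of bee richness buys about 7.3 percentage
points more fruit set per standard deviation of imperviousness (the
positive richness × urbanization interaction built into the generator),
not significant at this single-study size.  The same commands run on real
data by pointing the pipeline at your own `sheets.csv`/`gardens.csv`
(schemas in `gardenset/sheets.py`), or via the CLI:

```bash
gardenset report --seed 1 --outdir results/run     # full pipeline + manifest
gardenset qc results/data/sheets.csv               # single stages
```

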