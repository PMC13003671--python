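# Methods

This note documents the models, accounting rules and design choices behind
`gardenset`: how per-plant fruit set is reconstructed from interval
censuses, how the quality criteria and participation typology are defined,
what the statistical stages assume, and what the synthetic garden-season
generator does and does not emulate.

## Fruit-set reconstruction

A gardener visits a marked plant every few days and records four counts:
open flowers `O_t`, faded flowers `F_t`, fruits on the plant `R_t`, and
fruits harvested since the previous visit `H_t`.  Fruit set is

    fruit set (%) = 100 · total fruits / total flowers bloomed,

with both totals reconstructed from the census series.

**Fruits.**  New fruits in the interval ending at visit `t` are

    n_fruit_t = max(0, R_t + H_t − R_{t−1}),        C_t = Σ_{s≤t} n_fruit_s,

with `C_0 = R_0 + H_0`.  Gardeners followed one of two reporting
conventions — *count-first* (count fruits, then harvest; the harvest
appears in the next row's harvested column) or *harvest-first* (harvest,
then count what remains, so `H_t` can exceed `R_t`).  Although the
conventions read like two different procedures, both reduce to the single
interval formula above; the detected mode (harvest-first iff some visit
has `H_t > R_t` or a comment says so, one mode per series) only changes
which plausibility warnings apply.  Negative differences indicate fruit
loss between visits and are clipped to zero, which also guarantees a fruit
that sits on the plant across several visits is counted exactly once.

**Flowers.**  Stage-by-stage subtraction of flower counts is
under-determined, because the individual transitions (open→faded,
faded→fruit) are not observed.  The package therefore uses a *unit
conservation* form: each flower is a unit that is, at any visit, open,
faded, or already converted to a (possibly harvested) fruit, so the
visible unit total is `U_t = O_t + F_t + C_t` and new flower units are

    n_0 = U_0,      n_t = max(0, U_t − U_{t−1}),

summed over visits.  This satisfies every clause of the verbal protocol:
flowers present at the first visit are counted; fruits or faded flowers
whose emergence from an earlier stage was missed are added; persisting
flowers are never double-counted.  Because pollination of flowers that
newly opened or faded at the final visit cannot be assessed, the stage-wise
clipped increments `max(0,ΔO_T) + max(0,ΔF_T)` are subtracted — never new
fruits, whose pollination is proven.

Two consequences worth knowing:

* *Lower bound.*  Units can vanish unobserved (a faded flower drops while
  another opens), so reconstructed flowers ≤ true flowers bloomed on any
  schedule, with equality when every transition is visible at some visit.
  This is verified exactly against simulator ground truth under daily
  visits with zero fruit loss.
* *Boundedness.*  For any non-negative count series, `Σ n_t ≥ U_T` and the
  last-visit subtraction is at most `O_T + F_T`, hence total flowers ≥
  `C_T` = total fruits and fruit set never exceeds 100%.  A fruit set
  above 100% therefore cannot arise from valid counts; the code still
  warns if forced inputs produce one.

A series with zero reconstructed flowers has an *undefined* fruit set
(0/0), which is distinct from a valid 0% (flowers bloomed, none set);
series where no fruit developed are kept.

## Quality criteria

Five criteria are applied sequentially, each series attributed to its
*first* failing criterion so that per-criterion exclusion counts sum to
the total:

1. the crop is one of the eight study crops (free-text names are matched
   against a German/English synonym table; unknown names map to "other");
2. at least three measurements;
3. no fruit at the first measurement (`R_0 = 0` and `H_0 = 0`) — the
   indicator that no development stage was missed;
4. the series is plausible and error-free: no missing or negative counts,
   no duplicate visit dates, no reconstructed fruits without flowers;
5. after 1–4, at least three surviving plants per garden and year; a
   garden-year below that loses all its plants.

An optional single-point *spike rule* (off by default) drops an individual
record whose value in some count column differs from both neighbours by
more than a configurable multiple of the column's robust step scale — the
automated analogue of manually removing an obvious typo.  The ordering of
attribution is a package decision: it is the only reading under which the
per-criterion counts are well defined and sum to the total.

## Participation typology and comments

Duration `D` is whole days between first and last measurement; frequency
is `D / n` days per measurement with `n` the number of measurements (the
divisor `n − 1` is available behind a flag for sensitivity analysis, since
intervals rather than measurements would be the natural denominator).
Types cross duration (long iff `D ≥ 56`, eight weeks) with frequency (high
iff `freq ≤ 4.0` days).  Both boundary conventions are recorded in the run
manifest: 56 days counts as compliant with "at least eight weeks", and
4.0 days/measurement is anchored to "every four days or less".
Single-observation contributions form their own "once" class outside the
four types.  A long break is a gap of strictly more than ten days.

Comment coding is a deterministic, case-insensitive keyword screen into
four challenge categories (plant health, plant death, harvest loss,
protocol difficulties) with a bundled German/English lexicon that users
can replace; a comment matching no category is coded "other".  Keyword
matching approximates what is inherently a manual judgement, so outputs
carry a `keyword-matched` provenance marker and are intended to be
overridable by hand coding.

## Statistical stages

* **Mixed models.**  REML linear mixed models of per-plant fruit set (%)
  on standardized covariates (bee richness or abundance — never both,
  imperviousness, temperature, garden size) with a garden random
  intercept; exactly one interaction per model (richness×imperviousness,
  structure I, or richness×temperature, structure II); year enters as a
  categorical factor; the plant-group factor joins full-data fits only.
  Fixed-effect p-values use the large-sample normal approximation — a
  Satterthwaite-style degree-of-freedom correction is not available in the
  backend, and the approximation is noted on every fit.  Marginal and
  conditional R² follow the Nakagawa–Schielzeth variance partition.
  Diagnostics (Shapiro–Wilk p on residuals, maximum VIF, standardized
  residual range) are always emitted.  Rows with missing model columns are
  dropped listwise and counted.  Factors with a single observed level are
  dropped from the formula with a note rather than producing a singular
  design.
* **ANOVA.**  One-way ANOVA of fruit set across the four participation
  types (QC-passing series only), Levene's test for variance homogeneity,
  and — only when the omnibus test is significant at 0.05 — Tukey HSD with
  a compact letter display (insert-and-absorb).  Types with fewer than two
  observations are dropped as uninformative.
* **Exact tests.**  Fisher's exact test on each 4×2 type-by-comment table.
  The r×2 case is computed by direct enumeration of the conditional
  multivariate hypergeometric distribution (summing tables no more
  probable than the observed one); it reproduces scipy's 2×2 test exactly
  and agrees with R's `fisher.test` on 4×2 references.  Holm-corrected
  pairwise 2×2 follow-ups run only when the omnibus p < 0.05.  All
  contributions enter these tables regardless of QC outcome.
* **Spearman ρ** between garden bee richness and abundance, for context on
  why the two never co-occur in one model.

## The synthetic garden season

The generator exists to give every downstream stage a known ground truth.
Its layers:

* **Gardens.**  Imperviousness, temperature and size uniform over the
  study's printed ranges (20.9–96.2%, 18.4–21.5 °C, 0.04–2.39 ha);
  richness ≈ N(25.2, 7.5²) rounded, abundance log-normal with mean 153.7
  and SD 122.8, coupled through a Gaussian copula whose normal correlation
  `2·sin(πρ/6)` targets a Spearman ρ of 0.52; abundance is floored at
  richness.  Gardens split between two cities and two study years, with a
  N(0, σ²_garden) random intercept (default σ = 0.3 on the logit scale).
* **Plants and flowers.**  Each plant draws a crop from its group
  (default 45% cucurbits) and a per-flower conversion probability
  `p = expit(η + garden intercept)`, where η mirrors the structure-I fixed
  effects on standardized covariates.  Default effects put cucurbits near
  36% fruit set and the self-pollinating group near 58% (the printed group
  means), with a moderate positive richness×imperviousness interaction
  (+0.15 per SD², the direction of the study's headline result) and a
  small negative imperviousness main effect.  Flower openings are a
  homogeneous Poisson process (0.8/day over a 60-day flowering window);
  open lifespans are truncated-geometric (mean 2 d, max 7 d); a
  non-converting flower fades and, by default, remains visible for the
  rest of the season (finite faded persistence is available and is what
  makes flower undercounting testable).  Fruits ripen after a geometric
  lag (mean 8 d), may be lost unobserved at a per-day rate once ripe
  (default 1%/d; theft, rot, slugs), and are otherwise harvested at the
  first visit after ripening.
* **Observation.**  Visit schedules per participation type, with
  durations, intervals and break propensities anchored to the per-type
  means of the real study and tight start windows (0–3 days after first
  bloom — later starts make series fail criterion 3, which is also the
  criterion that dominates real exclusions).  25% of reporters are
  harvest-first.  Comments are sprinkled from the challenge lexicon at
  configurable rates, and labelled data-entry corruptions (unknown crop,
  truncation below three visits, fruit at first visit, a negative-count
  typo) are injected at rates anchored to the real exclusion shares, at
  most one per series, from a documented RNG stream.
* **Determinism.**  Every plant owns an RNG stream derived from the master
  seed and its garden/plant index; truth draws precede observation draws,
  so the recorded truth is identical whether or not sheets are generated,
  and identical configurations are byte-identical.

What the generator does **not** emulate: spatial garden layout and
pollinator movement, weather-driven covariance between gardens, cultivar
differences within a crop, male/female flowers in cucurbits (the protocol
did not either), gardener-specific counting error beyond the labelled
corruption types, and participant drop-out that depends on plant fate.
Passing validation therefore shows the *accounting and inference machinery*
is correct under a plausible observation process — not that real gardener
data are free of biases the generator lacks.

## Validation experiments and their sizes

All experiments live in `gardenset.validation`, are seeded, and are run
both by the test suite and by `scripts/acceptance.py`.

* *Ledger exactness*: 30 gardens × 5 plants, daily visits, zero loss, no
  corruption — reconstructed totals must equal event-level truth for every
  plant (they do; this is the regime where no information is lost).
* *Telescoping identity*: 500 randomized series with complete harvest
  reporting — the fruit total must equal `R_T + ΣH − R_0` exactly.
* *Worked ledger example*: a five-visit series checked by hand (3 fruits,
  5 flowers, 60%).
* *Planted QC fixture*: 20 series with 2+3+4+3+2 planted violations —
  recovered exactly under first-fail attribution.
* *Interaction recovery*: 100 replicates of 30 gardens × 10 plants with
  the recovery effect set.  The fitted model is linear in percent fruit
  set while the generator is logistic per flower, so the estimand is the
  *population least-squares projection* of expected fruit set onto the
  model design; its interaction coefficient is computed by Monte Carlo
  over the covariate and intercept distributions (~3.6 percentage points
  per SD² at the default effects).  The 95% Wald interval must cover it in
  ≥ 85% of replicates — the margin below the nominal 95% absorbs the
  linearization and the per-sample standardization.
* *Type-I error*: 200 replicates of 40 gardens × 10 plants with all
  effects and the garden variance at zero; the interaction's rejection
  rate at α = 0.05 must stay within three binomial standard errors of
  0.05.
* *Observer bias*: 50 replicates of 16 gardens × 10 plants, all plants on
  long-duration schedules (half low-, half high-frequency), ripe-fruit
  loss at 5%/day.  Only fruits that ripen *and* vanish within a single
  inter-visit gap can bias the reconstruction (a fruit seen once is
  counted forever), so the per-plant effect is small; the per-replicate
  study is sized at 160 plants so the one-sided test of
  mean(long/low) < mean(long/high) has adequate power.  The reconstructed
  deficit of sparse schedules is about 1.3–1.8 percentage points.

Replicate counts and study sizes are the package's chosen balance between
Monte-Carlo error and runtime; the two model-validation experiments
dominate the cost (a few minutes on one core).

## Numerical and policy choices

* Dates are ISO-8601; time of day is stored but ignored by all duration
  arithmetic (thresholds are whole days).
* Blank count cells are missing, never zero; non-integer cells are row
  problems, never rounded; negative integers parse (they are data-entry
  typos for criterion 4 to catch, and one of the injectable corruptions).
* `H_t` is per-visit (fruits harvested since the previous visit), not
  cumulative.
* Strawberry is analyzed inside the "Solanaceae" group label, matching the
  study's grouping by pollination biology rather than botany; the label is
  kept for comparability.
* The exact-test p-value convention sums tables with probability ≤ the
  observed one (with a 1e−7 relative tolerance against ties lost to
  floating point), matching the classical two-sided Fisher test.
* Mixed-model fits that do not converge or sit at the zero-variance
  boundary are flagged on the result object, never raised; fully singular
  designs (more garden-level terms than surviving gardens) are reported as
  skipped models by the pipeline.
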