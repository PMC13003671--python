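"""Statistical stages: mixed models, ANOVA across participation types,
exact tests on challenge categories.

The central model is a linear mixed-effects model of per-plant fruit set
(%) on standardized garden covariates with a random intercept per garden::

    fruit set ~ bee richness * imperviousness + temperature + size + year + (1|garden)   (I)
    fruit set ~ bee richness * temperature + imperviousness + size + year + (1|garden)  (II)

Exactly one interaction enters per fitted model, and bee abundance may
replace richness (never both).  Fits are by REML; fixed-effect p-values use
the large-sample normal approximation (noted on every fit); marginal and
conditional R² follow the Nakagawa–Schielzeth variance partition.

Participation types are compared by one-way ANOVA with Levene's test and —
only when the omnibus test is significant — Tukey HSD with a compact letter
display.  Challenge categories are tested with Fisher's exact test on the
4x2 type-by-comment tables (exact enumeration of the conditional
multivariate hypergeometric distribution), with Holm-corrected pairwise
2x2 follow-ups gated on omnibus significance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import ConfigurationError, ValidationError
from .sheets import GardenContext, gardens_to_frame

#: Covariates standardized before model fitting.
SCALED_COVARIATES = (
    "bee_richness",
    "bee_abundance",
    "imperviousness_pct",
    "mean_temp_c",
    "size_ha",
)

_Z_NAMES = {
    "bee_richness": "z_rich",
    "bee_abundance": "z_abund",
    "imperviousness_pct": "z_imp",
    "mean_temp_c": "z_temp",
    "size_ha": "z_size",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed-effect structure to fit.

    ``bee_metric`` is richness or abundance (never both); ``interaction_with``
    names the single covariate interacting with it (imperviousness for model
    structure I, temperature for II); the remaining covariate enters
    additively.  ``include_plant_group`` adds the plant-group factor and is
    meant for the full-dataset fit only.
    """

    bee_metric: str = "richness"
    interaction_with: str = "imperviousness"
    include_plant_group: bool = False

    def __post_init__(self) -> None:
        metrics = (
            [self.bee_metric]
            if isinstance(self.bee_metric, str)
            else list(self.bee_metric)
        )
        if len(metrics) != 1 or metrics[0] not in ("richness", "abundance"):
            raise ConfigurationError(
                "bee_metric must be exactly one of 'richness' or 'abundance'; "
                "richness and abundance are never included simultaneously"
            )
        inter = (
            [self.interaction_with]
            if isinstance(self.interaction_with, str)
            else list(self.interaction_with)
        )
        if len(inter) != 1 or inter[0] not in ("imperviousness", "temperature"):
            raise ConfigurationError(
                "interaction_with must be exactly one of 'imperviousness' or "
                "'temperature' (one interaction term per model)"
            )

    @property
    def formula(self) -> str:
        bee = "z_rich" if self.bee_metric == "richness" else "z_abund"
        inter = "z_imp" if self.interaction_with == "imperviousness" else "z_temp"
        other = "z_temp" if inter == "z_imp" else "z_imp"
        terms = [f"{bee} * {inter}", other, "z_size", "C(year)"]
        if self.include_plant_group:
            terms.append("C(plant_group)")
        return "fruit_set_pct ~ " + " + ".join(terms)

    @property
    def structure(self) -> str:
        return "I" if self.interaction_with == "imperviousness" else "II"


@dataclass
class ModelFit:
    spec: ModelSpec
    coefficients: pd.DataFrame      # term, estimate, se, z, p
    var_garden: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    diagnostics: dict[str, float]
    n_obs: int
    n_gardens: int
    n_dropped: int
    converged: bool
    singular: bool
    notes: list[str] = field(default_factory=list)


def scale_predictors(
    data: pd.DataFrame, columns: Sequence[str] = SCALED_COVARIATES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize covariates to sample mean 0 and SD 1 over the analysis rows.

    Returns the frame with added ``z_*`` columns plus a table of the scaling
    constants.  A constant column raises (zero SD cannot be standardized).
    """
    out = data.copy()
    rows = []
    for col in columns:
        if col not in out.columns:
            continue
        values = out[col].astype(float)
        mean, sd = values.mean(), values.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"cannot scale constant column {col!r} (zero SD)")
        out[_Z_NAMES[col]] = (values - mean) / sd
        rows.append({"column": col, "scaled_name": _Z_NAMES[col], "mean": mean, "sd": sd})
    return out, pd.DataFrame(rows)


def build_model_frame(
    fruit_table: pd.DataFrame, gardens: Sequence[GardenContext] | pd.DataFrame
) -> pd.DataFrame:
    """Merge per-plant fruit-set results with garden-year covariates."""
    gdf = gardens if isinstance(gardens, pd.DataFrame) else gardens_to_frame(gardens)
    merged = fruit_table.merge(gdf, on=["garden_id", "year"], how="left", validate="m:1")
    unmatched = merged["imperviousness_pct"].isna().sum()
    if unmatched:
        warnings.warn(
            f"{unmatched} plants have no matching garden-year covariates",
            stacklevel=2,
        )
    return merged


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of the mixed model with a garden random intercept.

    Rows with missing model columns are dropped (listwise) and counted.
    Non-convergence or a singular (zero-variance) garden intercept is
    flagged on the result, never raised.
    """
    needed = ["fruit_set_pct", "garden_id", "year", "z_size", "z_imp", "z_temp"]
    needed.append("z_rich" if spec.bee_metric == "richness" else "z_abund")
    if spec.include_plant_group:
        needed.append("plant_group")
    rows = data.dropna(subset=[c for c in needed if c in data.columns])
    n_dropped = len(data) - len(rows)
    if rows["garden_id"].nunique() < 2:
        raise ValidationError("mixed model needs at least two gardens")

    notes = ["fixed-effect p-values use the large-sample normal approximation"]
    formula = spec.formula
    if rows["year"].nunique() < 2:
        formula = formula.replace(" + C(year)", "")
        notes.append("single study year in the data: year term dropped")
    if spec.include_plant_group and rows["plant_group"].nunique() < 2:
        formula = formula.replace(" + C(plant_group)", "")
        notes.append("single plant group in the data: group term dropped")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, rows, groups=rows["garden_id"])
        try:
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
        except Exception as exc:  # pragma: no cover - pathological inputs
            raise ValidationError(f"mixed model failed outright: {exc}") from exc

    fe = fit.fe_params
    se = fit.bse_fe
    zvals = fe / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    coefficients = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.values,
            "se": se.values,
            "z": zvals.values,
            "p": pvals,
        }
    )

    var_garden = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    var_residual = float(fit.scale)
    exog = model.exog
    fitted_fixed = exog @ fe.values
    var_fixed = float(np.var(fitted_fixed, ddof=1))
    denom = var_fixed + var_garden + var_residual
    r2m = var_fixed / denom
    r2c = (var_fixed + var_garden) / denom

    singular = var_garden < 1e-8 * max(var_residual, 1.0)
    if singular:
        notes.append("garden random-intercept variance is at the zero boundary")
    if not converged:
        notes.append("optimizer did not report convergence")

    resid = np.asarray(fit.resid, dtype=float)
    std_resid = resid / np.std(resid, ddof=1)
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan
    vif_terms = [i for i, name in enumerate(model.exog_names) if name != "Intercept"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vifs = [variance_inflation_factor(exog, i) for i in vif_terms]
    diagnostics = {
        "shapiro_p": shapiro_p,
        "max_vif": float(np.max(vifs)) if vifs else np.nan,
        "std_resid_min": float(std_resid.min()),
        "std_resid_max": float(std_resid.max()),
    }

    return ModelFit(
        spec=spec,
        coefficients=coefficients,
        var_garden=var_garden,
        var_residual=var_residual,
        r2_marginal=r2m,
        r2_conditional=r2c,
        diagnostics=diagnostics,
        n_obs=len(rows),
        n_gardens=rows["garden_id"].nunique(),
        n_dropped=n_dropped,
        converged=converged,
        singular=singular,
        notes=notes,
    )


def coefficient_table(fits: Mapping[str, ModelFit]) -> pd.DataFrame:
    """Stack coefficient tables of several fits into one long table."""
    frames = []
    for label, fit in fits.items():
        t = fit.coefficients.copy()
        t.insert(0, "model", label)
        t["r2_marginal"] = fit.r2_marginal
        t["r2_conditional"] = fit.r2_conditional
        t["n_obs"] = fit.n_obs
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ANOVA across participation types
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    levene_statistic: float
    levene_p: float
    group_means: pd.DataFrame
    tukey: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


def anova_participation(
    data: pd.DataFrame,
    value_col: str = "fruit_set_pct",
    group_col: str = "participation_type",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA of fruit set across participation types.

    Tukey HSD pairwise comparisons and the compact letter display are
    computed only when the omnibus test is significant at ``alpha``.
    """
    df = data.dropna(subset=[value_col, group_col])
    df = df[df[group_col] != "once"]
    # singleton groups carry no within-group information; drop them
    sizes = df.groupby(group_col)[value_col].transform("size")
    df = df[sizes >= 2]
    groups = [g[value_col].to_numpy(dtype=float) for _, g in df.groupby(group_col)]
    if len(groups) < 2:
        raise ValidationError(
            "ANOVA needs at least two participation types with two or more "
            "observations each"
        )
    f_stat, p = stats.f_oneway(*groups)
    lev_stat, lev_p = stats.levene(*groups, center="median")
    k, n = len(groups), sum(len(g) for g in groups)
    summary = (
        df.groupby(group_col)[value_col]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    tukey_table = None
    letters = None
    if p < alpha:
        res = pairwise_tukeyhsd(
            df[value_col].to_numpy(dtype=float), df[group_col].to_numpy(), alpha=alpha
        )
        tukey_table = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        sig_pairs = [
            (str(row["group1"]), str(row["group2"]))
            for _, row in tukey_table.iterrows()
            if float(row["p-adj"]) < alpha
        ]
        letters = compact_letter_display(
            sorted(df[group_col].unique()), sig_pairs
        )
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        levene_statistic=float(lev_stat),
        levene_p=float(lev_p),
        group_means=summary,
        tukey=tukey_table,
        letters=letters,
    )


def compact_letter_display(
    groups: Sequence[str], significant_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Groups share a letter iff they are not significantly different in the
    supplied pairwise comparisons.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in significant_pairs:
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for reduced in (s - {a}, s - {b}):
                if reduced and not any(reduced <= other for other in sets):
                    sets.append(reduced)
    # absorb: drop sets contained in others
    sets = [s for s in sets if not any(s < other for other in sets)]
    sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in sorted(s):
            out[g] += letter
    return out


# ---------------------------------------------------------------------------
# Fisher's exact tests on challenge categories
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p_value: float
    table: pd.DataFrame
    pairwise: pd.DataFrame | None = None


def fisher_exact_rx2(table: np.ndarray | pd.DataFrame) -> float:
    """Exact conditional test of independence for an r x 2 table.

    Enumerates the conditional distribution of the first column given all
    margins (multivariate hypergeometric) and sums the probabilities of
    tables no more probable than the observed one — the same two-sided
    convention as the classical 2x2 Fisher test.
    """
    a = np.asarray(table, dtype=int)
    if a.ndim != 2 or a.shape[1] != 2 or (a < 0).any():
        raise ValidationError("fisher_exact_rx2 expects a non-negative r x 2 table")
    rows = a.sum(axis=1)
    c1 = int(a[:, 0].sum())
    n = int(rows.sum())
    if n == 0 or c1 == 0 or c1 == n:
        return 1.0

    def log_prob(x: tuple[int, ...]) -> float:
        lp = -(gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        for xi, ri in zip(x, rows):
            lp += gammaln(ri + 1) - gammaln(xi + 1) - gammaln(ri - xi + 1)
        return lp

    obs_lp = log_prob(tuple(a[:, 0]))
    total = 0.0
    ranges = [range(int(r) + 1) for r in rows[:-1]]
    last_row = int(rows[-1])
    for head in itertools.product(*ranges):
        x_last = c1 - sum(head)
        if x_last < 0 or x_last > last_row:
            continue
        lp = log_prob(head + (x_last,))
        if lp <= obs_lp + 1e-7:
            total += np.exp(lp)
    return float(min(1.0, total))


def fisher_challenges(
    tables: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, FisherResult]:
    """Fisher's exact test per challenge category.

    Pairwise 2x2 tests between participation types with Holm correction are
    run only when a category's omnibus test is significant at ``alpha``.
    """
    results: dict[str, FisherResult] = {}
    for category, table in tables.items():
        p = fisher_exact_rx2(table)
        pairwise = None
        if p < alpha:
            rows = []
            types = list(table.index)
            for a, b in itertools.combinations(types, 2):
                sub = table.loc[[a, b]].to_numpy()
                rows.append(
                    {"type_a": a, "type_b": b, "p_raw": fisher_exact_rx2(sub)}
                )
            pw = pd.DataFrame(rows)
            pw["p_holm"] = multipletests(pw["p_raw"], method="holm")[1]
            pairwise = pw
        results[category] = FisherResult(p_value=p, table=pd.DataFrame(table), pairwise=pairwise)
    return results


def spearman_rich_abund(
    gardens: Sequence[GardenContext] | pd.DataFrame,
) -> tuple[float, float]:
    """Spearman correlation between bee richness and abundance per garden-year."""
    gdf = gardens if isinstance(gardens, pd.DataFrame) else gardens_to_frame(gardens)
    rho, p = stats.spearmanr(gdf["bee_richness"], gdf["bee_abundance"])
    return float(rho), float(p)
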