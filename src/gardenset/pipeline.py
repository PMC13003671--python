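"""End-to-end orchestration: simulate/read -> QC -> fruit set ->
participation -> comments -> inference, with a machine-readable manifest.

Every stage writes its table under the output directory, and the manifest
records the configuration hash, seed, input digests, per-stage row counts
and the active decision conventions (duration/frequency boundaries,
frequency divisor, spike rule), so a run is reproducible and auditable.
No series is silently dropped: every input plant id ends up in exactly one
of the result set, the QC-exclusion ledger, the undefined-fruit-set list,
or the parse-failure list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import fruitset as fs
from . import inference as inf
from . import participation as part
from . import sheets as io
from . import simulate as sim
from .errors import ConfigurationError, ValidationError

log = logging.getLogger("gardenset")

DEFAULT_PIPELINE_CONFIG: dict[str, Any] = {
    "seed": 0,
    "participation": {
        "long_duration_days": part.LONG_DURATION_DAYS,
        "high_frequency_days": part.HIGH_FREQUENCY_DAYS,
        "long_break_days": part.LONG_BREAK_DAYS,
        "interval_divisor": False,
    },
    "qc": {"min_plants_per_garden_year": 3, "spike_rule": None},
    "models": {
        "bee_metrics": ["richness"],
        "structures": ["I", "II"],
        "subsets": ["all", "Cucurbitaceae", "Solanaceae"],
    },
    "anova_alpha": 0.05,
    "fisher_alpha": 0.05,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    decisions: dict[str, Any]
    notices: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    tables: dict[str, pd.DataFrame]
    model_fits: dict[str, inf.ModelFit]
    anova: dict[str, inf.AnovaResult]
    fisher: dict[str, inf.FisherResult]
    spearman: tuple[float, float] | None


def _deep_update(base: dict, extra: Mapping) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULT_PIPELINE_CONFIG, user)


def simulation_config_from_dict(block: Mapping, seed: int) -> sim.SimulationConfig:
    """Build a SimulationConfig from a plain config mapping."""
    kwargs = dict(block)
    kwargs.setdefault("seed", seed)
    if "beta" in kwargs and isinstance(kwargs["beta"], Mapping):
        kwargs["beta"] = sim.EffectSizes(**kwargs["beta"])
    if "covariates" in kwargs and isinstance(kwargs["covariates"], Mapping):
        cov = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in kwargs["covariates"].items()
        }
        kwargs["covariates"] = sim.CovariateRanges(**cov)
    if "schedules" in kwargs and isinstance(kwargs["schedules"], Mapping):
        kwargs["schedules"] = {
            name: sim.ScheduleSpec(
                start_window=tuple(s["start_window"]),
                duration_days=tuple(s["duration_days"]),
                interval_days=tuple(s["interval_days"]),
                break_probability=s.get("break_probability", 0.0),
                break_length_days=tuple(s.get("break_length_days", (11, 15))),
            )
            for name, s in kwargs["schedules"].items()
        }
    try:
        return sim.SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"simulation config: {exc}") from exc


def run_pipeline(config: Mapping, outdir) -> PipelineResult:
    """Run the full analysis on simulated or user-supplied data.

    ``config`` must contain either a ``simulation`` block or an ``inputs``
    block with ``sheets``/``gardens`` CSV paths.  All stage outputs are
    written as CSV under ``outdir`` together with ``manifest.json``.
    """
    config = _deep_update(DEFAULT_PIPELINE_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    notices: list[str] = []
    input_digests: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {}

    # --- stage 1: simulate or read -------------------------------------
    if "simulation" in config:
        sim_config = simulation_config_from_dict(config["simulation"], seed)
        study = sim.simulate_study(sim_config)
        series, gardens = study.sheets, study.gardens
        io.write_observation_sheets(series, outdir / "sheets.csv")
        io.write_garden_table(gardens, outdir / "gardens.csv")
        sim.truth_to_csv(study.truth, outdir / "truth.csv")
        input_digests["sheets.csv"] = _digest_file(outdir / "sheets.csv")
        input_digests["gardens.csv"] = _digest_file(outdir / "gardens.csv")
        parse_failed: list[str] = []
        if study.corruption_log:
            log.info("injected %d corruptions", len(study.corruption_log))
    elif "inputs" in config:
        sheets_path = Path(config["inputs"]["sheets"])
        gardens_path = Path(config["inputs"]["gardens"])
        input_digests["sheets"] = _digest_file(sheets_path)
        input_digests["gardens"] = _digest_file(gardens_path)
        read = io.read_observation_sheets(sheets_path)
        series = read.series
        ids_ok = {s.plant_id for s in series}
        parse_failed = sorted(
            {p.plant_id for p in read.problems if p.plant_id not in ids_ok}
        )
        for prob in read.problems:
            log.warning("row %d (%s/%s): %s", prob.row, prob.plant_id, prob.column, prob.message)
        gardens = io.read_garden_table(gardens_path)
    else:
        raise ConfigurationError(
            "config needs either a 'simulation' block or an 'inputs' block"
        )
    n_read = len(series)

    # --- stage 2: quality control ---------------------------------------
    qc_cfg = config["qc"]
    spike = (
        fs.SpikeRule(**qc_cfg["spike_rule"])
        if qc_cfg.get("spike_rule")
        else None
    )
    reports = fs.apply_quality_criteria(
        series,
        gardens,
        spike_rule=spike,
        min_plants_per_garden_year=int(qc_cfg.get("min_plants_per_garden_year", 3)),
    )
    for r in reports:
        if not r.passed:
            log.info(
                "excluded %s: criterion %s (%s)",
                r.plant_id,
                r.first_failed_criterion,
                r.detail or fs.CRITERION_LABELS[r.first_failed_criterion],
            )
    tables["qc_report"] = pd.DataFrame(
        [
            {
                "plant_id": r.plant_id,
                "passed": r.passed,
                "first_failed_criterion": r.first_failed_criterion,
                **{f"c{c}": r.criteria[c] for c in (1, 2, 3, 4, 5)},
                "detail": r.detail,
            }
            for r in reports
        ]
    )
    tables["qc_exclusions"] = fs.exclusion_table(reports)
    n_pass = sum(r.passed for r in reports)

    # --- stage 3: fruit set ---------------------------------------------
    fruit_table = fs.fruit_set_table(series, reports, only_passing=True)
    undefined = fruit_table.attrs.get("dropped", [])
    if undefined:
        notices.append(
            f"{len(undefined)} QC-passing series had an undefined fruit set "
            "(no flowers) and were set aside"
        )
    tables["fruit_set"] = fruit_table

    # --- stage 4: participation and comments ----------------------------
    p_cfg = config["participation"]
    profiles = [
        part.participation_profile(
            s,
            long_duration_days=int(p_cfg["long_duration_days"]),
            high_frequency_days=float(p_cfg["high_frequency_days"]),
            interval_divisor=bool(p_cfg["interval_divisor"]),
        )
        for s in series
    ]
    codes = [part.code_comments(s) for s in series]
    tables["participation"] = part.profiles_table(profiles)
    tables["participation_summary"] = part.type_summary(profiles)
    contingency = {
        cat: part.challenge_contingency(profiles, codes, cat)
        for cat in part.CHALLENGE_CATEGORIES
    }
    for cat, table in contingency.items():
        tables[f"contingency_{cat}"] = table.reset_index()

    # --- stage 5: inference ----------------------------------------------
    model_fits: dict[str, inf.ModelFit] = {}
    anova_results: dict[str, inf.AnovaResult] = {}
    fisher_results: dict[str, inf.FisherResult] = {}
    spearman = None

    if fruit_table.empty:
        notices.append("no QC-passing series: model stage skipped")
    else:
        merged = inf.build_model_frame(fruit_table, gardens)
        try:
            merged, scaling = inf.scale_predictors(merged)
            tables["scaling"] = scaling
        except ValidationError as exc:
            notices.append(f"scaling skipped: {exc}")
            merged = None
        if merged is not None:
            m_cfg = config["models"]
            subsets = {
                "all": merged,
                "Cucurbitaceae": merged[merged["plant_group"] == "Cucurbitaceae"],
                "Solanaceae": merged[merged["plant_group"] == "Solanaceae"],
            }
            for subset_name in m_cfg["subsets"]:
                sub = subsets[subset_name]
                for metric in m_cfg["bee_metrics"]:
                    for structure in m_cfg["structures"]:
                        spec = inf.ModelSpec(
                            bee_metric=metric,
                            interaction_with=(
                                "imperviousness" if structure == "I" else "temperature"
                            ),
                            include_plant_group=(subset_name == "all"),
                        )
                        label = f"{subset_name}_{metric}_{structure}"
                        try:
                            model_fits[label] = inf.fit_lmm(sub, spec)
                        except ValidationError as exc:
                            notices.append(f"model {label} skipped: {exc}")
            if model_fits:
                tables["model_coefficients"] = inf.coefficient_table(model_fits)
                tables["model_diagnostics"] = pd.DataFrame(
                    [
                        {
                            "model": label,
                            "n_obs": f.n_obs,
                            "n_gardens": f.n_gardens,
                            "var_garden": f.var_garden,
                            "var_residual": f.var_residual,
                            "r2_marginal": f.r2_marginal,
                            "r2_conditional": f.r2_conditional,
                            "converged": f.converged,
                            "singular": f.singular,
                            **f.diagnostics,
                        }
                        for label, f in model_fits.items()
                    ]
                )

            # ANOVA of fruit set across participation types (QC-passing only)
            prof_df = tables["participation"][["plant_id", "participation_type"]]
            anova_frame = merged.merge(prof_df, on="plant_id", how="left")
            for subset_name in m_cfg["subsets"]:
                sub = (
                    anova_frame
                    if subset_name == "all"
                    else anova_frame[anova_frame["plant_group"] == subset_name]
                )
                try:
                    anova_results[subset_name] = inf.anova_participation(
                        sub, alpha=float(config["anova_alpha"])
                    )
                except ValidationError as exc:
                    notices.append(f"ANOVA {subset_name} skipped: {exc}")
            if anova_results:
                tables["anova"] = pd.DataFrame(
                    [
                        {
                            "subset": name,
                            "F": a.f_statistic,
                            "df_between": a.df_between,
                            "df_within": a.df_within,
                            "p": a.p_value,
                            "levene_p": a.levene_p,
                            "letters": json.dumps(a.letters) if a.letters else "",
                        }
                        for name, a in anova_results.items()
                    ]
                )
    spearman = inf.spearman_rich_abund(gardens) if len(gardens) > 2 else None

    fisher_results = inf.fisher_challenges(
        contingency, alpha=float(config["fisher_alpha"])
    )
    tables["fisher"] = pd.DataFrame(
        [
            {
                "category": cat,
                "p": res.p_value,
                "pairwise_run": res.pairwise is not None,
            }
            for cat, res in fisher_results.items()
        ]
    )

    # --- outputs and manifest --------------------------------------------
    io.write_results(tables, outdir)
    part_table = tables["participation"]
    profile_types = (
        part_table["participation_type"]
        if "participation_type" in part_table.columns
        else pd.Series(dtype=str)
    )
    manifest = RunManifest(
        config_hash=_config_hash(dict(config)),
        seed=seed,
        input_digests=input_digests,
        stage_counts={
            "read": n_read,
            "parse_failed": len(parse_failed),
            "qc_passed": int(n_pass),
            "qc_excluded": int(n_read - n_pass),
            "undefined_fruit_set": len(undefined),
            "fruit_set_results": int(len(fruit_table)),
            "typed": int((profile_types != "once").sum()),
            "modeled": model_fits[next(iter(model_fits))].n_obs if model_fits else 0,
        },
        decisions={
            "long_duration_days": config["participation"]["long_duration_days"],
            "high_frequency_days": config["participation"]["high_frequency_days"],
            "long_break_days": config["participation"]["long_break_days"],
            "frequency_divisor": (
                "n_measurements - 1"
                if config["participation"]["interval_divisor"]
                else "n_measurements"
            ),
            "duration_boundary": "D >= 56 days counts as long",
            "frequency_boundary": "freq <= 4.0 days/measurement counts as high",
            "spike_rule": config["qc"]["spike_rule"] or "off",
        },
        notices=notices,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    if spearman is not None:
        (outdir / "spearman.json").write_text(
            json.dumps({"rho": spearman[0], "p": spearman[1]})
        )
    return PipelineResult(
        manifest=manifest,
        tables=tables,
        model_fits=model_fits,
        anova=anova_results,
        fisher=fisher_results,
        spearman=spearman,
    )
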