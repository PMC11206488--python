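"""End-to-end orchestration: load -> impute -> score -> substitute ->
aggregate -> estimate -> report.

Stage order is fixed: imputation must precede scoring (scores need
complete profiles) and scoring must precede substitution (candidates are
chosen by score).  A run is fully determined by its manifest — input file
hashes (or the synthetic seed), scenario IDs, point-table version and the
number of replicate weights.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import read_config
from .errors import ConfigError
from .food_db import BRANDED, GENERIC, FoodDatabase, impute_missing_nutrients, \
    load_food_table
from .intake import daily_intakes, filter_sample, load_recalls, load_respondents
from .matching import MatchTable, load_matches, match_coverage
from .profiles import PointTables, load_point_tables
from .substitution import SCENARIOS, ScenarioConfig, apply_scenario, baseline_foods
from .survey import SurveyDesign, scenario_report, subset_recalls
from .synth import SynthConfig, World, generate_world

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "PreparedInputs", "prepare_world", "run_scenarios",
           "run", "scenario_configs_from", "world_from_config"]


@dataclass
class PreparedInputs:
    """Scored databases plus the eligible analysis sample."""

    generic: FoodDatabase          # imputed + scored
    branded: FoodDatabase | None   # imputed + scored
    matches: MatchTable | None
    respondents: pd.DataFrame      # eligible, with >= 1 recall line
    recalls: pd.DataFrame          # restricted to eligible respondents
    design: SurveyDesign
    imputation_log: pd.DataFrame
    counts: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    subset_report: pd.DataFrame | None
    baseline_intakes: pd.DataFrame
    scenario_intakes: dict[str, pd.DataFrame]
    substitution_maps: dict[str, dict]
    prepared: PreparedInputs
    manifest: dict


def prepare_world(world: World, tables: PointTables | None = None) -> PreparedInputs:
    """Impute, score and filter one world down to the analysis inputs."""
    tables = tables or load_point_tables()
    generic, imp_log = impute_missing_nutrients(world.generic)
    branded = world.branded
    branded_imp = pd.DataFrame()
    if branded is not None and len(branded) and branded.has_missing():
        branded, branded_imp = impute_missing_nutrients(branded)
    generic = generic.score_with(tables)
    if branded is not None and len(branded):
        branded = branded.score_with(tables)

    eligible = filter_sample(world.respondents)
    recalls = world.recalls[
        world.recalls["respondent_id"].astype(str).isin(
            set(eligible["respondent_id"].astype(str)))]
    with_lines = set(recalls["respondent_id"].astype(str))
    no_recall = set(eligible["respondent_id"].astype(str)) - with_lines
    if no_recall:
        log.warning("excluding %d eligible respondent(s) with empty recalls",
                    len(no_recall))
        eligible = eligible[eligible["respondent_id"].astype(str).isin(with_lines)]
    design = SurveyDesign.from_frame(eligible)
    counts = dict(
        foods_loaded=len(generic),
        branded_loaded=0 if branded is None else len(branded),
        imputed_cells=len(imp_log) + len(branded_imp),
        respondents_total=len(world.respondents),
        respondents_retained=len(eligible),
        recall_lines=len(recalls),
    )
    return PreparedInputs(generic=generic, branded=branded,
                          matches=world.matches, respondents=eligible,
                          recalls=recalls, design=design,
                          imputation_log=imp_log, counts=counts)


def run_scenarios(prep: PreparedInputs,
                  scenarios: list[ScenarioConfig],
                  tables: PointTables | None = None) -> PipelineResult:
    """Evaluate baseline and every requested scenario, with the
    substituted-foods-only subset analysis when scenario 1 is present."""
    tables = tables or load_point_tables()
    base_foods = baseline_foods(prep.recalls, prep.generic)
    baseline = daily_intakes(prep.recalls, base_foods)

    scenario_intakes: dict[str, pd.DataFrame] = {}
    sub_maps: dict[str, dict] = {}
    effective: dict[str, pd.DataFrame] = {}
    for sc in scenarios:
        eff, sub_map = apply_scenario(prep.recalls, sc, prep.generic,
                                      prep.branded, prep.matches, tables)
        effective[sc.scenario_id] = eff
        sub_maps[sc.scenario_id] = sub_map
        scenario_intakes[sc.scenario_id] = daily_intakes(prep.recalls, eff)
        prep.counts[f"substituted_foods_{sc.scenario_id}"] = int(
            sum(r.replaced for r in sub_map.values()))
        log.info("scenario %s: %d of %d distinct foods substituted",
                 sc.scenario_id, prep.counts[f"substituted_foods_{sc.scenario_id}"],
                 len(sub_map))

    report = scenario_report(baseline, scenario_intakes, prep.design)

    subset_rep = None
    s1_ids = [s.scenario_id for s in scenarios if s.scenario_id.startswith("1")]
    if s1_ids:
        substituted = set().union(*(
            {fid for fid, r in sub_maps[sid].items() if r.replaced}
            for sid in s1_ids))
        sub_lines = subset_recalls(prep.recalls, substituted)
        if len(sub_lines):
            ids = pd.Index(sorted(set(sub_lines["respondent_id"].astype(str))))
            sub_design = prep.design.subset(ids)
            sub_base = daily_intakes(sub_lines, base_foods)
            sub_scen = {sid: daily_intakes(sub_lines, effective[sid])
                        for sid in s1_ids}
            subset_rep = scenario_report(sub_base, sub_scen, sub_design)
            prep.counts["subset_respondents"] = len(ids)

    manifest = dict(scenarios=[s.scenario_id for s in scenarios],
                    point_tables=tables.version, B=prep.design.B,
                    software_version=__version__, counts=dict(prep.counts))
    return PipelineResult(report=report, subset_report=subset_rep,
                          baseline_intakes=baseline,
                          scenario_intakes=scenario_intakes,
                          substitution_maps=sub_maps, prepared=prep,
                          manifest=manifest)


# ---------------------------------------------------------------------------
# config-file front end


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def world_from_config(cfg: dict[str, str], base: Path,
                      seed: int | None = None) -> tuple[World, dict]:
    """Build a world from config: synthetic (``synth.*`` keys) or files."""
    synth_keys = {k: v for k, v in cfg.items() if k.startswith("synth.")}
    if synth_keys:
        kwargs: dict = {}
        casts = dict(seed=int, n_respondents=int, n_categories=int,
                     foods_per_category=int, B=int,
                     branded_match_fraction=float,
                     lower_score_match_fraction=float, missing_rate=float,
                     fraction_under_two=float, fraction_breastfeeding=float,
                     planted_sodium_reduction_mg=float)
        for key, value in synth_keys.items():
            name = key[len("synth."):]
            if name == "items_per_recall":
                lo, hi = (int(x) for x in value.split(","))
                kwargs[name] = (lo, hi)
            elif name in casts:
                kwargs[name] = casts[name](value)
            else:
                raise ConfigError(f"unknown synth config key {key!r}")
        if seed is not None:
            kwargs["seed"] = seed
        sc = SynthConfig(**kwargs)
        return generate_world(sc), {"synthetic_seed": sc.seed}

    required = ("generic_db", "respondents", "recalls")
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ConfigError(f"config must name input files (or a synth block); "
                          f"missing keys: {missing}")
    paths = {k: (base / cfg[k]).resolve() for k in
             ("generic_db", "branded_db", "matches", "respondents", "recalls")
             if k in cfg}
    generic = load_food_table(paths["generic_db"], GENERIC)
    branded = matches = None
    if "branded_db" in paths:
        branded = load_food_table(paths["branded_db"], BRANDED)
        if "matches" in paths:
            matches = load_matches(paths["matches"], generic, branded)
    respondents = load_respondents(paths["respondents"])
    recalls = load_recalls(paths["recalls"])
    world = World(generic=generic, branded=branded, matches=matches,
                  respondents=respondents, recalls=recalls)
    return world, {"inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                              for k, p in paths.items()}}


def scenario_configs_from(cfg: dict[str, str],
                          scenario_ids: list[str] | None = None) -> list[ScenarioConfig]:
    overrides = {k[len("override."):]: v for k, v in cfg.items()
                 if k.startswith("override.")}
    if scenario_ids is None:
        raw = cfg.get("scenarios", cfg.get("scenario", ""))
        scenario_ids = [s.strip() for s in raw.split(",") if s.strip()]
    if not scenario_ids:
        raise ConfigError("no scenarios requested (set 'scenarios = 1A,1B,2A,2B' "
                          "or pass --scenario)")
    return [ScenarioConfig(sid, overrides=overrides if sid == "2A" else {})
            for sid in scenario_ids]


def run(config_path: str | Path, out_dir: str | Path | None = None,
        scenario_ids: list[str] | None = None,
        seed: int | None = None) -> PipelineResult:
    """Run the full pipeline from a config file; optionally write results.

    Outputs (when ``out_dir`` is given): ``results.csv``, optional
    ``results_subset.csv`` and ``manifest.json``.
    """
    config_path = Path(config_path)
    cfg = read_config(config_path)
    world, provenance = world_from_config(cfg, config_path.parent, seed=seed)
    tables_path = cfg.get("point_tables")
    tables = load_point_tables(
        None if tables_path is None else config_path.parent / tables_path,
        fibre_table=cfg.get("fibre_table", "aoac"))
    scenarios = scenario_configs_from(cfg, scenario_ids)

    prep = prepare_world(world, tables)
    result = run_scenarios(prep, scenarios, tables)
    result.manifest.update(provenance)

    if world.matches is not None and result.prepared.branded is not None:
        cov = match_coverage(prep.recalls, world.matches, prep.generic,
                             result.prepared.branded)
        result.manifest["match_coverage"] = dict(
            n_consumed_foods=cov.n_consumed_foods,
            matched_fraction=cov.matched_fraction,
            lower_score_fraction=cov.lower_score_fraction)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.report.to_csv(out / "results.csv", index=False,
                             float_format="%.6g")
        if result.subset_report is not None:
            result.subset_report.to_csv(out / "results_subset.csv", index=False,
                                        float_format="%.6g")
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                      sort_keys=True))
    return result
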