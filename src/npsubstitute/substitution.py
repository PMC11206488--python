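"""Food-substitution scenarios.

Four scenarios replace consumed foods with same-category alternatives
carrying lower Ofcom scores:

========  =========  ============  ==========================================
scenario  source     rule          substitute
========  =========  ============  ==========================================
1A        branded    optimistic    lowest-scoring branded option(s); ties are
                                   merged into a composite food whose
                                   nutrients are the unweighted mean
1B        branded    realistic     composite over *all* lower-scoring branded
                                   options, nutrients weighted by market share
2A        generic    optimistic    single lowest-scoring generic food; ties
                                   broken by lower calories, then food ID
2B        generic    realistic     generic food at the *next-lowest* score
                                   (the largest score still below the
                                   original's); same tie-breaks as 2A
========  =========  ============  ==========================================

Foods with no strictly lower-scoring same-category option are left as is.
Scenario 2A additionally supports per-category manual overrides — a
designated substitute used for categories (cereal grains, tea, coffee in
the original analysis) whose lowest-scoring member is unrepresentative;
the designated food is used whenever its score does not exceed the
original's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, ValidationError
from .food_db import BRANDED, GENERIC, FoodDatabase
from .matching import MatchTable
from .profiles import (NUTRIENT_FIELDS, FvnLevel, NutrientProfile, PointTables,
                       ofcom_score)

__all__ = ["SCENARIOS", "ScenarioConfig", "SubstitutionResult",
           "candidates", "select_substitute", "apply_scenario"]

SCENARIOS = ("1A", "1B", "2A", "2B")


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario plus its manual per-category overrides.

    ``overrides`` maps category_code -> designated substitute food_id in
    the candidate database.  Overrides are meaningful for scenario 2A (the
    original analysis applied them there and explicitly not to 2B) but are
    honoured for any scenario they are configured on.
    """

    scenario_id: str
    overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario_id not in SCENARIOS:
            raise ConfigError(
                f"scenario_id must be one of {SCENARIOS}, got {self.scenario_id!r}")

    @property
    def candidate_source(self) -> str:
        return BRANDED if self.scenario_id.startswith("1") else GENERIC

    @property
    def rule(self) -> str:
        return "OPTIMISTIC" if self.scenario_id.endswith("A") else "REALISTIC"


@dataclass(frozen=True)
class SubstitutionResult:
    """Outcome for one consumed food under one scenario.

    ``replaced`` is False when no suitable lower-scoring option exists —
    the food is then carried through unchanged.  Composite replacements
    (scenarios 1A/1B with several constituents) receive a synthesized ID
    and a score recomputed from the composite profile.
    """

    original_food_id: str
    replacement_id: str
    profile: NutrientProfile
    score: float
    replaced: bool
    composite: bool = False
    constituents: tuple[str, ...] = ()


def _profile_from_row(row: pd.Series) -> NutrientProfile:
    return NutrientProfile(*(float(row[f]) for f in NUTRIENT_FIELDS),
                           fvn_level=FvnLevel(row["fvn_level"]))


def candidates(food_id: str, scenario: ScenarioConfig,
               generic_db: FoodDatabase, branded_db: FoodDatabase | None,
               matches: MatchTable | None) -> pd.DataFrame:
    """Strictly lower-scoring same-category options for one consumed food.

    Scenario 1 draws on branded foods matched (via the match table) to
    generic foods of the consumed food's category; scenario 2 draws on all
    other generic foods of that category.  The comparison baseline is the
    consumed food's own score.
    """
    row = generic_db.row(food_id)
    original_score = float(row["ofcom_score"])
    category = row["category_code"]
    if scenario.candidate_source == BRANDED:
        if branded_db is None or matches is None:
            raise ConfigError("scenario 1 requires a branded database and matches")
        generic_in_cat = generic_db.category(category).index
        pairs = matches.pairs[matches.pairs["generic_food_id"].isin(generic_in_cat)]
        pool = branded_db.frame.loc[pairs["branded_food_id"].unique()]
    else:
        pool = generic_db.category(category).drop(index=food_id, errors="ignore")
    return pool[pool["ofcom_score"] < original_score]


def _unchanged(food_id: str, row: pd.Series) -> SubstitutionResult:
    return SubstitutionResult(
        original_food_id=food_id, replacement_id=food_id,
        profile=_profile_from_row(row), score=float(row["ofcom_score"]),
        replaced=False)


def _existing(food_id: str, cand: pd.Series, cand_id: str) -> SubstitutionResult:
    return SubstitutionResult(
        original_food_id=food_id, replacement_id=cand_id,
        profile=_profile_from_row(cand), score=float(cand["ofcom_score"]),
        replaced=True)


def _composite(food_id: str, original_score: float, parts: pd.DataFrame,
               weights: np.ndarray, scenario_id: str,
               tables: PointTables | None) -> SubstitutionResult:
    weights = weights / weights.sum()
    nutrients = {
        f: float(np.average(parts[f].to_numpy(dtype=float), weights=weights))
        for f in NUTRIENT_FIELDS}
    # conservative FVN for a synthesized food: the least generous level
    # among constituents
    fvn = min((FvnLevel(v) for v in parts["fvn_level"]),
              key=lambda lv: lv.effective_points)
    profile = NutrientProfile(**nutrients, fvn_level=fvn)
    score = ofcom_score(profile, tables).total_score
    if score >= original_score:
        # averaging point-table nonlinearities can push a blend of
        # individually better foods back above the original; keep the
        # "replacement is strictly better" contract by not substituting
        return None  # caller falls back to unchanged
    return SubstitutionResult(
        original_food_id=food_id,
        replacement_id=f"SUB-{scenario_id}-{food_id}",
        profile=profile, score=float(score), replaced=True, composite=True,
        constituents=tuple(parts.index))


def _tie_break(cands: pd.DataFrame) -> str:
    """Lowest calories first, then lexicographically smallest food ID."""
    order = cands.sort_values(["energy_kcal"], kind="mergesort")
    best_kcal = order["energy_kcal"].iloc[0]
    tied = order[order["energy_kcal"] == best_kcal]
    return sorted(tied.index)[0]


def select_substitute(food_id: str, cands: pd.DataFrame,
                      scenario: ScenarioConfig, generic_db: FoodDatabase,
                      branded_db: FoodDatabase | None = None,
                      tables: PointTables | None = None) -> SubstitutionResult:
    """Apply one scenario's selection rule to a precomputed candidate set."""
    row = generic_db.row(food_id)
    original_score = float(row["ofcom_score"])

    if scenario.scenario_id == "2A" and row["category_code"] in scenario.overrides:
        designated = scenario.overrides[row["category_code"]]
        cand_db = branded_db if scenario.candidate_source == BRANDED else generic_db
        drow = cand_db.row(designated)
        if drow["category_code"] != row["category_code"]:
            raise ValidationError(
                f"override food {designated!r} is not in category "
                f"{row['category_code']!r}")
        if float(drow["ofcom_score"]) <= original_score and designated != food_id:
            return _existing(food_id, drow, designated)
        return _unchanged(food_id, row)

    if len(cands) == 0:
        return _unchanged(food_id, row)

    sid = scenario.scenario_id
    if sid == "1A":
        low = cands[cands["ofcom_score"] == cands["ofcom_score"].min()]
        if len(low) == 1:
            return _existing(food_id, low.iloc[0], low.index[0])
        res = _composite(food_id, original_score, low,
                         np.ones(len(low)), sid, tables)
        return res if res is not None else _unchanged(food_id, row)
    if sid == "1B":
        if len(cands) == 1:
            return _existing(food_id, cands.iloc[0], cands.index[0])
        shares = cands.get("market_share")
        w = (np.nan_to_num(shares.to_numpy(dtype=float), nan=0.0)
             if shares is not None else np.zeros(len(cands)))
        if w.sum() <= 0:
            warnings.warn(
                f"no usable market shares among substitutes for {food_id!r}; "
                f"falling back to an unweighted composite", stacklevel=2)
            w = np.ones(len(cands))
        res = _composite(food_id, original_score, cands, w, sid, tables)
        return res if res is not None else _unchanged(food_id, row)
    if sid == "2A":
        low = cands[cands["ofcom_score"] == cands["ofcom_score"].min()]
        chosen = _tie_break(low)
        return _existing(food_id, low.loc[chosen], chosen)
    # 2B: the largest distinct score still below the original
    next_lowest = cands["ofcom_score"].max()
    tier = cands[cands["ofcom_score"] == next_lowest]
    chosen = _tie_break(tier)
    return _existing(food_id, tier.loc[chosen], chosen)


def apply_scenario(recalls: pd.DataFrame, scenario: ScenarioConfig,
                   generic_db: FoodDatabase,
                   branded_db: FoodDatabase | None = None,
                   matches: MatchTable | None = None,
                   tables: PointTables | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, SubstitutionResult]]:
    """Substitute every distinct consumed food once and build the
    effective food table the recalls are evaluated against.

    Returns ``(effective_foods, substitution_map)``.  ``effective_foods``
    is indexed by the *original* food_id and carries the replacement's
    nutrients, FVN level and score next to the original's category and
    reference amount — grams consumed and reference amounts are retained
    from the original food, only composition and score change.
    """
    distinct = pd.Index(recalls["food_id"].astype(str).unique())
    unknown = distinct.difference(generic_db.food_ids)
    if len(unknown):
        raise IntegrityError(f"recalls reference unknown foods: {sorted(unknown)[:5]}")
    sub_map: dict[str, SubstitutionResult] = {}
    rows = []
    for food_id in distinct:
        cands = candidates(food_id, scenario, generic_db, branded_db, matches)
        res = select_substitute(food_id, cands, scenario, generic_db,
                                branded_db, tables)
        sub_map[food_id] = res
        orig = generic_db.row(food_id)
        rows.append({
            "food_id": food_id,
            "category_code": orig["category_code"],
            "reference_amount_g": float(orig["reference_amount_g"]),
            **{f: getattr(res.profile, f) for f in NUTRIENT_FIELDS},
            "fvn_level": res.profile.fvn_level.value,
            "ofcom_score": res.score,
            "replaced": res.replaced,
            "replacement_id": res.replacement_id,
        })
    effective = pd.DataFrame(rows).set_index("food_id")
    return effective, sub_map


def baseline_foods(recalls: pd.DataFrame,
                   generic_db: FoodDatabase) -> pd.DataFrame:
    """Effective food table with no substitution (the baseline arm)."""
    distinct = pd.Index(recalls["food_id"].astype(str).unique())
    unknown = distinct.difference(generic_db.food_ids)
    if len(unknown):
        raise IntegrityError(f"recalls reference unknown foods: {sorted(unknown)[:5]}")
    cols = ["category_code", "reference_amount_g", *NUTRIENT_FIELDS,
            "fvn_level", "ofcom_score"]
    eff = generic_db.frame.loc[distinct, cols].copy()
    eff["replaced"] = False
    eff["replacement_id"] = eff.index
    return eff
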