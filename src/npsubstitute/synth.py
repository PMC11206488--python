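"""Seeded synthetic worlds: food databases, match tables, recalls, weights.

The generator emulates the statistical shape of the real inputs — a
generic national composition database with category structure, a smaller
branded database whose entries perturb generic parents, a branded-generic
match table covering a small fraction of consumed foods, multi-item 24 h
recalls, and survey main + bootstrap replicate weights — so the whole
pipeline is exercisable without any external data.

Randomness is split from one seed into named substreams (foods,
respondents, weights, recalls, branded, missingness — spawned in that
fixed order from a ``numpy`` ``SeedSequence``), so regeneration is
reproducible stream by stream.

Two planted structures support verification:

* match-coverage planting — the realized fractions of consumed foods with
  a branded match (default 8.0%) and with a strictly lower-scoring match
  (default 2.9%) are planted by construction;
* effect planting — with ``planted_sodium_reduction_mg`` set, every food
  in the planted categories shares its category's profile and has a
  branded substitute whose only difference is sodium lowered by exactly
  that amount, making the population sodium change analytically
  computable from the recalls alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .food_db import BRANDED, GENERIC, FoodDatabase
from .matching import MatchTable
from .profiles import (NUTRIENT_FIELDS, FvnLevel, NutrientProfile, PointTables,
                       default_tables, ofcom_score)

__all__ = ["SynthConfig", "World", "generate_world", "generate_missingness",
           "ARCHETYPES"]


@dataclass(frozen=True)
class Archetype:
    """Nutrient ranges (per 100 g) and FVN assumption of a food family."""

    name: str
    fvn_level: FvnLevel
    energy_kcal: tuple[float, float]
    satfat_g: tuple[float, float]
    sugars_g: tuple[float, float]
    sodium_mg: tuple[float, float]
    fibre_g: tuple[float, float]
    protein_g: tuple[float, float]
    reference_amount_g: tuple[float, float]


#: Category archetypes cycled over generated categories.  Ranges are set
#: so that a day's recall lands in a realistic envelope (roughly
#: 1500-2500 kcal, 1500-3500 mg sodium).
ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("produce", FvnLevel.MAX, (25, 90), (0.0, 0.4), (2, 14),
              (1, 60), (1.0, 5.0), (0.5, 3.0), (80, 150)),
    Archetype("beverage", FvnLevel.MIN, (0, 60), (0.0, 0.3), (0, 12),
              (0, 60), (0.0, 0.5), (0.0, 3.5), (240, 360)),
    Archetype("protein food", FvnLevel.MIN, (100, 400), (1, 15), (0, 6),
              (40, 900), (0.0, 1.0), (8, 30), (55, 120)),
    Archetype("composite dish", FvnLevel.AVERAGED_MID, (90, 350), (1, 10),
              (1, 20), (100, 800), (0.5, 6.0), (3, 15), (150, 300)),
    Archetype("snack", FvnLevel.LOW_MID, (350, 550), (2, 12), (10, 45),
              (100, 700), (1.0, 7.0), (4, 10), (30, 60)),
    Archetype("vegetable dish", FvnLevel.HIGH_MID, (60, 200), (0.5, 5), (2, 12),
              (80, 500), (1.5, 6.0), (2, 8), (100, 200)),
)

_PLANTED_SODIUM_RANGE = (300.0, 880.0)


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults reflect the emulated study shape
    at desk scale (8.0% branded match coverage, 2.9% lower-scoring,
    500 bootstrap replicate weights)."""

    seed: int = 0
    n_respondents: int = 2000
    n_categories: int = 24
    foods_per_category: int = 12
    branded_match_fraction: float = 0.08
    lower_score_match_fraction: float = 0.029
    items_per_recall: tuple[int, int] = (4, 16)
    B: int = 500
    missing_rate: float = 0.0
    fraction_under_two: float = 0.02
    fraction_breastfeeding: float = 0.02
    planted_sodium_reduction_mg: float | None = None
    archetypes: tuple[Archetype, ...] = ARCHETYPES

    def validate(self) -> None:
        if not (0.0 <= self.lower_score_match_fraction
                <= self.branded_match_fraction <= 1.0):
            raise ConfigError(
                "need 0 <= lower_score_match_fraction <= "
                "branded_match_fraction <= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.items_per_recall[0] < 1 or self.items_per_recall[0] > self.items_per_recall[1]:
            raise ConfigError("items_per_recall must be a nonempty (lo, hi) range")
        if self.planted_sodium_reduction_mg is not None:
            d = self.planted_sodium_reduction_mg
            if not (100.0 <= d <= 280.0):
                raise ConfigError(
                    "planted_sodium_reduction_mg must lie in [100, 280] so the "
                    "reduction always crosses a sodium point threshold and "
                    "sodium stays non-negative")


@dataclass
class World:
    """One generated study world."""

    generic: FoodDatabase
    branded: FoodDatabase
    matches: MatchTable
    respondents: pd.DataFrame
    recalls: pd.DataFrame
    planted_categories: tuple[str, ...] = ()
    config: SynthConfig | None = None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five delimited files the pipeline consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "generic": out / "generic_foods.csv",
            "branded": out / "branded_foods.csv",
            "matches": out / "matches.csv",
            "respondents": out / "respondents.csv",
            "recalls": out / "recalls.csv",
        }
        self.generic.frame.drop(columns=["ofcom_score"], errors="ignore") \
            .to_csv(paths["generic"], index=True, index_label="food_id")
        self.branded.frame.drop(columns=["ofcom_score"], errors="ignore") \
            .to_csv(paths["branded"], index=True, index_label="food_id")
        self.matches.pairs.to_csv(paths["matches"], index=False)
        self.respondents.to_csv(paths["respondents"], index=False)
        self.recalls.to_csv(paths["recalls"], index=False)
        return paths


def _draw_in_range(rng: np.random.Generator, lo: float, hi: float,
                   size: int) -> np.ndarray:
    """Log-normal-like positive draw clipped into [lo, hi]."""
    mid = max((lo + hi) / 2.0, 1e-3)
    return np.clip(rng.lognormal(np.log(mid), 0.4, size=size), lo, hi)


def _category_code(i: int) -> str:
    return f"{i + 1:02d}{chr(ord('A') + i % 4)}"


def _score_profile(row: dict, tables: PointTables) -> float:
    prof = NutrientProfile(*(float(row[f]) for f in NUTRIENT_FIELDS),
                           fvn_level=FvnLevel(row["fvn_level"]))
    return ofcom_score(prof, tables).total_score


def _generate_generic(cfg: SynthConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, tuple[str, ...]]:
    rows = []
    planted: list[str] = []
    planted_mode = cfg.planted_sodium_reduction_mg is not None
    fid = 0
    for ci in range(cfg.n_categories):
        arch = cfg.archetypes[ci % len(cfg.archetypes)]
        code = _category_code(ci)
        cat_name = f"{arch.name} ({code})"
        is_planted = planted_mode and ci % 2 == 0
        if is_planted:
            planted.append(code)
            # one shared profile per planted category: every member then has
            # exactly the same composition, so its branded substitute lowers
            # sodium by exactly the planted amount for every consumer
            shared = {f: float(_draw_in_range(rng, *getattr(arch, f), 1)[0])
                      for f in NUTRIENT_FIELDS}
            shared["sodium_mg"] = float(rng.uniform(*_PLANTED_SODIUM_RANGE))
        for k in range(cfg.foods_per_category):
            fid += 1
            if is_planted:
                nutrients = dict(shared)
            else:
                nutrients = {f: float(_draw_in_range(rng, *getattr(arch, f), 1)[0])
                             for f in NUTRIENT_FIELDS}
            rows.append({
                "food_id": f"G{fid:05d}",
                "name": f"{arch.name} {code}-{k + 1}",
                "category_code": code,
                "category_name": cat_name,
                **nutrients,
                "fvn_level": arch.fvn_level.value,
                "reference_amount_g": float(
                    _draw_in_range(rng, *arch.reference_amount_g, 1)[0]),
            })
    return pd.DataFrame(rows).set_index("food_id"), tuple(planted)


def _generate_respondents(cfg: SynthConfig, rng: np.random.Generator,
                          weight_rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_respondents
    ages = rng.uniform(2.0, 90.0, size=n)
    under_two = rng.random(n) < cfg.fraction_under_two
    ages[under_two] = rng.uniform(0.25, 2.0, size=int(under_two.sum()))
    ages[under_two] = np.minimum(ages[under_two], 1.99)
    breastfeeding = (rng.random(n) < cfg.fraction_breastfeeding) & (ages >= 18)
    weights = weight_rng.lognormal(np.log(1000.0), 0.5, size=n)
    # bootstrap-style replicate weights: main weight times independent
    # positive multipliers with mean 1
    mult = weight_rng.gamma(shape=4.0, scale=0.25, size=(n, cfg.B))
    df = pd.DataFrame({
        "respondent_id": [f"R{i + 1:05d}" for i in range(n)],
        "age_years": np.round(ages, 2),
        "breastfeeding": breastfeeding,
        "survey_weight": weights,
    })
    rep = pd.DataFrame(weights[:, None] * mult,
                       columns=[f"replicate_weight_{b + 1}" for b in range(cfg.B)])
    return pd.concat([df, rep], axis=1)


def _generate_recalls(cfg: SynthConfig, generic: pd.DataFrame,
                      respondents: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.items_per_recall
    n_items = rng.integers(lo, hi + 1, size=len(respondents))
    total = int(n_items.sum())
    popularity = rng.lognormal(0.0, 1.0, size=len(generic))
    popularity /= popularity.sum()
    food_idx = rng.choice(len(generic), size=total, p=popularity)
    food_ids = generic.index.to_numpy()[food_idx]
    ref = generic["reference_amount_g"].to_numpy()[food_idx]
    grams = np.clip(ref * rng.lognormal(-0.35, 0.45, size=total), 1.0, 2000.0)
    return pd.DataFrame({
        "respondent_id": np.repeat(respondents["respondent_id"].to_numpy(), n_items),
        "food_id": food_ids,
        "grams_consumed": np.round(grams, 1),
    })


def _perturb_not_lower(parent: dict, rng: np.random.Generator) -> dict:
    """A branded sibling whose score cannot fall below the parent's
    (A-nutrients only increase, favourable nutrients only decrease)."""
    child = dict(parent)
    child["sugars_g"] = parent["sugars_g"] * float(rng.uniform(1.05, 1.35)) + 1.0
    child["sodium_mg"] = parent["sodium_mg"] * float(rng.uniform(1.05, 1.35)) + 25.0
    child["satfat_g"] = parent["satfat_g"] * float(rng.uniform(1.0, 1.25))
    child["fibre_g"] = parent["fibre_g"] * float(rng.uniform(0.7, 1.0))
    return child


def _perturb_lower(parent: dict, parent_score: float,
                   tables: PointTables) -> dict | None:
    """A branded sibling with a strictly lower score, by shrinking the
    unfavourable nutrients; None when the parent is already at the floor."""
    for factor in (0.6, 0.4, 0.25, 0.1, 0.0):
        child = dict(parent)
        for f in ("energy_kcal", "satfat_g", "sugars_g", "sodium_mg"):
            child[f] = parent[f] * factor
        if _score_profile(child, tables) < parent_score:
            return child
    return None


def _generate_branded(cfg: SynthConfig, generic: pd.DataFrame,
                      recalls: pd.DataFrame, rng: np.random.Generator,
                      tables: PointTables) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Branded foods as perturbations of generic parents, planting the
    target match-coverage fractions over distinct consumed foods."""
    consumed = pd.Index(recalls["food_id"].unique())
    m = len(consumed)
    n_matched = int(round(cfg.branded_match_fraction * m))
    n_lower = min(int(round(cfg.lower_score_match_fraction * m)), n_matched)

    order = consumed.to_numpy().copy()
    rng.shuffle(order)
    scores = {fid: _score_profile(generic.loc[fid].to_dict(), tables)
              for fid in order}

    rows, pairs = [], []
    bid = 0

    def add_branded(parent_id: str, child: dict):
        nonlocal bid
        bid += 1
        b_id = f"B{bid:05d}"
        parent = generic.loc[parent_id]
        rows.append({
            "food_id": b_id,
            "name": f"brand of {parent['name']}",
            "category_code": parent["category_code"],
            "category_name": parent["category_name"],
            **{f: child[f] for f in NUTRIENT_FIELDS},
            "fvn_level": child["fvn_level"],
            "reference_amount_g": float(parent["reference_amount_g"]),
            "market_share": float(rng.uniform(0.02, 0.30)),
        })
        pairs.append((parent_id, b_id))

    lower_done = 0
    used = set()
    for fid in order:
        if lower_done >= n_lower:
            break
        parent = generic.loc[fid].to_dict()
        child = _perturb_lower(parent, scores[fid], tables)
        if child is None:
            continue
        add_branded(fid, child)
        used.add(fid)
        lower_done += 1

    not_lower_needed = n_matched - lower_done
    added = 0
    for fid in order:
        if added >= not_lower_needed:
            break
        if fid in used:
            continue
        parent = generic.loc[fid].to_dict()
        add_branded(fid, _perturb_not_lower(parent, rng))
        used.add(fid)
        added += 1

    frame = (pd.DataFrame(rows).set_index("food_id") if rows
             else pd.DataFrame(columns=["name", "category_code", "category_name",
                                        *NUTRIENT_FIELDS, "fvn_level",
                                        "reference_amount_g", "market_share"]))
    return frame, pairs


def _generate_branded_planted(cfg: SynthConfig, generic: pd.DataFrame,
                              planted: tuple[str, ...],
                              rng: np.random.Generator,
                              ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """One branded substitute per planted category: the shared category
    profile with sodium lowered by exactly the planted reduction."""
    delta = float(cfg.planted_sodium_reduction_mg)
    rows, pairs = [], []
    bid = 0
    for code in planted:
        members = generic[generic["category_code"] == code]
        parent_id = members.index[0]
        parent = members.iloc[0]
        bid += 1
        b_id = f"B{bid:05d}"
        nutrients = {f: float(parent[f]) for f in NUTRIENT_FIELDS}
        nutrients["sodium_mg"] = nutrients["sodium_mg"] - delta
        rows.append({
            "food_id": b_id,
            "name": f"reduced-sodium brand of {parent['name']}",
            "category_code": code,
            "category_name": parent["category_name"],
            **nutrients,
            "fvn_level": parent["fvn_level"],
            "reference_amount_g": float(parent["reference_amount_g"]),
            "market_share": float(rng.uniform(0.02, 0.30)),
        })
        pairs.append((parent_id, b_id))
    return pd.DataFrame(rows).set_index("food_id"), pairs


def generate_world(config: SynthConfig) -> World:
    """Generate one deterministic world from the config seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    # fixed spawn order: foods, respondents, weights, recalls, branded, missing
    s_food, s_resp, s_wt, s_recall, s_brand, s_miss = ss.spawn(6)
    tables = default_tables()

    generic_frame, planted = _generate_generic(config, np.random.default_rng(s_food))
    respondents = _generate_respondents(config, np.random.default_rng(s_resp),
                                        np.random.default_rng(s_wt))
    recalls = _generate_recalls(config, generic_frame, respondents,
                                np.random.default_rng(s_recall))

    if config.planted_sodium_reduction_mg is not None:
        branded_frame, pairs = _generate_branded_planted(
            config, generic_frame, planted, np.random.default_rng(s_brand))
    else:
        branded_frame, pairs = _generate_branded(
            config, generic_frame, recalls, np.random.default_rng(s_brand), tables)

    generic_db = FoodDatabase(generic_frame, GENERIC)
    branded_db = FoodDatabase(branded_frame, BRANDED)
    matches = MatchTable.from_pairs(pairs, generic_db, branded_db) if pairs else \
        MatchTable(pairs=pd.DataFrame(columns=["generic_food_id", "branded_food_id"]))

    if config.missing_rate > 0:
        generic_db = generate_missingness(
            generic_db, config.missing_rate,
            np.random.default_rng(s_miss))

    return World(generic=generic_db, branded=branded_db, matches=matches,
                 respondents=respondents, recalls=recalls,
                 planted_categories=planted, config=config)


def generate_missingness(db: FoodDatabase, rate: float,
                         seed: int | np.random.Generator) -> FoodDatabase:
    """Blank nutrient cells independently with probability ``rate``.

    Every (category, nutrient) pair keeps at least one non-missing donor:
    if a draw would blank a pair completely, one member is restored.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError("missingness rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    frame = db.frame.copy()
    mask = rng.random((len(frame), len(NUTRIENT_FIELDS))) < rate
    codes = frame["category_code"].to_numpy()
    for j, nutrient in enumerate(NUTRIENT_FIELDS):
        for code in pd.unique(codes):
            rows = np.flatnonzero(codes == code)
            if mask[rows, j].all() and len(rows) > 0:
                keep = rows[int(rng.integers(len(rows)))]
                mask[keep, j] = False
        col = frame[nutrient].to_numpy(dtype=float)
        col[mask[:, j]] = np.nan
        frame[nutrient] = col
    return FoodDatabase(frame, db.source)
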