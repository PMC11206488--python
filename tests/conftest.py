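import numpy as np
import pandas as pd
import pytest

from npsubstitute import (GENERIC, BRANDED, FoodDatabase, MatchTable,
                          ScenarioConfig, SynthConfig, generate_world,
                          load_point_tables, prepare_world)
from npsubstitute.profiles import NUTRIENT_FIELDS


@pytest.fixture(scope="session")
def tables():
    return load_point_tables()


def make_food_frame(rows):
    """Rows: (food_id, category, kcal, satfat, sugars, sodium, fibre,
    protein, fvn, ref_amount[, market_share])."""
    records = []
    for r in rows:
        rec = dict(zip(("food_id", "category_code", *NUTRIENT_FIELDS,
                        "fvn_level", "reference_amount_g"), r[:10]))
        rec["name"] = f"food {r[0]}"
        rec["category_name"] = f"category {r[1]}"
        if len(r) > 10:
            rec["market_share"] = r[10]
        records.append(rec)
    return pd.DataFrame(records).set_index("food_id")


@pytest.fixture
def small_generic(tables):
    # one category of five foods spanning a range of scores
    frame = make_food_frame([
        ("G1", "10A", 500, 8, 30, 600, 1, 5, "MIN", 50),
        ("G2", "10A", 350, 4, 18, 300, 2, 6, "MIN", 50),
        ("G3", "10A", 100, 1, 5, 100, 3, 4, "MIN", 50),
        ("G4", "10A", 60, 0.2, 4, 40, 2, 2, "MAX", 100),
        ("G5", "10A", 0, 0, 0, 0, 0, 0, "MIN", 240),
    ])
    return FoodDatabase(frame, GENERIC).score_with(tables)


@pytest.fixture(scope="session")
def world():
    """Default small synthetic world, scored and filtered."""
    return generate_world(SynthConfig(seed=11, n_respondents=250, B=40))


@pytest.fixture(scope="session")
def prepared(world):
    return prepare_world(world)


def rng_profiles(n, seed, include_thresholds=True):
    """Random nutrient draws plus exact-threshold stress values."""
    rng = np.random.default_rng(seed)
    kcal = rng.uniform(0, 1200, n)
    satfat = rng.uniform(0, 15, n)
    sugars = rng.uniform(0, 60, n)
    sodium = rng.uniform(0, 1200, n)
    fibre = rng.uniform(0, 8, n)
    protein = rng.uniform(0, 12, n)
    if include_thresholds:
        # place a slice of draws exactly on table thresholds to stress
        # the strict ">" comparisons
        k = min(n // 10, 200)
        satfat[:k] = rng.integers(1, 11, k).astype(float)
        sodium[k:2 * k] = rng.integers(1, 11, k) * 90.0
        sugars[2 * k:3 * k] = rng.choice(
            [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45], k)
        kcal[3 * k:4 * k] = rng.integers(1, 11, k) * 335.0 / 4.184
    levels = np.random.default_rng(seed + 1).choice(
        ["MIN", "LOW_MID", "HIGH_MID", "MAX", "AVERAGED_MID"], n)
    return pd.DataFrame({
        "energy_kcal": kcal, "satfat_g": satfat, "sugars_g": sugars,
        "sodium_mg": sodium, "fibre_g": fibre, "protein_g": protein,
        "fvn_level": levels})
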