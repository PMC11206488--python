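"""Per-respondent daily intakes from 24 h recall line items.

A recall is a set of (respondent_id, food_id, grams_consumed) lines.  Each
line contributes nutrients in proportion to grams (per-100 g composition
times grams / 100) and contributes to the *dietary* nutrient-profile score
through its portion, the grams consumed divided by the food's reference
amount:

    dietary score = sum(score_i * portion_i) / sum(portion_i)

over all foods in the recall — a portion-weighted mean of per-food scores.
Only a single recall day is processed; no usual-intake (between-day)
adjustment is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

log = logging.getLogger(__name__)

__all__ = ["filter_sample", "portion", "dietary_ofcom_score", "daily_totals",
           "daily_intakes", "load_recalls", "load_respondents"]

#: DailyIntake columns, in output order.
INTAKE_COLUMNS = ("dietary_ofcom", "calories_kcal", "satfat_g", "sodium_mg",
                  "sugars_g")

_NUTRIENT_TO_INTAKE = {"energy_kcal": "calories_kcal", "satfat_g": "satfat_g",
                       "sodium_mg": "sodium_mg", "sugars_g": "sugars_g"}


def load_recalls(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"respondent_id": str, "food_id": str})
    missing = [c for c in ("respondent_id", "food_id", "grams_consumed")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    if (df["grams_consumed"] <= 0).any():
        bad = df.index[df["grams_consumed"] <= 0][0]
        raise ValidationError(
            f"{path.name}: grams_consumed must be positive (data row {bad + 1})")
    return df


def load_respondents(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"respondent_id": str})
    required = ("respondent_id", "age_years", "breastfeeding", "survey_weight")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return df


def filter_sample(respondents: pd.DataFrame) -> pd.DataFrame:
    """Apply the analysis sample restrictions.

    Keeps respondents aged 2 years or older who are not breastfeeding.
    A missing age cannot be silently included and raises.
    """
    if respondents["age_years"].isna().any():
        bad = respondents.loc[respondents["age_years"].isna(), "respondent_id"]
        raise ValidationError(
            f"age_years missing for respondent(s) {bad.tolist()[:5]}; "
            f"eligibility cannot be determined")
    keep = (respondents["age_years"] >= 2) & ~respondents["breastfeeding"].astype(bool)
    return respondents[keep]


def portion(grams_consumed: float, reference_amount_g: float) -> float:
    """Portion of one recall line: grams consumed / reference amount."""
    if not reference_amount_g > 0:
        raise ValidationError(
            f"reference_amount_g must be positive, got {reference_amount_g!r}")
    if not grams_consumed > 0:
        raise ValidationError(f"grams_consumed must be positive, got {grams_consumed!r}")
    return grams_consumed / reference_amount_g


def dietary_ofcom_score(items: pd.DataFrame, scores: pd.Series,
                        reference_amounts: pd.Series) -> float:
    """Portion-weighted mean food score for one respondent's recall."""
    if len(items) == 0:
        raise ValidationError("empty recall: dietary score is undefined")
    ids = items["food_id"].astype(str)
    portions = items["grams_consumed"].to_numpy(dtype=float) / \
        reference_amounts.loc[ids].to_numpy(dtype=float)
    s = scores.loc[ids].to_numpy(dtype=float)
    return float(np.sum(s * portions) / np.sum(portions))


def daily_totals(items: pd.DataFrame, foods: pd.DataFrame) -> dict[str, float]:
    """Daily nutrient totals for one respondent (grams x per-100 g / 100)."""
    ids = items["food_id"].astype(str)
    unknown = set(ids) - set(foods.index)
    if unknown:
        raise IntegrityError(f"recall references unknown foods: {sorted(unknown)[:5]}")
    grams = items["grams_consumed"].to_numpy(dtype=float)
    out = {}
    for nutrient, col in _NUTRIENT_TO_INTAKE.items():
        per100 = foods.loc[ids, nutrient].to_numpy(dtype=float)
        out[col] = float(np.sum(grams * per100 / 100.0))
    return out


def daily_intakes(recalls: pd.DataFrame, foods: pd.DataFrame) -> pd.DataFrame:
    """Daily intakes and dietary score for every respondent in the recalls.

    ``foods`` is an effective food table (baseline or post-substitution)
    indexed by the original food_id with per-100 g nutrients,
    ``ofcom_score`` and ``reference_amount_g``.  Returns one row per
    respondent, indexed by respondent_id, with :data:`INTAKE_COLUMNS`.
    """
    ids = recalls["food_id"].astype(str)
    unknown = set(ids) - set(foods.index)
    if unknown:
        raise IntegrityError(f"recalls reference unknown foods: {sorted(unknown)[:5]}")
    lines = pd.DataFrame({
        "respondent_id": recalls["respondent_id"].astype(str).to_numpy(),
        "grams": recalls["grams_consumed"].to_numpy(dtype=float),
    })
    food_rows = foods.loc[ids]
    lines["portion"] = lines["grams"] / food_rows["reference_amount_g"].to_numpy(dtype=float)
    lines["score_x_portion"] = (
        food_rows["ofcom_score"].to_numpy(dtype=float) * lines["portion"].to_numpy())
    for nutrient, col in _NUTRIENT_TO_INTAKE.items():
        lines[col] = lines["grams"] * food_rows[nutrient].to_numpy(dtype=float) / 100.0
    g = lines.groupby("respondent_id")
    agg = g[["portion", "score_x_portion", *_NUTRIENT_TO_INTAKE.values()]].sum()
    agg["dietary_ofcom"] = agg["score_x_portion"] / agg["portion"]
    out = agg[list(INTAKE_COLUMNS)].copy()
    out.index.name = "respondent_id"
    return out
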