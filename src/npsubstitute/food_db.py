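"""Food-composition database loading, validation and median imputation.

A database is a delimited table (CSV or TSV, decided by extension) of one
row per food with per-100 g nutrients, a category code in the style of the
Bureau of Nutritional Sciences groupings (e.g. ``"51B"`` for coffee), a
reference amount in grams, an FVN assumption level and — for branded
sources only — a market share.  Missing nutrient cells stay missing (NaN)
at load time; they are repaired by category-median imputation, mirroring
how national composition databases patch gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError
from .profiles import (NUTRIENT_FIELDS, FvnLevel, NutrientProfile, PointTables,
                       score_frame)

log = logging.getLogger(__name__)

GENERIC = "GENERIC"
BRANDED = "BRANDED"

REQUIRED_COLUMNS = (
    "food_id", "name", "category_code", "category_name",
    *NUTRIENT_FIELDS, "fvn_level", "reference_amount_g",
)


@dataclass(frozen=True)
class FoodRecord:
    """One database entry (a convenience view over a table row)."""

    food_id: str
    source: str
    category_code: str
    category_name: str
    display_name: str
    profile: NutrientProfile
    reference_amount_g: float
    market_share: float | None = None


class FoodDatabase:
    """Category-indexed collection of foods backed by a DataFrame.

    The frame is indexed by ``food_id`` and keeps nutrients as floats with
    NaN for missing cells.  ``score_with`` adds an ``ofcom_score`` column.
    """

    def __init__(self, frame: pd.DataFrame, source: str):
        if source not in (GENERIC, BRANDED):
            raise ValidationError(f"source must be GENERIC or BRANDED, got {source!r}")
        self.source = source
        self.frame = frame
        self._by_category = {code: sub for code, sub in frame.groupby("category_code")}

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.frame.index

    @property
    def food_ids(self) -> pd.Index:
        return self.frame.index

    def category(self, code: str) -> pd.DataFrame:
        """All rows in one category (empty frame for an unknown code)."""
        return self._by_category.get(code, self.frame.iloc[0:0])

    @property
    def category_codes(self) -> list[str]:
        return sorted(self._by_category)

    def row(self, food_id: str) -> pd.Series:
        try:
            return self.frame.loc[food_id]
        except KeyError:
            raise IntegrityError(
                f"unknown food_id {food_id!r} in {self.source} database") from None

    def record(self, food_id: str) -> FoodRecord:
        r = self.row(food_id)
        share = r.get("market_share")
        return FoodRecord(
            food_id=food_id,
            source=self.source,
            category_code=r["category_code"],
            category_name=r["category_name"],
            display_name=r["name"],
            profile=NutrientProfile(
                *(float(r[f]) for f in NUTRIENT_FIELDS),
                fvn_level=FvnLevel(r["fvn_level"])),
            reference_amount_g=float(r["reference_amount_g"]),
            market_share=None if share is None or pd.isna(share) else float(share),
        )

    def records(self) -> Iterator[FoodRecord]:
        for food_id in self.frame.index:
            yield self.record(food_id)

    def has_missing(self) -> bool:
        return bool(self.frame[list(NUTRIENT_FIELDS)].isna().any().any())

    def score_with(self, tables: PointTables | None = None) -> "FoodDatabase":
        """Return a copy whose frame carries an ``ofcom_score`` column."""
        frame = self.frame.copy()
        frame["ofcom_score"] = score_frame(frame, tables)
        return FoodDatabase(frame, self.source)

    @property
    def scores(self) -> pd.Series:
        if "ofcom_score" not in self.frame.columns:
            raise ValidationError("database has not been scored; call score_with()")
        return self.frame["ofcom_score"]


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_food_table(path: str | Path, source: str) -> FoodDatabase:
    """Load and validate one food table.

    Missing nutrient cells are preserved as NaN, never coerced to zero.
    Schema problems, duplicate IDs and negative values are hard errors
    (negative values name the offending 1-based data row).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={"food_id": str,
                                                            "category_code": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path.name}: missing required columns {missing_cols}")
    if source == GENERIC and "market_share" in df.columns and df["market_share"].notna().any():
        raise SchemaError(
            f"{path.name}: market_share values are only valid for BRANDED sources")
    dupes = df["food_id"][df["food_id"].duplicated()].unique()
    if len(dupes):
        raise IntegrityError(f"{path.name}: duplicate food_id(s): {sorted(dupes)}")

    for col in NUTRIENT_FIELDS:
        df[col] = pd.to_numeric(df[col], errors="raise")
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValidationError(
                f"{path.name}: negative {col} at data row {neg[0] + 1} "
                f"(food_id {df.loc[neg[0], 'food_id']!r})")
    df["reference_amount_g"] = pd.to_numeric(df["reference_amount_g"], errors="raise")
    bad_ref = df.index[~(df["reference_amount_g"] > 0)]
    if len(bad_ref):
        raise ValidationError(
            f"{path.name}: reference_amount_g must be positive; bad at data row "
            f"{bad_ref[0] + 1} (food_id {df.loc[bad_ref[0], 'food_id']!r})")
    known_levels = {lv.value for lv in FvnLevel}
    bad_levels = set(df["fvn_level"].astype(str)) - known_levels
    if bad_levels:
        raise ValidationError(f"{path.name}: unknown fvn_level values {sorted(bad_levels)}")
    if source == BRANDED and "market_share" in df.columns:
        df["market_share"] = pd.to_numeric(df["market_share"], errors="raise")
        if (df["market_share"].dropna() < 0).any():
            raise ValidationError(f"{path.name}: negative market_share")
    return FoodDatabase(df.set_index("food_id"), source)


def impute_missing_nutrients(db: FoodDatabase) -> tuple[FoodDatabase, pd.DataFrame]:
    """Replace missing nutrient cells by the category median.

    Each missing cell takes the median of the non-missing values of that
    nutrient within the same ``category_code``; a category with no donor
    for a nutrient falls back to the whole-database median with a warning.
    Non-missing cells are never touched, and the pass is idempotent.

    Returns the repaired database and a log frame with one row per imputed
    cell: ``food_id, nutrient, imputed_value, donor_count, global_fallback``.
    """
    frame = db.frame.copy()
    entries: list[dict] = []
    for nutrient in NUTRIENT_FIELDS:
        col = frame[nutrient]
        if not col.isna().any():
            continue
        cat_median = col.groupby(frame["category_code"]).median()
        cat_count = col.groupby(frame["category_code"]).count()
        global_median = col.median()
        if np.isnan(global_median):
            raise ValidationError(
                f"nutrient {nutrient!r} is missing for every food; cannot impute")
        for food_id in frame.index[col.isna()]:
            cat = frame.at[food_id, "category_code"]
            donors = int(cat_count.get(cat, 0))
            value = cat_median.get(cat, np.nan)
            fallback = donors == 0 or np.isnan(value)
            if fallback:
                value = global_median
                donors = int(col.count())
                warnings.warn(
                    f"no {nutrient} donors in category {cat!r}; "
                    f"imputed food {food_id!r} from the whole-database median",
                    stacklevel=2)
            frame.at[food_id, nutrient] = float(value)
            entries.append(dict(food_id=food_id, nutrient=nutrient,
                                imputed_value=float(value), donor_count=donors,
                                global_fallback=fallback))
    log_frame = pd.DataFrame(
        entries, columns=["food_id", "nutrient", "imputed_value",
                          "donor_count", "global_fallback"])
    return FoodDatabase(frame, db.source), log_frame
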