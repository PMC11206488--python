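"""Branded-to-generic match tables.

The cross-walk between a branded (market) database and the generic
composition database consumed foods are coded against.  Matches are an
*input* artifact here — produced upstream by fuzzy/nutritional-threshold
matching with manual review — and are only validated and indexed:
each branded food maps to at most one generic food, both IDs must exist,
and the pair must share a food category (substitutions are made within a
category, so cross-category pairs are rejected outright).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError
from .food_db import FoodDatabase

__all__ = ["MatchTable", "load_matches", "match_coverage", "CoverageReport"]


@dataclass(frozen=True)
class MatchTable:
    """Validated set of (generic_food_id, branded_food_id) pairs."""

    pairs: pd.DataFrame  # columns: generic_food_id, branded_food_id

    def __len__(self) -> int:
        return len(self.pairs)

    def branded_for(self, generic_food_id: str) -> list[str]:
        sel = self.pairs["generic_food_id"] == generic_food_id
        return self.pairs.loc[sel, "branded_food_id"].tolist()

    def generic_ids(self) -> set[str]:
        return set(self.pairs["generic_food_id"])

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]],
                   generic_db: FoodDatabase,
                   branded_db: FoodDatabase) -> "MatchTable":
        frame = pd.DataFrame(pairs, columns=["generic_food_id", "branded_food_id"])
        return _validate(frame, generic_db, branded_db)


def _validate(frame: pd.DataFrame, generic_db: FoodDatabase,
              branded_db: FoodDatabase) -> MatchTable:
    frame = frame.astype(str).reset_index(drop=True)
    unknown_g = sorted(set(frame["generic_food_id"]) - set(generic_db.food_ids))
    if unknown_g:
        raise IntegrityError(f"match table references unknown generic IDs: {unknown_g}")
    unknown_b = sorted(set(frame["branded_food_id"]) - set(branded_db.food_ids))
    if unknown_b:
        raise IntegrityError(f"match table references unknown branded IDs: {unknown_b}")
    dupes = frame["branded_food_id"][frame["branded_food_id"].duplicated()].unique()
    if len(dupes):
        raise IntegrityError(
            f"branded food(s) matched to more than one generic food: {sorted(dupes)}")
    gcat = generic_db.frame["category_code"]
    bcat = branded_db.frame["category_code"]
    cross = frame[
        gcat.loc[frame["generic_food_id"]].to_numpy()
        != bcat.loc[frame["branded_food_id"]].to_numpy()]
    if len(cross):
        bad = list(cross.itertuples(index=False, name=None))
        raise ValidationError(
            f"match pair(s) span different categories (substitutions are "
            f"within-category): {bad}")
    return MatchTable(pairs=frame)


def load_matches(path: str | Path, generic_db: FoodDatabase,
                 branded_db: FoodDatabase) -> MatchTable:
    """Load a delimited match file (columns generic_food_id, branded_food_id)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    required = ("generic_food_id", "branded_food_id")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return _validate(frame[list(required)], generic_db, branded_db)


@dataclass(frozen=True)
class CoverageReport:
    """Match coverage over the distinct foods reported as consumed."""

    n_consumed_foods: int
    matched_fraction: float        # foods with >= 1 branded match
    lower_score_fraction: float    # foods with >= 1 strictly lower-scoring match


def match_coverage(recalls: pd.DataFrame, matches: MatchTable,
                   generic_db: FoodDatabase,
                   branded_db: FoodDatabase) -> CoverageReport:
    """Fractions of distinct consumed foods with a match / a better match.

    Computed over *distinct* consumed food IDs, so duplicated recall lines
    cannot move the result.  Both databases must be scored.
    """
    consumed = pd.Index(recalls["food_id"].astype(str).unique())
    if len(consumed) == 0:
        return CoverageReport(0, 0.0, 0.0)
    unknown = consumed.difference(generic_db.food_ids)
    if len(unknown):
        raise IntegrityError(f"recalls reference unknown foods: {sorted(unknown)[:5]}")
    gscores = generic_db.scores
    bscores = branded_db.scores

    pairs = matches.pairs[matches.pairs["generic_food_id"].isin(consumed)]
    matched_ids = set(pairs["generic_food_id"])
    lower = pairs[
        bscores.loc[pairs["branded_food_id"]].to_numpy()
        < gscores.loc[pairs["generic_food_id"]].to_numpy()]
    lower_ids = set(lower["generic_food_id"])
    n = len(consumed)
    return CoverageReport(
        n_consumed_foods=n,
        matched_fraction=len(matched_ids) / n,
        lower_score_fraction=len(lower_ids) / n,
    )
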