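"""Ofcom/FSA nutrient-profiling scores.

The model awards "A" points for energy, saturated fat, total sugars and
sodium per 100 g, and subtracts "C" points for fruit/vegetable/nut (FVN)
content, fibre and protein.  Lower totals indicate more favourable
profiles.  Because composition databases rarely state the FVN percentage,
each food carries an *assumption level* instead of a percentage:

``MIN``          no FVN points (content at or below 40%)
``LOW_MID``      1 point (content just above 40%)
``HIGH_MID``     2 points (content just above 60%)
``MAX``          the table maximum, 5 points (content above 80%)
``AVERAGED_MID`` score the food twice, at ``LOW_MID`` and ``HIGH_MID``,
                 and average the two complete totals (used for foods of
                 ambiguous composition, e.g. a fruit-and-nut granola bar)

The point thresholds are loaded from a plain-text table
(:data:`DEFAULT_TABLE_RESOURCE`) so alternate versions can be swapped in.
All threshold comparisons are strict: a food earns a point only when its
value exceeds the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

__all__ = [
    "FvnLevel",
    "NutrientProfile",
    "OfcomComponents",
    "PointTables",
    "load_point_tables",
    "a_points",
    "fvn_points",
    "c_points",
    "ofcom_score",
    "score_frame",
    "NUTRIENT_FIELDS",
]

#: Per-100 g nutrient fields, in the column order used by food tables.
NUTRIENT_FIELDS = (
    "energy_kcal",
    "satfat_g",
    "sugars_g",
    "sodium_mg",
    "fibre_g",
    "protein_g",
)

DEFAULT_TABLE_RESOURCE = "data/ofcom_2004_05.txt"


class FvnLevel(str, Enum):
    """Fruit/vegetable/nut content assumption assigned to a food."""

    MIN = "MIN"
    LOW_MID = "LOW_MID"
    HIGH_MID = "HIGH_MID"
    MAX = "MAX"
    AVERAGED_MID = "AVERAGED_MID"

    @property
    def effective_points(self) -> float:
        """Nominal FVN point value used only for ordering levels
        (AVERAGED_MID sits between LOW_MID and HIGH_MID)."""
        return {"MIN": 0.0, "LOW_MID": 1.0, "AVERAGED_MID": 1.5,
                "HIGH_MID": 2.0, "MAX": 5.0}[self.value]


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g composition of one food plus its FVN assumption level."""

    energy_kcal: float
    satfat_g: float
    sugars_g: float
    sodium_mg: float
    fibre_g: float
    protein_g: float
    fvn_level: FvnLevel = FvnLevel.MIN

    def validate(self) -> None:
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValidationError(f"nutrient field {name!r} is not finite: {v!r}")
            if v < 0:
                raise ValidationError(f"nutrient field {name!r} is negative: {v!r}")
        if not isinstance(self.fvn_level, FvnLevel):
            raise ValidationError(f"fvn_level is not a FvnLevel: {self.fvn_level!r}")


@dataclass(frozen=True)
class OfcomComponents:
    """Decomposed Ofcom score for one food.

    For a single-level FVN assumption ``total_score == a_points - c_points``.
    Under ``AVERAGED_MID`` the food is scored completely at ``LOW_MID`` and
    ``HIGH_MID`` and ``total_score`` is the mean of the two totals (always a
    multiple of 0.5); ``c_points`` and ``protein_capped`` then report the
    ``LOW_MID`` evaluation and the two full totals are kept in
    ``score_low`` / ``score_high``.
    """

    a_points: int
    c_points: int
    protein_capped: bool
    total_score: float
    score_low: float | None = None
    score_high: float | None = None


@dataclass(frozen=True)
class PointTables:
    """Threshold tables and constants of one version of the scoring model."""

    version: str
    energy_kj: tuple[float, ...]
    satfat_g: tuple[float, ...]
    sugars_g: tuple[float, ...]
    sodium_mg: tuple[float, ...]
    fvn_points_by_level: tuple[float, ...]  # (MIN, LOW_MID, HIGH_MID, MAX)
    fibre_aoac_g: tuple[float, ...]
    fibre_nsp_g: tuple[float, ...]
    protein_g: tuple[float, ...]
    protein_cap_a_points: int
    kcal_to_kj: float = 4.184
    fibre_table: str = "aoac"  # "aoac" or "nsp"

    @property
    def fibre_thresholds(self) -> tuple[float, ...]:
        return self.fibre_aoac_g if self.fibre_table == "aoac" else self.fibre_nsp_g

    @property
    def max_fvn_points(self) -> float:
        return self.fvn_points_by_level[-1]

    def with_fibre_table(self, which: str) -> "PointTables":
        if which not in ("aoac", "nsp"):
            raise ConfigError(f"fibre_table must be 'aoac' or 'nsp', got {which!r}")
        return replace(self, fibre_table=which)


def _parse_numbers(text: str) -> tuple[float, ...]:
    return tuple(float(tok) for tok in text.split(","))


def load_point_tables(path: str | Path | None = None,
                      fibre_table: str = "aoac") -> PointTables:
    """Load a point-table config (key = value lines, '#' comments).

    With no path, the packaged 2004-05 tables are used.
    """
    if path is None:
        text = (resources.files(__package__) / DEFAULT_TABLE_RESOURCE).read_text()
    else:
        text = Path(path).read_text()
    kv: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"point-table line is not 'key = value': {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        kv[key] = val
    try:
        tables = PointTables(
            version=kv.get("version", "unversioned"),
            energy_kj=_parse_numbers(kv["energy_kj"]),
            satfat_g=_parse_numbers(kv["satfat_g"]),
            sugars_g=_parse_numbers(kv["sugars_g"]),
            sodium_mg=_parse_numbers(kv["sodium_mg"]),
            fvn_points_by_level=_parse_numbers(kv["fvn_points"]),
            fibre_aoac_g=_parse_numbers(kv["fibre_aoac_g"]),
            fibre_nsp_g=_parse_numbers(kv["fibre_nsp_g"]),
            protein_g=_parse_numbers(kv["protein_g"]),
            protein_cap_a_points=int(kv["protein_cap_a_points"]),
            kcal_to_kj=float(kv.get("kcal_to_kj", "4.184")),
            fibre_table=fibre_table,
        )
    except KeyError as exc:
        raise ConfigError(f"point-table file missing key {exc.args[0]!r}") from exc
    for name in ("energy_kj", "satfat_g", "sugars_g", "sodium_mg"):
        thr = getattr(tables, name)
        if list(thr) != sorted(thr):
            raise ConfigError(f"thresholds for {name} are not ascending")
    return tables


_DEFAULT_TABLES: PointTables | None = None


def default_tables() -> PointTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_point_tables()
    return _DEFAULT_TABLES


def _points(value: float, thresholds: Sequence[float]) -> int:
    # strict comparison: number of thresholds strictly below the value
    return int(np.searchsorted(thresholds, value, side="left"))


def a_points(profile: NutrientProfile, tables: PointTables | None = None) -> int:
    """Sum of the four unfavourable-component point scores (0-40).

    Energy is converted from kcal to kJ before lookup; every lookup is
    strict ("> threshold" earns the point) and monotone in its nutrient.
    """
    tables = tables or default_tables()
    profile.validate()
    return (
        _points(profile.energy_kcal * tables.kcal_to_kj, tables.energy_kj)
        + _points(profile.satfat_g, tables.satfat_g)
        + _points(profile.sugars_g, tables.sugars_g)
        + _points(profile.sodium_mg, tables.sodium_mg)
    )


def fvn_points(fvn_level: FvnLevel, tables: PointTables | None = None) -> float:
    """FVN point value for one concrete assumption level.

    ``AVERAGED_MID`` has no single point value (averaging happens at the
    score level, never on the points) and is rejected.
    """
    tables = tables or default_tables()
    if fvn_level == FvnLevel.AVERAGED_MID:
        raise ValidationError(
            "AVERAGED_MID has no single FVN point value; score the food at "
            "LOW_MID and HIGH_MID and average the totals")
    idx = {FvnLevel.MIN: 0, FvnLevel.LOW_MID: 1,
           FvnLevel.HIGH_MID: 2, FvnLevel.MAX: 3}[fvn_level]
    return tables.fvn_points_by_level[idx]


def c_points(profile: NutrientProfile, a: int,
             tables: PointTables | None = None) -> tuple[int, bool]:
    """Favourable-component points (FVN + fibre + protein) and the cap flag.

    Protein points are withheld when ``a`` reaches the cap (11 in the
    2004-05 model) unless the food holds maximum FVN points.
    """
    tables = tables or default_tables()
    profile.validate()
    fvn = fvn_points(profile.fvn_level, tables)
    fibre = _points(profile.fibre_g, tables.fibre_thresholds)
    protein = _points(profile.protein_g, tables.protein_g)
    capped = a >= tables.protein_cap_a_points and fvn < tables.max_fvn_points
    total = fvn + fibre + (0 if capped else protein)
    return int(total), capped


def _score_single(profile: NutrientProfile, tables: PointTables) -> OfcomComponents:
    a = a_points(profile, tables)
    c, capped = c_points(profile, a, tables)
    return OfcomComponents(a_points=a, c_points=c, protein_capped=capped,
                           total_score=float(a - c))


def ofcom_score(profile: NutrientProfile,
                tables: PointTables | None = None) -> OfcomComponents:
    """Complete Ofcom score of a food.

    Single-level FVN assumptions give ``a - c``.  ``AVERAGED_MID``
    computes two full scores, at ``LOW_MID`` and ``HIGH_MID``, with the
    protein cap re-evaluated at each level, and averages the totals.
    """
    tables = tables or default_tables()
    if profile.fvn_level != FvnLevel.AVERAGED_MID:
        return _score_single(profile, tables)
    low = _score_single(replace(profile, fvn_level=FvnLevel.LOW_MID), tables)
    high = _score_single(replace(profile, fvn_level=FvnLevel.HIGH_MID), tables)
    return OfcomComponents(
        a_points=low.a_points,
        c_points=low.c_points,
        protein_capped=low.protein_capped,
        total_score=(low.total_score + high.total_score) / 2.0,
        score_low=low.total_score,
        score_high=high.total_score,
    )


# ---------------------------------------------------------------------------
# vectorised scoring over food tables


def _frame_points(values: pd.Series, thresholds: Sequence[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(thresholds), values.to_numpy(dtype=float),
                           side="left")


def _frame_score_at_level(df: pd.DataFrame, fvn: np.ndarray,
                          tables: PointTables) -> np.ndarray:
    """Total score for every row at per-row FVN point values ``fvn``."""
    a = (
        _frame_points(df["energy_kcal"] * tables.kcal_to_kj, tables.energy_kj)
        + _frame_points(df["satfat_g"], tables.satfat_g)
        + _frame_points(df["sugars_g"], tables.sugars_g)
        + _frame_points(df["sodium_mg"], tables.sodium_mg)
    )
    fibre = _frame_points(df["fibre_g"], tables.fibre_thresholds)
    protein = _frame_points(df["protein_g"], tables.protein_g)
    capped = (a >= tables.protein_cap_a_points) & (fvn < tables.max_fvn_points)
    c = fvn + fibre + np.where(capped, 0, protein)
    return a - c


def score_frame(df: pd.DataFrame, tables: PointTables | None = None) -> pd.Series:
    """Ofcom total score for every row of a food table.

    Expects the per-100 g nutrient columns of :data:`NUTRIENT_FIELDS` plus
    ``fvn_level`` (strings).  Missing nutrient cells must already be
    imputed.  Returns a float Series aligned to ``df.index``.
    """
    tables = tables or default_tables()
    nut = df[list(NUTRIENT_FIELDS)]
    if nut.isna().any().any():
        bad = nut.columns[nut.isna().any()].tolist()
        raise ValidationError(
            f"cannot score foods with missing nutrients (impute first): {bad}")
    if (nut < 0).any().any():
        bad = nut.columns[(nut < 0).any()].tolist()
        raise ValidationError(f"negative nutrient values in columns: {bad}")
    levels = df["fvn_level"].astype(str)
    known = {lv.value for lv in FvnLevel}
    unknown = set(levels.unique()) - known
    if unknown:
        raise ValidationError(f"unknown fvn_level values: {sorted(unknown)}")

    pts = {FvnLevel.MIN.value: tables.fvn_points_by_level[0],
           FvnLevel.LOW_MID.value: tables.fvn_points_by_level[1],
           FvnLevel.HIGH_MID.value: tables.fvn_points_by_level[2],
           FvnLevel.MAX.value: tables.fvn_points_by_level[3]}
    averaged = (levels == FvnLevel.AVERAGED_MID.value).to_numpy()
    fvn = levels.map(lambda s: pts.get(s, np.nan)).to_numpy(dtype=float)

    out = np.empty(len(df), dtype=float)
    plain = ~averaged
    if plain.any():
        out[plain] = _frame_score_at_level(df.loc[plain], fvn[plain], tables)
    if averaged.any():
        sub = df.loc[averaged]
        low = _frame_score_at_level(
            sub, np.full(len(sub), pts[FvnLevel.LOW_MID.value]), tables)
        high = _frame_score_at_level(
            sub, np.full(len(sub), pts[FvnLevel.HIGH_MID.value]), tables)
        out[averaged] = (low + high) / 2.0
    return pd.Series(out, index=df.index, name="ofcom_score")
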