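"""Survey-weighted estimation with bootstrap replicate weights.

Point estimates are weighted means under the main survey weight; sampling
variance follows the Statistics Canada mean-bootstrap convention for
survey replicate weights,

    var(theta_hat) = (1/B) * sum_b (theta_hat_b - theta_hat)^2,

with theta_hat_b the estimate recomputed under replicate weight set b and
no Fay adjustment.  Scenario-versus-baseline contrasts are paired: the
per-respondent difference is the analysis variable, its weighted mean and
replicate SE form a t statistic referred to a t distribution with B - 1
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .intake import INTAKE_COLUMNS

__all__ = ["SurveyDesign", "WeightedEstimate", "PairedTest", "weighted_mean",
           "replicate_variance", "paired_scenario_test", "scenario_report",
           "subset_recalls"]

Z_95 = 1.96
ALPHA = 0.05


@dataclass(frozen=True)
class SurveyDesign:
    """Main weight plus B replicate weight vectors per respondent."""

    respondent_ids: pd.Index
    weights: np.ndarray          # shape (n,)
    replicate_weights: np.ndarray  # shape (n, B)

    def __post_init__(self):
        n = len(self.respondent_ids)
        if self.weights.shape != (n,):
            raise ValidationError("weights must be one per respondent")
        if self.replicate_weights.ndim != 2 or self.replicate_weights.shape[0] != n:
            raise ValidationError("replicate_weights must be an (n, B) matrix")
        if (self.weights <= 0).any():
            raise ValidationError("survey weights must be positive")
        if (self.replicate_weights < 0).any():
            raise ValidationError("replicate weights must be non-negative")

    @property
    def B(self) -> int:
        return self.replicate_weights.shape[1]

    @classmethod
    def from_frame(cls, respondents: pd.DataFrame) -> "SurveyDesign":
        """Build from a respondent table with ``survey_weight`` and
        ``replicate_weight_1..B`` columns."""
        rep_cols = sorted(
            (c for c in respondents.columns if c.startswith("replicate_weight_")),
            key=lambda c: int(c.rsplit("_", 1)[1]))
        if not rep_cols:
            raise ValidationError("respondent table has no replicate_weight_* columns")
        return cls(
            respondent_ids=pd.Index(respondents["respondent_id"].astype(str)),
            weights=respondents["survey_weight"].to_numpy(dtype=float),
            replicate_weights=respondents[rep_cols].to_numpy(dtype=float),
        )

    def subset(self, respondent_ids: pd.Index) -> "SurveyDesign":
        pos = pd.Index(self.respondent_ids).get_indexer(respondent_ids)
        if (pos < 0).any():
            missing = respondent_ids[pos < 0]
            raise ValidationError(
                f"respondents absent from the design: {missing.tolist()[:5]}")
        return SurveyDesign(pd.Index(respondent_ids), self.weights[pos],
                            self.replicate_weights[pos])


@dataclass(frozen=True)
class WeightedEstimate:
    estimate: float
    standard_error: float
    ci_low: float
    ci_high: float
    n: int
    B: int


@dataclass(frozen=True)
class PairedTest:
    estimate: float       # weighted mean scenario-minus-baseline difference
    standard_error: float
    t_statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValidationError("values and weights must have equal length")
    if (weights < 0).any():
        raise ValidationError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("sum of weights must be positive")
    return float(values @ weights / total)


def replicate_variance(values: np.ndarray, design: SurveyDesign) -> WeightedEstimate:
    """Weighted mean with mean-bootstrap replicate variance and 95% CI.

    Replicates whose weights sum to zero carry no information and are
    dropped (with a warning), reducing the effective B.
    """
    values = np.asarray(values, dtype=float)
    if design.B == 0:
        raise ValidationError("design has no replicate weights (B = 0)")
    est = weighted_mean(values, design.weights)
    rep = design.replicate_weights
    col_sums = rep.sum(axis=0)
    usable = col_sums > 0
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} replicate(s) with zero total weight",
            stacklevel=2)
        rep = rep[:, usable]
        col_sums = col_sums[usable]
    B = rep.shape[1]
    if B == 0:
        raise ValidationError("no usable replicates remain")
    theta_b = (values @ rep) / col_sums
    variance = float(np.sum((theta_b - est) ** 2) / B)
    se = float(np.sqrt(variance))
    return WeightedEstimate(estimate=est, standard_error=se,
                            ci_low=est - Z_95 * se, ci_high=est + Z_95 * se,
                            n=len(values), B=B)


def paired_scenario_test(baseline: pd.Series, scenario: pd.Series,
                         design: SurveyDesign) -> PairedTest:
    """Paired scenario-minus-baseline contrast for one outcome.

    Both series must be indexed by respondent_id and cover exactly the
    design's respondents.
    """
    for arm, name in ((baseline, "baseline"), (scenario, "scenario")):
        if not pd.Index(arm.index).equals(pd.Index(design.respondent_ids)):
            if set(arm.index) != set(design.respondent_ids):
                raise ValidationError(
                    f"{name} respondents do not match the survey design")
    d = (scenario.loc[design.respondent_ids].to_numpy(dtype=float)
         - baseline.loc[design.respondent_ids].to_numpy(dtype=float))
    we = replicate_variance(d, design)
    if we.standard_error == 0:
        t = 0.0 if we.estimate == 0 else np.inf * np.sign(we.estimate)
        p = 1.0 if we.estimate == 0 else 0.0
    else:
        t = we.estimate / we.standard_error
        p = float(2 * stats.t.sf(abs(t), df=we.B - 1))
    return PairedTest(estimate=we.estimate, standard_error=we.standard_error,
                      t_statistic=float(t), df=we.B - 1, p_value=p)


def scenario_report(baseline: pd.DataFrame,
                    scenarios: dict[str, pd.DataFrame],
                    design: SurveyDesign) -> pd.DataFrame:
    """Results table: one row per arm x outcome.

    ``baseline`` and each scenario frame are per-respondent daily intakes
    (index respondent_id, columns :data:`INTAKE_COLUMNS`).  Baseline rows
    carry no significance flag; scenario rows add the paired contrast
    against baseline.
    """
    rows = []
    order = design.respondent_ids

    def estimate_rows(arm_name: str, intakes: pd.DataFrame,
                      base: pd.DataFrame | None):
        for outcome in INTAKE_COLUMNS:
            values = intakes.loc[order, outcome].to_numpy(dtype=float)
            we = replicate_variance(values, design)
            row = dict(arm=arm_name, outcome=outcome, estimate=we.estimate,
                       standard_error=we.standard_error, ci_low=we.ci_low,
                       ci_high=we.ci_high, n=we.n, B=we.B,
                       diff=np.nan, diff_se=np.nan, p_value=np.nan,
                       significant="")
            if base is not None:
                test = paired_scenario_test(base[outcome], intakes[outcome], design)
                row.update(diff=test.estimate, diff_se=test.standard_error,
                           p_value=test.p_value,
                           significant="*" if test.significant else "")
            rows.append(row)

    estimate_rows("baseline", baseline, None)
    for name, intakes in scenarios.items():
        estimate_rows(name, intakes, baseline)
    return pd.DataFrame(rows)


def subset_recalls(recalls: pd.DataFrame,
                   substituted_food_ids: set[str]) -> pd.DataFrame:
    """Restrict recall lines to foods in ``substituted_food_ids``.

    Used for the substituted-foods-only subset analysis: respondents with
    no remaining lines drop out of the subset (its n is therefore the
    number of respondents who consumed at least one substitutable food).
    """
    keep = recalls["food_id"].astype(str).isin(substituted_food_ids)
    return recalls[keep]
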