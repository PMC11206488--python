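# Methods

This note documents the models and procedures `npsubstitute` implements,
the defaults it ships, and the choices made where the design was open.

## The nutrient-profiling score

The package implements the UK FSA/Ofcom 2004–05 nutrient-profiling model.
Per 100 g of food, "A" points are awarded for energy (kJ), saturated fat
(g), total sugars (g) and sodium (mg) — up to 10 points each from
ascending threshold tables — and "C" points for fruit/vegetable/nut (FVN)
content (0/1/2/5), fibre (0–5) and protein (0–5). The total is A − C;
lower is more favourable. Protein points are withheld when A ≥ 11 unless
FVN points are at their maximum (5). All threshold comparisons are
strict: a value exactly at a threshold earns nothing.

Implementation choices:

- **Tables as data.** The thresholds live in a versioned plain-text file
  (`src/npsubstitute/data/ofcom_2004_05.txt`) loaded at run time, so
  alternate table versions can be swapped without code changes.
- **Energy units.** North American composition databases report kcal;
  the model's energy table is in kJ. Values are converted by
  × 4.184 before lookup.
- **Fibre definition.** The guidance distinguishes NSP from AOAC fibre
  thresholds. AOAC is the default because North American databases report
  AOAC fibre; NSP is selectable (`load_point_tables(fibre_table="nsp")`).
- **FVN assumption levels.** Ingredient lists are typically unavailable,
  so foods carry an assumed FVN level rather than a percentage: `MIN`
  (0 points), `LOW_MID` (>40%, 1), `HIGH_MID` (>60%, 2), `MAX` (>80%, 5),
  or `AVERAGED_MID` for foods of ambiguous composition. `AVERAGED_MID`
  computes two *complete* scores — at `LOW_MID` and at `HIGH_MID`, with
  the protein cap re-evaluated independently each time — and averages the
  totals. Averaging the FVN points before scoring would be wrong because
  the cap rule is nonlinear in FVN points. Averaged totals are multiples
  of 0.5 and are carried as floats; score ties downstream use exact
  floating-point equality, which is safe because every representable
  value is a multiple of 0.5.

## Databases and imputation

Food tables are delimited files (CSV/TSV by extension) with per-100 g
nutrients, a category code, a reference amount (g), an FVN level and —
for branded sources — a market share. Missing nutrient cells are kept
missing at load (never coerced to zero) and repaired by **category-median
imputation**: each gap takes the median of non-missing same-category
values of that nutrient. The median of an even donor count is the mean of
the central pair. A category with no donor falls back to the
whole-database median with a warning. Imputation is idempotent and never
touches observed cells. A missing reference amount is an error, not
imputable: it scales every portion and a silent default would corrupt
dietary scores.

Branded↔generic match tables are **inputs**, not computed: producing them
(fuzzy name matching, nutritional-distance thresholds, dietitian review)
is a separate task. Loading validates that both IDs exist, that each
branded food maps to at most one generic food, and that pairs share a
category — substitutions are within-category, so cross-category matches
are rejected outright. Coverage (the fraction of distinct consumed foods
with a match, and with a strictly lower-scoring match) is computed over
distinct food IDs, making it invariant to duplicated recall lines.

## Substitution scenarios

For each distinct consumed food, candidates are same-category
alternatives with a strictly lower score than the consumed food's own
score. Scenario 1 draws candidates from branded foods matched to generic
foods of the category; scenario 2 from the generic database itself. Foods
with no qualifying candidate are left as is.

- **1A (branded, optimistic):** candidates tied at the minimum score; if
  several, a composite food is synthesized whose every nutrient is their
  unweighted mean, under a new food ID, with the score *recomputed* from
  the composite profile.
- **1B (branded, realistic):** a composite over *all* lower-scoring
  candidates, nutrients weighted by market share (shares renormalised
  over the candidate subset; all-zero or absent shares fall back to the
  unweighted mean with a warning).
- **2A (generic, optimistic):** the minimum-score candidate; ties broken
  by lower calories, then lexicographically smaller food ID.
- **2B (generic, realistic):** the candidate at the *next-lowest* score —
  the largest distinct score still below the original's — with the same
  tie-breaks.

Composite details: the composite inherits the original food's reference
amount (keeping baseline and scenario portions comparable) and the least
generous FVN level among its constituents (conservative: a synthesized
food should not gain C-points its parts did not all have). Because point
tables are nonlinear, a blend of individually better foods can
occasionally score at or above the original; such composites are **not
applied** and the food is left as is, preserving the invariant that every
applied replacement strictly lowers the per-food score.

Per-category **manual overrides** designate a fixed substitute for
categories whose lowest-scoring member is unrepresentative (the
motivating cases are cereal grains, tea and coffee, where a low-scoring
but calorie-dense powder would otherwise be chosen and inflate energy
intake). Overrides apply to scenario 2A; the designated food is used
whenever its score does not exceed the original's. Because override
targets are food IDs specific to a given database, no overrides ship by
default; they are supplied per run (`override.<category> = <food_id>`).

Substitution replaces composition and score only: grams consumed and
reference amounts are retained from the original food. Energy intake can
therefore rise under a scenario (substitutes lower in score are not
always lower in calories) even though the dietary score cannot. The
substitution map is computed once per distinct food and shared across
respondents, making runs deterministic.

## Intakes and the dietary score

Respondents aged under 2 years or breastfeeding are excluded; a missing
age is an error rather than a silent inclusion. A single recall day is
processed; no usual-intake (between-day variance) adjustment is made.
Each line contributes `grams × per-100 g / 100` to daily calorie,
saturated-fat, sodium and sugar totals, and its portion
(`grams / reference amount`) weights the food's score in the dietary
score. The denominator includes every consumed food, substituted or not.
A respondent with no recall lines is excluded with a warning — assigning
zero would distort scenario means.

## Survey estimation

Point estimates are weighted means under the main survey weight.
Variance follows the Statistics Canada bootstrap convention for
survey-provided replicate weights: the estimate is recomputed under each
of the B replicate weight vectors and

    var = (1/B) · Σ_b (θ̂_b − θ̂)²

with no Fay factor. 95% intervals use ±1.96·SE. Baseline-vs-scenario
contrasts are paired: the per-respondent difference is the analysis
variable; its weighted mean over its replicate SE is referred to a t
distribution with B − 1 degrees of freedom (a replicate-based choice;
with hundreds of replicates it is indistinguishable from normal).
Replicates whose weights sum to zero are dropped with a warning. B
defaults to 500 in the generator; the test suite uses B = 50 and worlds
of a few hundred to 2,000 respondents, sizes at which every estimator
property under test is already exercised.

The subset analysis restricts recall lines to foods that received a
scenario-1 substitution and recomputes baseline and scenario-1 intakes
over that subset; its n is the number of respondents who consumed at
least one such food.

## The synthetic generator

`generate_world` emulates the structure the pipeline assumes: categories
cycle through archetypes (produce, beverage, protein food, composite
dish, snack, vegetable dish) that set nutrient ranges, FVN levels and
reference amounts; nutrients are log-normal draws clipped to the
archetype range; recalls draw 4–16 items per respondent with
log-normal portion sizes (calibrated so a synthetic day lands near
1,800 kcal); replicate weights are the main weight times independent
gamma multipliers with mean 1. All randomness flows from one seed through
named substreams spawned in a fixed order (foods, respondents, weights,
recalls, branded, missingness), so worlds are reproducible stream by
stream.

Two structures are planted for verification:

- **Coverage planting.** Branded foods are built as perturbations of
  generic parents: shrinking the unfavourable nutrients yields a
  strictly lower-scoring match, inflating them (and trimming fibre)
  a never-lower one, by monotonicity. Defaults plant 8.0% of distinct
  consumed foods with a match and 2.9% with a lower-scoring match.
- **Effect planting.** With `planted_sodium_reduction_mg = δ`, every
  other category shares a single profile across its foods, with sodium
  drawn in (300, 880) mg, and carries one branded substitute identical
  except for sodium lowered by exactly δ. For δ ∈ [100, 280] the
  reduction always crosses at least one 90 mg sodium threshold, so the
  substitute strictly improves and is applied to every food in the
  category; the population sodium change is then computable directly
  from recall grams, giving the pipeline an analytic target it matches
  to floating-point precision.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: realistic demographic structure
and design effects in the weights, correlation between food popularity
and nutrient content, day-to-day intake variability, measurement/recall
error, or nutrient distributions fitted to any real composition
database. Results on synthetic worlds validate the machinery, not any
substantive dietary claim.

## Known limitations

- Only means are estimated (no quantiles or ratio estimators), and no
  multiple-testing correction is applied across the five outcomes.
- The consumed food's own score is the comparison baseline for branded
  candidates; analyses that compare against a matched generic twin's
  score instead would need a one-line change in `candidates`.
- Composite substitutes in 1B include only strictly lower-scoring
  candidates; options tied with the original are excluded.
- The scoring model's pass/fail "healthier" classification thresholds
  are out of scope; only the continuous score is used.
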