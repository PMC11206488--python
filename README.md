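# npsubstitute

Nutrient-profile scoring and food-substitution scenario modelling for
24 h dietary recall surveys.

## What this package is for

Nutrient-profiling (NP) systems score foods by their composition so that
policies — front-of-package labels, marketing restrictions, reformulation
targets — can distinguish more and less favourable products. A natural
policy question follows: *if consumers swapped the foods they actually eat
for similar, better-scoring alternatives, how much would population
intakes of calories, saturated fat, sodium and sugars change?*

`npsubstitute` implements that modelling exercise as a reusable,
tested pipeline for researchers in nutritional epidemiology:

1. score every food in a composition database with the UK FSA/Ofcom
   2004–05 nutrient-profiling model;
2. substitute each consumed food with a same-category alternative that has
   a more favourable score, under four scenarios (branded vs. generic
   candidate pools × optimistic vs. realistic selection rules);
3. aggregate 24 h recalls into per-respondent daily intakes and a
   *dietary* score;
4. estimate population means and baseline-vs-scenario contrasts with
   survey weights and bootstrap replicate-weight variance.

Because the national survey, composition and market databases such
analyses use are not redistributable, the package ships a synthetic-data
generator that emulates their statistical structure (category-structured
nutrient distributions, sparse branded matches, multi-item recalls,
replicate weights), so every stage is testable end to end.

## The score

For a food with per-100 g composition, "A" points accrue for
unfavourable components and "C" points for favourable ones:

```
A = pts(energy kJ) + pts(saturated fat g) + pts(total sugars g) + pts(sodium mg)   (0–10 each)
C = pts(fruit/veg/nut %) + pts(fibre g) + pts(protein g)                            (0/1/2/5, 0–5, 0–5)
score = A − C
```

Each `pts(·)` is a strict threshold lookup (a point is earned only
*above* a threshold); protein points are withheld when A ≥ 11 unless the
food holds maximum fruit/veg/nut (FVN) points. Lower scores are more
favourable. Because composition databases rarely state the FVN
percentage, each food carries an assumption level instead: `MIN`,
`LOW_MID` (>40%, 1 point), `HIGH_MID` (>60%, 2 points), `MAX` (>80%,
5 points), or `AVERAGED_MID` — score the food at both middling levels and
average the two totals (giving half-integer scores).

A respondent's recall is summarised by the portion-weighted dietary score

```
portion_i = grams consumed_i / reference amount_i
dietary score = Σ(score_i × portion_i) / Σ portion_i
```

and by daily nutrient totals `Σ grams_i × per-100 g value_i / 100`.

Scenario rules, imputation, the bootstrap variance convention and all
numerical choices are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
from npsubstitute import (ScenarioConfig, SynthConfig, generate_world,
                          prepare_world, run_scenarios)

world = generate_world(SynthConfig(seed=42, n_respondents=500, B=50))
prep = prepare_world(world)   # impute -> score -> filter sample
res = run_scenarios(prep, [ScenarioConfig(s) for s in ("1A", "1B", "2A", "2B")])
print(res.report)
```

Running `python examples/run_substitution_scenarios.py` (which wraps the
above) prints:

```
respondents retained: 479 of 500; 4789 recall lines
branded match coverage: 7.9% matched, 2.9% with a lower score

survey-weighted means (dietary score, daily intakes):
  baseline  score  7.45  kcal  1780.2  satfat  37.1  sodium  3302.7  sugars 112.2
  1A        score  3.28* kcal  1493.7* satfat  28.6* sodium  2685.6* sugars  98.7*
  1B        score  3.88* kcal  1511.2* satfat  28.9* sodium  2817.6* sugars  99.0*
  2A        score  2.22* kcal  1502.5* satfat  22.6* sodium  2293.2* sugars  77.9*
  2B        score  6.21* kcal  1577.0* satfat  35.6* sodium  2984.7* sugars  97.6*
```

Each row is a survey-weighted population mean under one scenario; `*`
flags a paired contrast against baseline with p < 0.05 under the
replicate-weight t test. Substitution can only improve per-food scores,
so every scenario lowers the dietary score; the optimistic generic
scenario (2A, lowest same-category score) moves nutrients of concern
furthest, while the realistic one (2B, next-lowest score) changes least.

Other examples, one per capability:

- `examples/score_foods.py` — score individual foods, including the
  averaged middling FVN assumption;
- `examples/impute_and_score_database.py` — category-median imputation of
  missing nutrients, then database-wide scoring;
- `examples/planted_sodium_recovery.py` — end-to-end verification on a
  world whose true sodium effect is analytically known.

A thin CLI mirrors the pipeline (`np-substitute run --config FILE --out DIR`,
plus `synth`, `score`, `substitute`, `aggregate`, `estimate` stage
commands); the config format is flat `key = value` lines (see
`tests/test_pipeline_cli.py` for a complete example).

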