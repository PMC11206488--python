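"""Run all four substitution scenarios on a synthetic survey world.

Generates a synthetic world (generic + branded databases, matches, 24 h
recalls, bootstrap replicate weights), runs the baseline and the four
scenarios, and prints the survey-weighted population means: dietary
nutrient-profile score, calories, saturated fat, sodium and total sugars,
each with its replicate standard error and the paired-contrast
significance flag (* means p < 0.05 against baseline).
"""

from npsubstitute import (ScenarioConfig, SynthConfig, generate_world,
                          match_coverage, prepare_world, run_scenarios)

world = generate_world(SynthConfig(seed=42, n_respondents=500, B=50))
prep = prepare_world(world)
print(f"respondents retained: {prep.counts['respondents_retained']} "
      f"of {prep.counts['respondents_total']}; "
      f"{prep.counts['recall_lines']} recall lines")

cov = match_coverage(prep.recalls, world.matches, prep.generic, prep.branded)
print(f"branded match coverage: {cov.matched_fraction:.1%} matched, "
      f"{cov.lower_score_fraction:.1%} with a lower score\n")

res = run_scenarios(prep, [ScenarioConfig(s) for s in ("1A", "1B", "2A", "2B")])
table = res.report.pivot(index="arm", columns="outcome", values="estimate") \
    .reindex(["baseline", "1A", "1B", "2A", "2B"])
flags = res.report.pivot(index="arm", columns="outcome", values="significant") \
    .reindex(table.index)
print("survey-weighted means (dietary score, daily intakes):")
for arm in table.index:
    row = table.loc[arm]
    f = flags.loc[arm]
    print(f"  {arm:9s} score {row.dietary_ofcom:5.2f}{f.dietary_ofcom or ' '} "
          f"kcal {row.calories_kcal:7.1f}{f.calories_kcal or ' '} "
          f"satfat {row.satfat_g:5.1f}{f.satfat_g or ' '} "
          f"sodium {row.sodium_mg:7.1f}{f.sodium_mg or ' '} "
          f"sugars {row.sugars_g:5.1f}{f.sugars_g or ' '}")

print("\nEvery scenario lowers the dietary score (substitution can only "
      "improve per-food\nscores); the optimistic generic scenario 2A moves "
      "nutrients of concern furthest,\nwhile the realistic 2B (next-lowest "
      "score) changes least. All contrasts here are\nsignificant because "
      "substitution shifts nearly every respondent the same way.")
if res.subset_report is not None:
    sub = res.subset_report.pivot(index="arm", columns="outcome",
                                  values="estimate")
    print(f"\nsubset analysis (lines restricted to scenario-1-substitutable "
          f"foods, n={res.prepared.counts['subset_respondents']}):")
    print(sub.round(2).to_string())
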