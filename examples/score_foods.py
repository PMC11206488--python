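"""Score a handful of foods with the 2004-05 nutrient-profiling model.

Builds per-100 g profiles for four foods, scores each, and prints the
A-points (energy, saturated fat, sugars, sodium), C-points (fruit/veg/nut,
fibre, protein) and the total.  Lower totals are more favourable; the
granola bar shows the averaged middling fruit/veg/nut assumption, which
can yield a half-integer score.
"""

from npsubstitute import FvnLevel, NutrientProfile, ofcom_score

foods = {
    "apple (>80% fruit)": NutrientProfile(52, 0.1, 10.4, 1, 2.4, 0.3,
                                          FvnLevel.MAX),
    "brewed coffee": NutrientProfile(0, 0, 0, 0, 0, 0, FvnLevel.MIN),
    "cheddar cheese": NutrientProfile(403, 21, 0.5, 621, 0, 25, FvnLevel.MIN),
    "fruit-and-nut granola bar": NutrientProfile(450, 6, 30, 200, 4, 8,
                                                 FvnLevel.AVERAGED_MID),
}

for name, profile in foods.items():
    comp = ofcom_score(profile)
    capped = " (protein points withheld)" if comp.protein_capped else ""
    print(f"{name:28s}  A={comp.a_points:2d}  C={comp.c_points:2d}"
          f"  total={comp.total_score:5.1f}{capped}")

print("\nA-points accrue from nutrients to limit; C-points from favourable "
      "components.\nThe granola bar's total is the mean of its >40% and >60% "
      "fruit/veg/nut scores.")
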