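# UK FSA/Ofcom nutrient profiling model, 2004-05 point tables.
# A-components: one point per threshold strictly exceeded (per 100 g).
# C-components: fruit/veg/nut points by assumption level; fibre and protein
# one point per threshold strictly exceeded.
version = ofcom-2004-05
energy_kj = 335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350
satfat_g = 1, 2, 3, 4, 5, 6, 7, 8, 9, 10
sugars_g = 4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45
sodium_mg = 90, 180, 270, 360, 450, 540, 630, 720, 810, 900
# FVN points awarded at the MIN / LOW_MID / HIGH_MID / MAX assumption levels
# (>40% earns 1 point, >60% earns 2, >80% earns 5).
fvn_points = 0, 1, 2, 5
# AOAC fibre is the default (North American food-composition convention);
# NSP thresholds provided as the selectable alternative.
fibre_aoac_g = 0.9, 1.9, 2.8, 3.7, 4.7
fibre_nsp_g = 0.7, 1.4, 2.1, 2.8, 3.5
protein_g = 1.6, 3.2, 4.8, 6.4, 8.0
# Protein points are withheld when A-points reach this cap unless the food
# holds maximum FVN points.
protein_cap_a_points = 11
kcal_to_kj = 4.184
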