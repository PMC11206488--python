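"""Independent table-lookup oracle for the 2004-05 nutrient-profiling model.

Deliberately written as literal if/elif chains with the published numbers
inline — no shared code or lookup machinery with the package — so tests
compare two independent codings of the same tables.
"""


def energy_points_kcal(kcal: float) -> int:
    kj = kcal * 4.184
    if kj > 3350:
        return 10
    elif kj > 3015:
        return 9
    elif kj > 2680:
        return 8
    elif kj > 2345:
        return 7
    elif kj > 2010:
        return 6
    elif kj > 1675:
        return 5
    elif kj > 1340:
        return 4
    elif kj > 1005:
        return 3
    elif kj > 670:
        return 2
    elif kj > 335:
        return 1
    return 0


def satfat_points(g: float) -> int:
    if g > 10:
        return 10
    elif g > 9:
        return 9
    elif g > 8:
        return 8
    elif g > 7:
        return 7
    elif g > 6:
        return 6
    elif g > 5:
        return 5
    elif g > 4:
        return 4
    elif g > 3:
        return 3
    elif g > 2:
        return 2
    elif g > 1:
        return 1
    return 0


def sugars_points(g: float) -> int:
    if g > 45:
        return 10
    elif g > 40:
        return 9
    elif g > 36:
        return 8
    elif g > 31:
        return 7
    elif g > 27:
        return 6
    elif g > 22.5:
        return 5
    elif g > 18:
        return 4
    elif g > 13.5:
        return 3
    elif g > 9:
        return 2
    elif g > 4.5:
        return 1
    return 0


def sodium_points(mg: float) -> int:
    if mg > 900:
        return 10
    elif mg > 810:
        return 9
    elif mg > 720:
        return 8
    elif mg > 630:
        return 7
    elif mg > 540:
        return 6
    elif mg > 450:
        return 5
    elif mg > 360:
        return 4
    elif mg > 270:
        return 3
    elif mg > 180:
        return 2
    elif mg > 90:
        return 1
    return 0


def fibre_points_aoac(g: float) -> int:
    if g > 4.7:
        return 5
    elif g > 3.7:
        return 4
    elif g > 2.8:
        return 3
    elif g > 1.9:
        return 2
    elif g > 0.9:
        return 1
    return 0


def protein_points(g: float) -> int:
    if g > 8.0:
        return 5
    elif g > 6.4:
        return 4
    elif g > 4.8:
        return 3
    elif g > 3.2:
        return 2
    elif g > 1.6:
        return 1
    return 0


FVN_POINTS = {"MIN": 0, "LOW_MID": 1, "HIGH_MID": 2, "MAX": 5}


def oracle_a_points(kcal, satfat, sugars, sodium) -> int:
    return (energy_points_kcal(kcal) + satfat_points(satfat)
            + sugars_points(sugars) + sodium_points(sodium))


def oracle_total(kcal, satfat, sugars, sodium, fibre, protein, fvn_level) -> float:
    """Complete score; AVERAGED_MID averages the LOW_MID and HIGH_MID totals."""
    if fvn_level == "AVERAGED_MID":
        low = oracle_total(kcal, satfat, sugars, sodium, fibre, protein, "LOW_MID")
        high = oracle_total(kcal, satfat, sugars, sodium, fibre, protein, "HIGH_MID")
        return (low + high) / 2.0
    a = oracle_a_points(kcal, satfat, sugars, sodium)
    fvn = FVN_POINTS[fvn_level]
    c = fvn + fibre_points_aoac(fibre)
    if not (a >= 11 and fvn < 5):
        c += protein_points(protein)
    return float(a - c)
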