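"""Scenario candidate selection, substitution rules and invariants."""

import numpy as np
import pandas as pd
import pytest

from npsubstitute import (BRANDED, GENERIC, FoodDatabase, MatchTable,
                          ScenarioConfig, apply_scenario, baseline_foods,
                          candidates, daily_intakes, select_substitute)
from npsubstitute.errors import ConfigError

from conftest import make_food_frame


@pytest.fixture
def category_db(tables):
    # five foods in one category with scores 3, 1, 1, 4, 6 by construction
    frame = make_food_frame([
        # kcal kept below the first energy threshold; a-points driven by
        # sugars + sodium; c = 1 fibre point everywhere
        ("F1", "30C", 50, 0.5, 5, 300, 1, 1, "MIN", 50),   # a=4, score 3
        ("F2", "30C", 50, 0.5, 5, 150, 1, 1, "MIN", 50),   # a=2, score 1
        ("F3", "30C", 60, 0.5, 5, 160, 1, 1, "MIN", 50),   # score 1, more kcal
        ("F4", "30C", 70, 0.5, 10, 300, 1, 1, "MIN", 50),  # a=5, score 4
        ("F5", "30C", 80, 0.5, 14, 400, 1, 1, "MIN", 50),  # a=7, score 6
    ])
    db = FoodDatabase(frame, GENERIC).score_with(tables)
    assert db.scores.loc[["F1", "F2", "F3", "F4", "F5"]].tolist() == \
        [3.0, 1.0, 1.0, 4.0, 6.0]
    return db


class TestCandidates:
    def test_strictly_lower_scores_only(self, category_db):
        cands = candidates("F4", ScenarioConfig("2A"), category_db, None, None)
        assert sorted(cands.index) == ["F1", "F2", "F3"]
        assert sorted(cands["ofcom_score"]) == [1.0, 1.0, 3.0]

    def test_lowest_scoring_food_has_no_candidates(self, category_db):
        cands = candidates("F2", ScenarioConfig("2B"), category_db, None, None)
        assert len(cands) == 0

    def test_branded_candidates_filtered_by_score(self, category_db, tables):
        # two branded foods matched into the category: one better, one worse
        branded = FoodDatabase(make_food_frame([
            ("B1", "30C", 50, 0.2, 3, 80, 1, 1, "MIN", 50, 0.5),
            ("B2", "30C", 600, 9, 40, 800, 0, 1, "MIN", 50, 0.5)]),
            BRANDED).score_with(tables)
        matches = MatchTable.from_pairs([("F2", "B1"), ("F5", "B2")],
                                        category_db, branded)
        cands = candidates("F4", ScenarioConfig("1A"), category_db, branded,
                           matches)
        assert list(cands.index) == ["B1"]

    def test_branded_scoring_higher_than_food_gives_empty_set(self, category_db,
                                                              tables):
        branded = FoodDatabase(make_food_frame([
            ("B2", "30C", 600, 9, 40, 800, 0, 1, "MIN", 50, 1.0)]),
            BRANDED).score_with(tables)
        matches = MatchTable.from_pairs([("F5", "B2")], category_db, branded)
        cands = candidates("F2", ScenarioConfig("1A"), category_db, branded,
                           matches)
        assert len(cands) == 0


class TestSelectSubstitute:
    def test_empty_candidates_leave_food_as_is(self, category_db):
        res = select_substitute(
            "F2", candidates("F2", ScenarioConfig("2A"), category_db, None, None),
            ScenarioConfig("2A"), category_db)
        assert not res.replaced
        assert res.replacement_id == "F2"
        assert res.score == 1.0

    def test_s2a_picks_minimum_score_breaking_ties_by_calories(self, category_db):
        sc = ScenarioConfig("2A")
        res = select_substitute(
            "F4", candidates("F4", sc, category_db, None, None), sc, category_db)
        # F2 and F3 tie at score 1; F2 has fewer calories
        assert res.replaced and res.replacement_id == "F2"

    def test_s2a_remaining_tie_breaks_by_food_id(self, tables):
        db = FoodDatabase(make_food_frame([
            ("FB", "40D", 50, 0.5, 5, 150, 1, 1, "MIN", 50),
            ("FA", "40D", 50, 0.5, 5, 150, 1, 1, "MIN", 50),
            ("FZ", "40D", 80, 0.5, 14, 400, 1, 1, "MIN", 50)]),
            GENERIC).score_with(tables)
        sc = ScenarioConfig("2A")
        res = select_substitute(
            "FZ", candidates("FZ", sc, db, None, None), sc, db)
        assert res.replacement_id == "FA"

    def test_s2b_takes_next_lowest_score(self, category_db):
        sc = ScenarioConfig("2B")
        res = select_substitute(
            "F4", candidates("F4", sc, category_db, None, None), sc, category_db)
        # candidate scores {3, 1, 1}; next-lowest below 4 is 3 -> F1
        assert res.replaced and res.replacement_id == "F1"
        assert res.score == 3.0

    def test_s2a_score_never_above_s2b_score(self, prepared, tables):
        eff_a, map_a = apply_scenario(prepared.recalls, ScenarioConfig("2A"),
                                      prepared.generic, tables=tables)
        eff_b, map_b = apply_scenario(prepared.recalls, ScenarioConfig("2B"),
                                      prepared.generic, tables=tables)
        assert (eff_a["ofcom_score"] <= eff_b["ofcom_score"]
                .loc[eff_a.index]).all()

    def test_override_designates_the_substitute(self, category_db):
        sc = ScenarioConfig("2A", overrides={"30C": "F1"})
        res = select_substitute(
            "F5", candidates("F5", sc, category_db, None, None), sc, category_db)
        assert res.replaced and res.replacement_id == "F1"

    def test_override_with_higher_score_leaves_as_is(self, category_db):
        sc = ScenarioConfig("2A", overrides={"30C": "F5"})
        res = select_substitute(
            "F4", candidates("F4", sc, category_db, None, None), sc, category_db)
        assert not res.replaced and res.replacement_id == "F4"

    def test_overrides_do_not_apply_to_s2b(self, category_db):
        sc = ScenarioConfig("2B", overrides={"30C": "F1"})
        res = select_substitute(
            "F5", candidates("F5", sc, category_db, None, None), sc, category_db)
        # next-lowest below 6 is 4 -> F4, ignoring the override
        assert res.replacement_id == "F4"

    def test_invalid_scenario_id_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig("3A")


@pytest.fixture
def branded_world(category_db, tables):
    branded = FoodDatabase(make_food_frame([
        # two candidates tied at the minimum score 1, different sodium
        # (B2's extra sodium points are offset by extra fibre points)
        ("B1", "30C", 50, 0.5, 5, 100, 1, 1, "MIN", 50, 0.75),
        ("B2", "30C", 50, 0.5, 5, 300, 3, 1, "MIN", 50, 0.25),
        # a strictly worse option (score 4), still below F5's score 6
        ("B3", "30C", 50, 0.5, 10, 310, 1, 1, "MIN", 50, 0.5),
    ]), BRANDED).score_with(tables)
    matches = MatchTable.from_pairs(
        [("F2", "B1"), ("F3", "B2"), ("F4", "B3")], category_db, branded)
    return branded, matches


class TestComposites:
    def test_s1a_unweighted_mean_over_tied_minimum(self, category_db,
                                                   branded_world, tables):
        branded, matches = branded_world
        sc = ScenarioConfig("1A")
        cands = candidates("F5", sc, category_db, branded, matches)
        res = select_substitute("F5", cands, sc, category_db, branded, tables)
        assert res.replaced and res.composite
        assert set(res.constituents) == {"B1", "B2"}
        assert res.profile.sodium_mg == pytest.approx(200.0)  # mean of 100, 300
        assert res.score < category_db.scores.loc["F5"]

    def test_s1b_market_share_weighted_mean(self, category_db, branded_world,
                                            tables):
        branded, matches = branded_world
        sc = ScenarioConfig("1B")
        # restrict to the two tied candidates to check the weighting exactly
        cands = candidates("F5", sc, category_db, branded, matches).loc[["B1", "B2"]]
        res = select_substitute("F5", cands, sc, category_db, branded, tables)
        # shares 0.75/0.25 over sodium 100/300 -> 150
        assert res.profile.sodium_mg == pytest.approx(150.0)

    def test_s1b_uses_all_lower_scoring_candidates(self, category_db,
                                                   branded_world, tables):
        branded, matches = branded_world
        sc = ScenarioConfig("1B")
        cands = candidates("F5", sc, category_db, branded, matches)
        res = select_substitute("F5", cands, sc, category_db, branded, tables)
        assert set(res.constituents) == {"B1", "B2", "B3"}

    def test_s1_scenarios_coincide_for_single_candidate(self, category_db,
                                                        tables):
        # the only branded food (score 4) qualifies solely for F5 (score 6)
        branded = FoodDatabase(make_food_frame([
            ("B3", "30C", 50, 0.5, 10, 310, 1, 1, "MIN", 50, 0.5)]),
            BRANDED).score_with(tables)
        matches = MatchTable.from_pairs([("F4", "B3")], category_db, branded)
        cands = candidates("F5", ScenarioConfig("1A"), category_db, branded,
                           matches)
        assert list(cands.index) == ["B3"]
        res_a = select_substitute("F5", cands, ScenarioConfig("1A"),
                                  category_db, branded, tables)
        res_b = select_substitute("F5", cands, ScenarioConfig("1B"),
                                  category_db, branded, tables)
        assert res_a.profile == res_b.profile
        assert res_a.replacement_id == res_b.replacement_id == "B3"
        assert not res_a.composite

    def test_s1b_all_zero_shares_falls_back_unweighted(self, category_db,
                                                       tables):
        branded = FoodDatabase(make_food_frame([
            ("B1", "30C", 50, 0.5, 5, 100, 1, 1, "MIN", 50, 0.0),
            ("B2", "30C", 50, 0.5, 5, 300, 3, 1, "MIN", 50, 0.0)]),
            BRANDED).score_with(tables)
        matches = MatchTable.from_pairs([("F2", "B1"), ("F3", "B2")],
                                        category_db, branded)
        sc = ScenarioConfig("1B")
        cands = candidates("F5", sc, category_db, branded, matches)
        with pytest.warns(UserWarning, match="market share"):
            res = select_substitute("F5", cands, sc, category_db, branded,
                                    tables)
        assert res.profile.sodium_mg == pytest.approx(200.0)


class TestApplyScenario:
    def test_no_candidates_anywhere_is_identity(self, tables):
        # every food is its category's sole member: nothing can be replaced
        db = FoodDatabase(make_food_frame([
            ("F1", "01A", 250, 2, 10, 300, 1, 1, "MIN", 50),
            ("F2", "02A", 150, 1, 5, 150, 1, 1, "MIN", 50)]),
            GENERIC).score_with(tables)
        recalls = pd.DataFrame({"respondent_id": ["R1", "R1"],
                                "food_id": ["F1", "F2"],
                                "grams_consumed": [100.0, 50.0]})
        eff, sub_map = apply_scenario(recalls, ScenarioConfig("2A"), db,
                                      tables=tables)
        assert not any(r.replaced for r in sub_map.values())
        base = baseline_foods(recalls, db)
        pd.testing.assert_frame_equal(
            eff.sort_index(axis=1).astype(base.sort_index(axis=1).dtypes),
            base.sort_index(axis=1), check_like=True, check_names=False)

    def test_only_substituted_lines_change_and_grams_are_kept(self, category_db,
                                                              tables):
        recalls = pd.DataFrame({"respondent_id": ["R1", "R1"],
                                "food_id": ["F2", "F4"],
                                "grams_consumed": [120.0, 80.0]})
        eff, sub_map = apply_scenario(recalls, ScenarioConfig("2A"),
                                      category_db, tables=tables)
        assert not sub_map["F2"].replaced and sub_map["F4"].replaced
        # reference amount retained from the original food
        assert eff.loc["F4", "reference_amount_g"] == 50.0
        intakes = daily_intakes(recalls, eff)
        base = daily_intakes(recalls, baseline_foods(recalls, category_db))
        assert intakes.loc["R1", "dietary_ofcom"] < base.loc["R1", "dietary_ofcom"]

    def test_map_shared_across_respondents_and_deterministic(self, category_db,
                                                             tables):
        recalls = pd.DataFrame({"respondent_id": ["R1", "R2"],
                                "food_id": ["F4", "F4"],
                                "grams_consumed": [10.0, 500.0]})
        eff1, m1 = apply_scenario(recalls, ScenarioConfig("2B"), category_db,
                                  tables=tables)
        eff2, m2 = apply_scenario(recalls, ScenarioConfig("2B"), category_db,
                                  tables=tables)
        assert m1["F4"].replacement_id == m2["F4"].replacement_id
        pd.testing.assert_frame_equal(eff1, eff2)


class TestStructuralInvariants:
    @pytest.mark.parametrize("scenario_id", ["1A", "1B", "2A", "2B"])
    def test_replaced_scores_strictly_lower(self, prepared, tables, scenario_id):
        eff, sub_map = apply_scenario(
            prepared.recalls, ScenarioConfig(scenario_id), prepared.generic,
            prepared.branded, prepared.matches, tables)
        originals = prepared.generic.scores
        for fid, res in sub_map.items():
            if res.replaced:
                assert res.score < originals.loc[fid]
            else:
                assert res.score == originals.loc[fid]
                assert res.replacement_id == fid

    @pytest.mark.parametrize("scenario_id", ["1A", "1B", "2A", "2B"])
    def test_dietary_score_never_rises(self, prepared, tables, scenario_id):
        eff, _ = apply_scenario(
            prepared.recalls, ScenarioConfig(scenario_id), prepared.generic,
            prepared.branded, prepared.matches, tables)
        base = daily_intakes(prepared.recalls,
                             baseline_foods(prepared.recalls, prepared.generic))
        scen = daily_intakes(prepared.recalls, eff)
        assert (scen["dietary_ofcom"] <= base["dietary_ofcom"] + 1e-12).all()
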