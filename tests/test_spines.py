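"""Spine turnover, survival, re-emergence, class composition."""

import numpy as np
import pandas as pd
import pytest

from cortexcal import spines as sp
from cortexcal import synthgen as sg
from cortexcal._validate import UndefinedResultError


def build_table(sessions):
    """sessions: {session_index: [(pid, position, cls, present), ...]} —
    every protrusion must appear in every session row-set."""
    rows = []
    for s, entries in sessions.items():
        for pid, pos, cls, present in entries:
            rows.append(
                {
                    "protrusion_id": pid,
                    "session_index": s,
                    "dendrite_id": "d0",
                    "position_um": pos,
                    "class": cls,
                    "present": present,
                }
            )
    return pd.DataFrame(rows)


def simple_history(present_by_session):
    """present_by_session: list (per session) of sets of present ids; all
    protrusions are thin spines at distinct positions."""
    all_ids = sorted(set().union(*present_by_session))
    sessions = {}
    for s, present in enumerate(present_by_session):
        sessions[s] = [(pid, 10.0 + 3.0 * i, "thin", pid in present) for i, pid in enumerate(all_ids)]
    return build_table(sessions)


class TestTurnover:
    def test_identical_sessions_zero_rates(self):
        table = simple_history([{"a", "b", "c"}, {"a", "b", "c"}])
        t = sp.turnover(table, 0, 1)
        assert (t["pct_formed"], t["pct_eliminated"]) == (0.0, 0.0)

    def test_printed_arithmetic(self):
        prev = {f"s{i}" for i in range(100)}
        nxt = (prev - {f"s{i}" for i in range(5)}) | {f"new{i}" for i in range(8)}
        table = simple_history([prev, nxt])
        t = sp.turnover(table, 0, 1)
        assert t["pct_eliminated"] == pytest.approx(5.0)
        assert t["pct_formed"] == pytest.approx(8.0)

    def test_matches_set_difference_oracle(self, rng):
        for seed in range(10):
            cfg = sg.SpineHistoryConfig(
                n_sessions=3, n_spines_initial=60, p_eliminate=0.2, p_form=0.15, seed=seed
            )
            table, _ = sg.generate_spine_history(cfg)
            t = sp.turnover(table, 0, 1)
            prev = sp.present_ids(table, 0)
            nxt = sp.present_ids(table, 1)
            assert t["n_formed"] == len(nxt - prev)
            assert t["n_eliminated"] == len(prev - nxt)
            assert t["pct_formed"] == pytest.approx(100 * len(nxt - prev) / len(prev))
            # conservation on every table
            assert len(nxt) == len(prev) - t["n_eliminated"] + t["n_formed"]

    def test_filopodia_use_protrusion_denominator(self):
        sessions = {
            0: [("s1", 1.0, "thin", True), ("s2", 2.0, "thin", True),
                ("f1", 3.0, "filopodium", True), ("f2", 4.0, "filopodium", True)],
            1: [("s1", 1.0, "thin", True), ("s2", 2.0, "thin", True),
                ("f1", 3.0, "filopodium", False), ("f2", 4.0, "filopodium", True)],
        }
        t = sp.turnover(build_table(sessions), 0, 1)
        assert t["pct_filopodia_eliminated"] == pytest.approx(100 / 4)  # 1 of 4 protrusions
        assert t["pct_eliminated"] == 0.0  # spine denominator is 2

    def test_empty_previous_session_undefined(self):
        table = simple_history([set(), {"a"}])
        with pytest.raises(UndefinedResultError):
            sp.turnover(table, 0, 1)


class TestSurvival:
    def test_printed_cohort_counts(self):
        # 55 new spines of which 27 persist: 49.1% to one decimal
        base = {f"b{i}" for i in range(100)}
        cohort = {f"n{i}" for i in range(55)}
        persisting = {f"n{i}" for i in range(27)}
        table = simple_history([base, base | cohort, base | persisting])
        res = sp.survival(table, 1, 2)
        assert res["n_cohort"] == 55 and res["n_surviving"] == 27
        assert round(res["pct_surviving"], 1) == 49.1

    def test_all_persist(self):
        base = {"a"}
        table = simple_history([base, base | {"x", "y"}, base | {"x", "y"}])
        assert sp.survival(table, 1, 2)["pct_surviving"] == 100.0

    def test_binomial_calibration(self):
        cfg = sg.SpineHistoryConfig(
            n_sessions=3, n_spines_initial=5000, p_eliminate=0.0, p_form=0.1,
            p_survive=0.3, filopodium_fraction=0.0, seed=77,
        )
        table, _ = sg.generate_spine_history(cfg)
        res = sp.survival(table, 1, 2)
        rate = res["pct_surviving"] / 100.0
        se = np.sqrt(rate * (1 - rate) / res["n_cohort"])
        assert abs(rate - 0.3) <= 1.96 * se

    def test_empty_cohort_undefined(self):
        base = {"a", "b"}
        table = simple_history([base, base, base])
        with pytest.raises(UndefinedResultError):
            sp.survival(table, 1, 2)


class TestReemergence:
    def three_session_table(self, new_pos):
        sessions = {
            0: [("old", 10.0, "thin", True), ("keep", 50.0, "thin", True),
                ("new", new_pos, "thin", False)],
            1: [("old", 10.0, "thin", False), ("keep", 50.0, "thin", True),
                ("new", new_pos, "thin", False)],
            2: [("old", 10.0, "thin", False), ("keep", 50.0, "thin", True),
                ("new", new_pos, "thin", True)],
        }
        return build_table(sessions)

    def test_within_radius_counted(self):
        res = sp.reemergence(self.three_session_table(11.5), (0, 1), (1, 2))
        assert res["pct_new_near_elimination"] == 100.0
        assert res["pct_eliminated_recovered"] == 100.0

    def test_at_or_beyond_radius_not_counted(self):
        res = sp.reemergence(self.three_session_table(12.5), (0, 1), (1, 2))
        assert res["pct_new_near_elimination"] == 0.0
        res = sp.reemergence(self.three_session_table(12.0), (0, 1), (1, 2))
        assert res["pct_new_near_elimination"] == 0.0  # strict < 2.0

    def test_different_dendrite_not_counted(self):
        table = self.three_session_table(11.5)
        table.loc[table.protrusion_id == "new", "dendrite_id"] = "d1"
        res = sp.reemergence(table, (0, 1), (1, 2))
        assert res["pct_new_near_elimination"] == 0.0

    def test_empty_denominators_reported_undefined(self):
        base = {"a", "b"}
        table = simple_history([base, base, base])
        res = sp.reemergence(table, (0, 1), (1, 2))
        assert res["pct_new_near_elimination"] is None
        assert res["pct_eliminated_recovered"] is None

    def test_invariance_to_relabeling_and_translation(self, rng):
        cfg = sg.SpineHistoryConfig(
            n_sessions=3, n_spines_initial=80, p_eliminate=0.2, p_form=0.2,
            reemergence_fraction=0.5, seed=11,
        )
        table, _ = sg.generate_spine_history(cfg)
        res1 = sp.reemergence(table, (0, 1), (1, 2))
        shifted = table.copy()
        shifted["position_um"] = shifted["position_um"] + 500.0
        shifted["dendrite_id"] = "renamed"
        res2 = sp.reemergence(shifted, (0, 1), (1, 2))
        assert res1["pct_new_near_elimination"] == res2["pct_new_near_elimination"]
        assert res1["pct_eliminated_recovered"] == res2["pct_eliminated_recovered"]


class TestClassComposition:
    def test_all_mushroom(self):
        sessions = {0: [(f"m{i}", float(i), "mushroom", True) for i in range(5)]}
        comp = sp.class_composition(build_table(sessions), {f"m{i}" for i in range(5)})
        assert comp == {"mushroom": 1.0, "stubby": 0.0, "thin": 0.0, "other": 0.0}

    def test_printed_cohort_of_28(self):
        # 8 mushroom, 8 stubby, 9 thin, 3 other out of 28 reproduces the
        # printed one-decimal percentages 28.6 / 28.6 / 32.1 / 10.7
        entries = (
            [(f"m{i}", float(i), "mushroom", True) for i in range(8)]
            + [(f"s{i}", 10.0 + i, "stubby", True) for i in range(8)]
            + [(f"t{i}", 20.0 + i, "thin", True) for i in range(9)]
            + [(f"o{i}", 30.0 + i, "other", True) for i in range(3)]
        )
        table = build_table({0: entries})
        comp = sp.class_composition(table, {e[0] for e in entries})
        assert round(100 * comp["mushroom"], 1) == 28.6
        assert round(100 * comp["stubby"], 1) == 28.6
        assert round(100 * comp["thin"], 1) == 32.1
        assert round(100 * comp["other"], 1) == 10.7

    def test_fractions_sum_to_one(self, rng):
        cfg = sg.SpineHistoryConfig(n_sessions=2, n_spines_initial=100, p_form=0.3, seed=2)
        table, _ = sg.generate_spine_history(cfg)
        cohort = sp.present_ids(table, 1) - sp.present_ids(table, 0)
        comp = sp.class_composition(table, cohort)
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_empty_cohort_undefined(self):
        table = simple_history([{"a"}])
        with pytest.raises(UndefinedResultError):
            sp.class_composition(table, set())


class TestPositionalMatcher:
    def test_assigns_stable_ids(self):
        rows = []
        for s in range(3):
            for pos in (5.0, 12.0, 20.0):
                rows.append(
                    {"session_index": s, "dendrite_id": "d0",
                     "position_um": pos + 0.1 * s, "class": "thin", "present": True}
                )
        matched = sp.match_protrusions_by_position(pd.DataFrame(rows), tolerance_um=0.5)
        assert matched.groupby("protrusion_id").size().tolist() == [3, 3, 3]

    def test_far_records_get_new_ids(self):
        rows = [
            {"session_index": 0, "dendrite_id": "d0", "position_um": 5.0,
             "class": "thin", "present": True},
            {"session_index": 1, "dendrite_id": "d0", "position_um": 9.0,
             "class": "thin", "present": True},
        ]
        matched = sp.match_protrusions_by_position(pd.DataFrame(rows), tolerance_um=0.5)
        assert matched["protrusion_id"].nunique() == 2
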