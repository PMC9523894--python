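"""Selective and action-typed drug screens against brute-force references."""

import numpy as np
import pandas as pd
import pytest

from micropharm import (
    SCREEN_MODES,
    ScreenResult,
    build_target_homology_map,
    intersect_inchikey,
    microbes_targeted_by_drug,
    screen_selective,
    screen_typed,
)
from micropharm.druggability import HomologyHit
from oracles import brute_force_selective, brute_force_typed


def random_untyped_instance(rng, n_drugs=40, n_targets=25, n_microbes=12):
    drugs = [f"d{i}" for i in range(n_drugs)]
    targets = [f"t{i}" for i in range(n_targets)]
    microbes = [f"M{i}" for i in range(n_microbes)]
    rows = [
        {
            "drug_id": str(rng.choice(drugs)),
            "inchikey": "",
            "target_id": str(rng.choice(targets)),
        }
        for _ in range(int(rng.integers(20, 120)))
    ]
    interactions = pd.DataFrame(rows).drop_duplicates()
    homology_map = {
        t: {str(m) for m in rng.choice(microbes, size=rng.integers(0, 4), replace=False)}
        for t in targets
    }
    k = int(rng.integers(1, n_microbes - 1))
    pathogenic = set(microbes[:k])
    commensal = set(microbes[k:])
    return interactions, homology_map, pathogenic, commensal


def random_typed_instance(rng, n_chems=50, n_microbes=12, n_rows=400):
    microbes = [f"M{i}" for i in range(n_microbes)]
    rows = [
        {
            "chemical_id": f"c{rng.integers(0, n_chems)}",
            "inchikey": "",
            "microbe_id": str(rng.choice(microbes)),
            "target_protein": f"t{rng.integers(0, 40)}",
            "action": str(rng.choice(["inhibition", "activation", "other"])),
            "is_drug": bool(rng.random() < 0.7),
        }
        for _ in range(n_rows)
    ]
    typed = pd.DataFrame(rows)
    k = int(rng.integers(1, n_microbes - 1))
    return typed, set(microbes[:k]), set(microbes[k:])


class TestMicrobesTargeted:
    homology_map = {"t1": {"M1", "M2"}, "t2": {"M2", "M3"}, "t3": set()}

    def table(self, pairs):
        return pd.DataFrame(
            [{"drug_id": d, "inchikey": "", "target_id": t} for d, t in pairs]
        )

    def test_single_target(self):
        table = self.table([("d1", "t1")])
        assert microbes_targeted_by_drug("d1", table, self.homology_map) == {"M1", "M2"}

    def test_unmapped_targets_give_empty_set(self):
        table = self.table([("d1", "t3"), ("d1", "t_unknown")])
        assert microbes_targeted_by_drug("d1", table, self.homology_map) == set()

    def test_union_over_targets(self):
        table = self.table([("d1", "t1"), ("d1", "t2")])
        assert microbes_targeted_by_drug("d1", table, self.homology_map) == {
            "M1",
            "M2",
            "M3",
        }

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError):
            microbes_targeted_by_drug("ghost", self.table([("d1", "t1")]), self.homology_map)


class TestScreenSelective:
    def test_pathogen_only_drug_retained_mixed_excluded(self):
        interactions = pd.DataFrame(
            [
                {"drug_id": "good", "inchikey": "", "target_id": "tp"},
                {"drug_id": "bad", "inchikey": "", "target_id": "tp"},
                {"drug_id": "bad", "inchikey": "", "target_id": "tc"},
            ]
        )
        homology_map = {"tp": {"P1"}, "tc": {"C1"}}
        result = screen_selective(interactions, homology_map, {"P1"}, {"C1"})
        assert result.members == {"good"}

    def test_overlapping_label_sets_rejected(self):
        interactions = pd.DataFrame(
            [{"drug_id": "d", "inchikey": "", "target_id": "t"}]
        )
        with pytest.raises(ValueError):
            screen_selective(interactions, {}, {"M"}, {"M"})

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            interactions, homology_map, pathogenic, commensal = random_untyped_instance(rng)
            result = screen_selective(interactions, homology_map, pathogenic, commensal)
            expected = brute_force_selective(
                interactions, homology_map, pathogenic, commensal
            )
            assert result.members == expected

    def test_enlarging_commensal_set_never_enlarges_result(self, rng):
        interactions, homology_map, pathogenic, commensal = random_untyped_instance(rng)
        moved = {next(iter(pathogenic))}
        small = screen_selective(
            interactions, homology_map, pathogenic - moved, commensal
        )
        large = screen_selective(
            interactions, homology_map, pathogenic - moved, commensal | moved
        )
        assert large.members <= small.members


class TestScreenTyped:
    def test_inhibitor_of_pathogen_only_retained(self):
        typed = pd.DataFrame(
            [
                {
                    "chemical_id": "c1",
                    "inchikey": "",
                    "microbe_id": "P1",
                    "target_protein": "t",
                    "action": "inhibition",
                    "is_drug": True,
                }
            ]
        )
        result = screen_typed(typed, "inh_not_inh", {"P1"}, {"C1"})
        assert result.members == {"c1"}

    def test_commensal_activation_blocks_inh_not_act(self):
        typed = pd.DataFrame(
            [
                {
                    "chemical_id": "c1",
                    "inchikey": "",
                    "microbe_id": "P1",
                    "target_protein": "t",
                    "action": "inhibition",
                    "is_drug": True,
                },
                {
                    "chemical_id": "c1",
                    "inchikey": "",
                    "microbe_id": "C1",
                    "target_protein": "t2",
                    "action": "activation",
                    "is_drug": True,
                },
            ]
        )
        assert screen_typed(typed, "inh_not_act", {"P1"}, {"C1"}).members == frozenset()
        # but the same chemical passes the rule that only excludes commensal inhibition
        assert screen_typed(typed, "inh_not_inh", {"P1"}, {"C1"}).members == {"c1"}

    def test_other_actions_never_satisfy_a_rule(self):
        typed = pd.DataFrame(
            [
                {
                    "chemical_id": "c1",
                    "inchikey": "",
                    "microbe_id": "P1",
                    "target_protein": "t",
                    "action": "catalysis",
                    "is_drug": True,
                }
            ]
        )
        typed["action"] = typed["action"].replace({"catalysis": "other"})
        for mode in SCREEN_MODES:
            assert screen_typed(typed, mode, {"P1"}, {"C1"}).members == frozenset()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            screen_typed(pd.DataFrame(), "sideways", set(), set())

    def test_matches_brute_force_in_every_mode(self, rng):
        for _ in range(10):
            typed, pathogenic, commensal = random_typed_instance(rng)
            for drugs_only in (True, False):
                for mode, (required, excluded) in SCREEN_MODES.items():
                    result = screen_typed(
                        typed, mode, pathogenic, commensal, drugs_only=drugs_only
                    )
                    expected = brute_force_typed(
                        typed, required, excluded, pathogenic, commensal, drugs_only
                    )
                    assert result.members == expected, mode

    def test_drug_filter_commutes_with_screening(self, rng):
        typed, pathogenic, commensal = random_typed_instance(rng)
        screened_then_filtered = {
            c
            for c in screen_typed(
                typed, "inh_not_inh", pathogenic, commensal, drugs_only=False
            ).members
            if typed.loc[typed["chemical_id"] == c, "is_drug"].any()
        }
        filtered_then_screened = screen_typed(
            typed[typed.groupby("chemical_id")["is_drug"].transform("any")],
            "inh_not_inh",
            pathogenic,
            commensal,
            drugs_only=False,
        ).members
        assert screened_then_filtered == set(filtered_then_screened)


def make_result(keys_by_member, rule="r"):
    return ScreenResult(
        rule=rule, members=frozenset(keys_by_member), keys=dict(keys_by_member)
    )


KEY_A = "A" * 14 + "-" + "B" * 10 + "-N"
KEY_B = "C" * 14 + "-" + "D" * 10 + "-N"
KEY_C = "E" * 14 + "-" + "F" * 10 + "-N"


class TestIntersectInchikey:
    def test_identical_single_key(self):
        a = make_result({"d1": KEY_A})
        b = make_result({"x9": KEY_A.lower()})  # normalization is case-insensitive
        assert intersect_inchikey(a, b).members == {KEY_A}

    def test_disjoint_keys(self):
        assert (
            intersect_inchikey(make_result({"d1": KEY_A}), make_result({"d2": KEY_B})).members
            == frozenset()
        )

    def test_partial_overlap(self):
        a = make_result({"d1": KEY_A, "d2": KEY_B, "d3": KEY_C})
        b = make_result({"x1": KEY_A, "x2": KEY_C})
        assert intersect_inchikey(a, b).members == {KEY_A, KEY_C}

    def test_malformed_and_missing_keys_dropped(self):
        a = make_result({"d1": KEY_A, "d2": "not-a-key", "d3": None})
        b = make_result({"x1": KEY_A})
        result = intersect_inchikey(a, b)
        assert result.members == {KEY_A}
        assert result.params["dropped_a"] == 2

    def test_commutative_and_idempotent(self):
        a = make_result({"d1": KEY_A, "d2": KEY_B})
        b = make_result({"x1": KEY_B, "x2": KEY_C})
        assert intersect_inchikey(a, b).members == intersect_inchikey(b, a).members
        again = intersect_inchikey(a, a)
        assert again.members == {KEY_A, KEY_B}


def test_build_target_homology_map_thresholds():
    hits = [
        HomologyHit("p1", "M1", "t1", "db", 1e-70, 10.0),
        HomologyHit("p2", "M2", "t1", "db", 1e-3, 10.0),
        HomologyHit("p3", "M3", "t2", "db", 1e-5, 10.0),
    ]
    mapping = build_target_homology_map(hits, 1e-4)
    assert mapping == {"t1": {"M1"}, "t2": {"M3"}}
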