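from __future__ import annotations

import pytest

from treeconsensus import synthetic
from treeconsensus.harmonization import (
    ExclusionRecord,
    HarmonizationRule,
    MergeAmbiguityError,
    RuleCoverageError,
    RuleSet,
    apply_rules,
    census,
    inclusion_filter,
    marginalize,
)
from treeconsensus.tree_model import (
    Criterion,
    CriteriaSet,
    DecisionTable,
    RecommendationSet,
    Scenario,
    scenario_space,
)

from conftest import make_rng, random_criteria
from oracles import oracle_dependent_criteria, oracle_regroup


FITNESS = CriteriaSet([Criterion("fitness", ("fit", "unfit"))])


def kps_table(pid, cutoff_levels=("<50", ">=50"), labels=("BSC", "chemo")):
    criteria = CriteriaSet([Criterion("performance_status", tuple(cutoff_levels))])
    low, high = cutoff_levels
    cells = {
        Scenario.from_mapping({"performance_status": low}): RecommendationSet.single(labels[0]),
        Scenario.from_mapping({"performance_status": high}): RecommendationSet.single(labels[1]),
    }
    return DecisionTable(pid, criteria, cells)


class TestApplyRules:
    def test_kps_cutoff_becomes_fit_unfit(self):
        """Center with a KPS split at 50 re-keyed onto fit/unfit."""
        table = kps_table("A")
        rules = RuleSet(
            FITNESS,
            (
                HarmonizationRule(
                    "performance_status",
                    "fitness",
                    (("<50", "unfit"), (">=50", "fit")),
                    frozenset({"A"}),
                    source_scale="KPS",
                    cutoff=50,
                ),
            ),
        )
        out = apply_rules(table, rules)
        assert out.criteria == FITNESS
        assert out.cells[Scenario.from_mapping({"fitness": "unfit"})] == RecommendationSet.single("BSC")
        assert out.cells[Scenario.from_mapping({"fitness": "fit"})] == RecommendationSet.single("chemo")

    def test_identity_rules_are_identity(self):
        table = kps_table("A")
        rules = RuleSet(table.criteria, ())  # pass-through, no rules at all
        assert apply_rules(table, rules) == table

    def test_partial_rules_rejected(self):
        table = kps_table("A")
        rules = RuleSet(
            FITNESS,
            (HarmonizationRule("performance_status", "fitness", (("<50", "unfit"),)),),
        )
        with pytest.raises(RuleCoverageError, match="unmapped"):
            apply_rules(table, rules)

    def test_unmapped_criterion_rejected(self):
        table = kps_table("A")
        with pytest.raises(RuleCoverageError, match="no rule"):
            apply_rules(table, RuleSet(FITNESS, ()))

    def test_merging_levels_unions_recommendations(self):
        criteria = CriteriaSet([Criterion("ps", ("a", "b", "c", "d"))])
        cells = {
            Scenario.from_mapping({"ps": lv}): RecommendationSet.single(label)
            for lv, label in zip("abcd", ["X", "X", "Y", "Z"])
        }
        table = DecisionTable("p", criteria, cells)
        rules = RuleSet(
            FITNESS,
            (HarmonizationRule("ps", "fitness", (("a", "fit"), ("b", "fit"), ("c", "unfit"), ("d", "unfit"))),),
        )
        out = apply_rules(table, rules)
        fit = out.cells[Scenario.from_mapping({"fitness": "fit"})]
        unfit = out.cells[Scenario.from_mapping({"fitness": "unfit"})]
        assert fit == RecommendationSet.single("X")
        assert unfit.labels == {"Y", "Z"}
        assert unfit.multiplicity == "equivalent-alternatives"
        assert "merge-ambiguity" in unfit.note

    def test_introduced_criterion_replicates_cells(self):
        """The collectively-introduced-criterion pattern: a participant who
        never mentioned the new axis becomes explicitly independent of it."""
        table = kps_table("A")
        harmonized = CriteriaSet(
            [Criterion("fitness", ("fit", "unfit")), Criterion("zugzwang", ("yes", "no"))]
        )
        rules = RuleSet(
            harmonized,
            (HarmonizationRule("performance_status", "fitness", (("<50", "unfit"), (">=50", "fit"))),),
        )
        out = apply_rules(table, rules)
        assert out.is_complete and len(out.cells) == 4
        for zz in ("yes", "no"):
            assert out.cells[Scenario.from_mapping({"fitness": "fit", "zugzwang": zz})] == \
                RecommendationSet.single("chemo")

    def test_non_surjective_map_is_merge_ambiguity(self):
        table = kps_table("A")
        rules = RuleSet(
            FITNESS,
            (HarmonizationRule("performance_status", "fitness", (("<50", "unfit"), (">=50", "unfit"))),),
        )
        with pytest.raises(MergeAmbiguityError) as err:
            apply_rules(table, rules)
        assert err.value.scenarios == [Scenario.from_mapping({"fitness": "fit"})]

    def test_excluded_source_cells_propagate(self):
        table = kps_table("A")
        s = Scenario.from_mapping({"performance_status": "<50"})
        del table.cells[s]
        table.excluded[s] = "moribund patients out of scope"
        rules = RuleSet(
            FITNESS,
            (HarmonizationRule("performance_status", "fitness", (("<50", "unfit"), (">=50", "fit"))),),
        )
        out = apply_rules(table, rules)
        assert out.excluded == {Scenario.from_mapping({"fitness": "unfit"}): "moribund patients out of scope"}

    def test_completeness_preserved_and_scenario_count_law(self):
        rng = make_rng(31)
        labels = synthetic.default_labels(3)
        criteria = CriteriaSet(
            [Criterion("p4", ("a", "b", "c", "d")), Criterion("q", ("u", "v"))]
        )
        table = synthetic.random_table(criteria, labels, rng, "p")
        harmonized = CriteriaSet([Criterion("p2", ("lo", "hi")), Criterion("q", ("u", "v"))])
        rules = RuleSet(
            harmonized,
            (HarmonizationRule("p4", "p2", (("a", "lo"), ("b", "lo"), ("c", "hi"), ("d", "hi"))),),
        )
        out = apply_rules(table, rules)
        assert out.is_complete
        # merging 4 levels into 2 halves the axis twice over: 8 -> 4 cells
        assert len(out.cells) == len(table.cells) // 2 == 4

    def test_random_surjective_mappings_match_preimage_union_oracle(self):
        rng = make_rng(77)
        labels = synthetic.default_labels(4)
        for _ in range(30):
            criteria = random_criteria(rng, max_criteria=3, max_levels=3)
            table = synthetic.random_table(criteria, labels, rng, "p")
            mapping = {}
            harmonized_criteria = []
            for c in criteria:
                k = int(rng.integers(2, len(c.levels) + 1))
                targets = [f"h{j+1}" for j in range(k)]
                # surjective: first k levels hit each target once, rest random
                perm = list(rng.permutation(len(c.levels)))
                level_map = {}
                for j, idx in enumerate(perm):
                    level_map[c.levels[idx]] = targets[j] if j < k else targets[int(rng.integers(k))]
                mapping[c.name] = (f"t_{c.name}", level_map)
                harmonized_criteria.append(Criterion(f"t_{c.name}", tuple(targets)))
            ruleset = RuleSet(
                CriteriaSet(harmonized_criteria),
                tuple(
                    HarmonizationRule(src, tgt, tuple(m.items()))
                    for src, (tgt, m) in mapping.items()
                ),
            )
            out = apply_rules(table, ruleset)
            expected = oracle_regroup(table, mapping, ruleset.criteria)
            got = {s.items: rs.labels for s, rs in out.cells.items()}
            assert got == expected


class TestCensus:
    def test_unused_and_universal_criteria(self, fitness_age):
        constant = DecisionTable(
            "p1",
            fitness_age,
            {s: RecommendationSet.single("A") for s in scenario_space(fitness_age)},
        )
        varying = DecisionTable(
            "p2",
            fitness_age,
            {s: RecommendationSet.single(s["fitness"]) for s in scenario_space(fitness_age)},
        )
        c = census([constant, varying])
        assert c.users["age"] == frozenset()
        assert c.users["fitness"] == frozenset({"p2"})
        assert c.count("fitness") == 1

    def test_census_matches_dependence_oracle(self):
        rng = make_rng(13)
        labels = synthetic.default_labels(3)
        for _ in range(20):
            criteria = random_criteria(rng)
            tables = [
                synthetic.random_table(criteria, labels, rng, f"p{i}") for i in range(4)
            ]
            c = census(tables)
            for t in tables:
                expected = oracle_dependent_criteria(t)
                got = {name for name, users in c.users.items() if t.participant_id in users}
                assert got == expected


class TestInclusionFilter:
    def _ensemble(self, n_users_of_rare=2, n_total=6):
        criteria = CriteriaSet(
            [Criterion("common", ("a", "b")), Criterion("rare", ("y", "n"))]
        )
        tables = []
        for i in range(n_total):
            uses_rare = i < n_users_of_rare

            def cell(s, uses_rare=uses_rare):
                label = "R" + s["common"]
                if uses_rare and s["rare"] == "y":
                    label = "SPECIAL"
                return RecommendationSet.single(label)

            tables.append(
                DecisionTable(
                    f"p{i}", criteria, {s: cell(s) for s in scenario_space(criteria)}
                )
            )
        return tables

    def test_rare_criterion_dropped_and_logged(self):
        tables = self._ensemble(n_users_of_rare=2, n_total=6)
        reduced, log = inclusion_filter(tables, k=3)
        assert log == [ExclusionRecord("rare", 2, ("p0", "p1"), 3)]
        for t in reduced:
            assert t.criteria.names == ("common",)
            assert t.is_complete
        # the affected participants' pooled cells keep both options
        merged = reduced[0].cells[Scenario.from_mapping({"common": "a"})]
        assert merged.labels == {"Ra", "SPECIAL"}
        assert merged.multiplicity == "equivalent-alternatives"

    def test_k1_is_identity(self):
        tables = self._ensemble()
        reduced, log = inclusion_filter(tables, k=1)
        assert reduced == tables and log == []

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            inclusion_filter(self._ensemble(), k=0)

    def test_retained_set_matches_census_threshold(self):
        rng = make_rng(3)
        labels = synthetic.default_labels(3)
        for _ in range(15):
            criteria = random_criteria(rng, max_criteria=3)
            tables = [
                synthetic.random_table(criteria, labels, rng, f"p{i}")
                for i in range(int(rng.integers(2, 6)))
            ]
            k = int(rng.integers(2, 4))
            c = census(tables)
            expected_drop = {n for n in criteria.names if c.count(n) < k}
            if expected_drop == set(criteria.names):
                with pytest.raises(Exception):
                    inclusion_filter(tables, c, k=k)
                continue
            reduced, log = inclusion_filter(tables, c, k=k)
            assert {rec.criterion for rec in log} == expected_drop
            for t in reduced:
                assert set(t.criteria.names) == set(criteria.names) - expected_drop


class TestMarginalize:
    def test_union_rule_never_chooses(self, fitness_age):
        cells = {s: RecommendationSet.single(s["age"]) for s in scenario_space(fitness_age)}
        table = DecisionTable("p", fitness_age, cells)
        out = marginalize(table, "age")
        (cell,) = set(out.cells.values())
        assert cell.labels == {"<70", ">=70"}
        assert cell.multiplicity == "equivalent-alternatives"

    def test_cannot_drop_last_criterion(self):
        table = kps_table("A")
        with pytest.raises(Exception):
            marginalize(table, "performance_status")


class TestTable1Fixture:
    def test_six_records_with_documented_cutoffs(self):
        records, _ = synthetic.table1_fixture()
        assert [r.center for r in records] == ["A", "B", "C", "D", "E", "F"]
        by_center = {r.center: r for r in records}
        assert (by_center["A"].scale, by_center["A"].cutoff) == ("KPS", 50)
        assert (by_center["B"].scale, by_center["B"].cutoff) == ("KPS", 60)
        assert (by_center["C"].scale, by_center["C"].cutoff) == ("KPS", 70)
        assert (by_center["D"].scale, by_center["D"].cutoff) == ("KPS", 90)
        assert (by_center["E"].scale, by_center["E"].cutoff) == ("ECOG", 1)
        assert by_center["F"].scale is None and by_center["F"].cutoff is None
        assert by_center["F"].levels == ("good", "bad")
        assert by_center["F"].note  # the moderated 1:1 mapping is documented

    def test_rules_map_every_encoding_onto_fit_unfit(self):
        records, ruleset = synthetic.table1_fixture()
        assert ruleset.criteria.names == ("fitness",)
        assert ruleset.criteria["fitness"].levels == ("fit", "unfit")
        for record in records:
            resolved = ruleset.mapping_for(record.center, "performance_status")
            assert resolved is not None
            target, level_map = resolved
            assert target == "fitness"
            assert set(level_map) == set(record.levels)
            assert set(level_map.values()) == {"fit", "unfit"}

    def test_rules_applied_to_toy_kps_table(self):
        _, ruleset = synthetic.table1_fixture()
        table = kps_table("A")
        out = apply_rules(table, ruleset)
        assert out.criteria == ruleset.criteria
        assert out.cells[Scenario.from_mapping({"fitness": "fit"})] == RecommendationSet.single("chemo")
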