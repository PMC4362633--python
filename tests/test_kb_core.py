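"""Unit tests for the core data model: taxonomy, rules, Skolemization,
tree-model checking and consistency."""

import pytest

from biokr.kb_core import (
    CardinalityConstraint,
    ClassDef,
    GraphRule,
    Individual,
    InstanceGraph,
    KBError,
    KnowledgeBase,
    Quantifier,
    RuleEdge,
    RuleNode,
    check_consistency,
    check_tree_model,
    deskolemize,
    skolemize,
)
from biokr.oracle_and_synth import SynthParams, generate_synthetic_kb


def a1_rule():
    return GraphRule(
        "a1", "Cell",
        nodes=(
            RuleNode("x", "Cell", Quantifier.UNIVERSAL_ROOT),
            RuleNode("y1", "Ribosome"),
            RuleNode("y2", "Chromosome"),
        ),
        edges=(RuleEdge("x", "has-part", "y1"), RuleEdge("x", "has-part", "y2")),
    )


class TestTaxonomyAndRelations:
    def test_protoplast_is_under_cell_not_plant_cell(self, plant_kb):
        assert plant_kb.is_subclass_of("Protoplast", "Cell")
        assert not plant_kb.is_subclass_of("Protoplast", "Plant-Cell")

    def test_self_parent_is_a_cycle_error(self):
        kb = KnowledgeBase()
        with pytest.raises(KBError, match="cycle"):
            kb.add_class(ClassDef("X", parents=frozenset({"X"})))

    def test_longer_taxonomy_cycle_is_rejected(self):
        kb = KnowledgeBase()
        with pytest.raises(KBError, match="cycle"):
            kb.add_class([
                ClassDef("A", parents=frozenset({"B"})),
                ClassDef("B", parents=frozenset({"A"})),
            ])

    def test_unknown_parent_is_rejected(self):
        kb = KnowledgeBase()
        with pytest.raises(KBError, match="unknown parent"):
            kb.add_class(ClassDef("A", parents=frozenset({"Nowhere"})))

    def test_duplicate_class_is_rejected(self, cell_kb):
        with pytest.raises(KBError, match="duplicate"):
            cell_kb.add_class(ClassDef("Cell"))

    def test_inverse_of_inverse_is_self(self, upper_kb):
        assert upper_kb.relations["is-part-of"].inverse == "has-part"
        assert upper_kb.relations["has-part"].inverse == "is-part-of"

    def test_disjointness_with_ancestor_is_rejected(self):
        kb = KnowledgeBase()
        with pytest.raises(KBError, match="ancestor"):
            kb.add_class([
                ClassDef("A"),
                ClassDef("B", parents=frozenset({"A"}), disjoint_with=frozenset({"A"})),
            ])

    def test_disjointness_is_inherited_downward(self, biomembrane_kb):
        # declared on Polar vs Nonpolar; any subclasses inherit it
        assert biomembrane_kb.disjoint("Polar-Molecule", "Nonpolar-Molecule")
        assert biomembrane_kb.disjoint("Nonpolar-Molecule", "Polar-Molecule")
        assert not biomembrane_kb.disjoint("Polar-Molecule", "Chemical-Entity")


class TestValidateRule:
    def test_a1_rule_is_valid(self, cell_kb):
        assert cell_kb.validate_rule(a1_rule()) == []

    def test_two_root_nodes_is_one_violation(self, cell_kb):
        rule = GraphRule(
            "bad", "Cell",
            nodes=(
                RuleNode("x", "Cell", Quantifier.UNIVERSAL_ROOT),
                RuleNode("y", "Cell", Quantifier.UNIVERSAL_ROOT),
            ),
            edges=(RuleEdge("x", "has-part", "y"),),
        )
        violations = cell_kb.validate_rule(rule)
        assert len(violations) == 1
        assert "universal-root" in violations[0]

    def test_undeclared_relation_is_flagged_by_name(self, cell_kb):
        rule = GraphRule(
            "bad", "Cell",
            nodes=(RuleNode("x", "Cell", Quantifier.UNIVERSAL_ROOT), RuleNode("y", "Ribosome")),
            edges=(RuleEdge("x", "no-such-relation", "y"),),
        )
        violations = cell_kb.validate_rule(rule)
        assert any("no-such-relation" in v for v in violations)

    def test_disconnected_rule_graph_is_flagged(self, cell_kb):
        rule = GraphRule(
            "bad", "Cell",
            nodes=(RuleNode("x", "Cell", Quantifier.UNIVERSAL_ROOT), RuleNode("y", "Ribosome")),
            edges=(),
        )
        assert any("not connected" in v for v in cell_kb.validate_rule(rule))


class TestSkolemize:
    def test_a1_terms_are_named_after_filler_classes(self):
        srule = skolemize(a1_rule())
        assert [t.function_name for _, t in srule.terms] == ["ribosome-of", "chromosome-of"]
        assert all(t.argument == "x" and t.scope == "a1" for _, t in srule.terms)

    def test_skolemize_is_deterministic(self):
        assert skolemize(a1_rule()) == skolemize(a1_rule())

    def test_name_collision_gets_ordinal_suffix(self):
        rule = GraphRule(
            "r", "Cell",
            nodes=(
                RuleNode("x", "Cell", Quantifier.UNIVERSAL_ROOT),
                RuleNode("y1", "Ribosome"),
                RuleNode("y2", "Ribosome"),
            ),
            edges=(RuleEdge("x", "has-part", "y1"), RuleEdge("x", "has-part", "y2")),
        )
        names = [t.function_name for _, t in skolemize(rule).terms]
        assert names == ["ribosome-of", "ribosome-of-2"]

    def test_rule_without_existentials_has_empty_term_map(self):
        rule = GraphRule("r", "Cell", nodes=(RuleNode("x", "Cell", Quantifier.UNIVERSAL_ROOT),))
        srule = skolemize(rule)
        assert srule.terms == ()
        assert srule.edges == rule.edges

    @pytest.mark.parametrize("seed", range(20))
    def test_deskolemize_round_trips(self, seed):
        kb = generate_synthetic_kb(SynthParams(seed=seed, rules_per_class=2))
        for srule in kb.iter_rules():
            again = skolemize(deskolemize(srule), srule.equalities)
            assert again == srule


class TestTreeModel:
    def test_a1_is_a_tree(self):
        assert check_tree_model(a1_rule()).is_tree

    def test_containment_cross_edge_makes_chromosome_offending(self, cell_kb):
        rule = cell_kb.rule_by_id("eukaryotic-cell-parts")
        report = check_tree_model(rule)
        assert not report.is_tree
        assert report.offending_nodes == (("y3", 2),)

    def test_part_of_edge_back_into_root_breaks_tree(self, plant_kb):
        report = check_tree_model(plant_kb.rule_by_id("cell-wall-synthesis"))
        assert not report.is_tree
        assert ("x", 2) in report.offending_nodes

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_bruteforce_predecessor_count(self, seed):
        # 50 KBs x up to ~20 rules per draw: >1000 random rules in total
        kb = generate_synthetic_kb(SynthParams(
            seed=seed, n_classes=6, rules_per_class=3, max_nodes_per_rule=5,
            cross_edge_prob=0.5,
        ))
        for rule in kb.iter_rules():
            report = check_tree_model(rule)
            incoming = {n.var_id: set() for n in rule.nodes}
            for e in rule.edges:
                incoming[e.object].add((e.subject, e.relation))
            root = rule.root_var
            expected = tuple(
                (v, len(es)) for v, es in sorted(incoming.items())
                if len(es) >= 2 or (v == root and es)
            )
            assert report.offending_nodes == expected
            assert report.is_tree == (not expected)


class TestConsistency:
    def test_disjoint_labels_are_one_conflict(self, biomembrane_kb):
        g = InstanceGraph()
        g.individuals["m1"] = Individual("m1", "seed", {"Polar-Molecule", "Nonpolar-Molecule"})
        conflicts = check_consistency(biomembrane_kb, g)
        assert len(conflicts) == 1
        assert conflicts[0].kind == "disjoint-labels"

    def test_empty_graph_is_consistent(self, biomembrane_kb):
        assert check_consistency(biomembrane_kb, InstanceGraph()) == []

    def test_exceeding_exactly_one_is_a_conflict(self, cell_kb):
        import copy

        kb = copy.deepcopy(cell_kb)
        kb.add_constraint("Cell", "has-part", "Chromosome", CardinalityConstraint.exactly(1))
        g = InstanceGraph()
        g.individuals["c1"] = Individual("c1", "seed", {"Cell"})
        for i in range(3):
            cid = f"ch{i}"
            g.individuals[cid] = Individual(cid, "seed", {"Chromosome"})
            g.add_triple("c1", "has-part", cid, "asserted")
        conflicts = check_consistency(kb, g)
        assert len(conflicts) == 1
        assert conflicts[0].kind == "cardinality"

    def test_conflicts_are_monotone_under_new_assertions(self, biomembrane_kb):
        g = InstanceGraph()
        g.individuals["m1"] = Individual("m1", "seed", {"Polar-Molecule", "Nonpolar-Molecule"})
        before = {str(c) for c in check_consistency(biomembrane_kb, g)}
        g.individuals["m2"] = Individual("m2", "seed", {"Glycoprotein"})
        g.add_triple("m1", "is-inside", "m2", "asserted")
        g.individuals["m2"].class_labels.add("Polar-Molecule")
        after = {str(c) for c in check_consistency(biomembrane_kb, g)}
        assert before <= after


class TestCardinalityConstraint:
    def test_exactly_zero_encodes_negative_information(self, plant_kb):
        cc = plant_kb.constraints[("Protoplast", "has-part", "Cell-Wall")]
        assert cc.min == 0 and cc.max == 0 and cc.is_exact

    def test_min_above_max_is_rejected(self):
        with pytest.raises(KBError):
            CardinalityConstraint(3, 1)
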