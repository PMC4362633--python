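"""Elaboration and the six question-answering operation families."""

from dataclasses import replace

import pytest

from biokr.io_formats import parse_kb
from biokr.kb_core import CardinalityConstraint, KBError
from biokr.ontology_fixtures import load_example_kb, load_upper_ontology
from biokr.reasoner import (
    Path,
    analogy,
    cardinality_query,
    compare,
    describe,
    elaborate,
    find_relationship,
    infer_cardinality_equalities,
    query_during,
    query_relation_values,
    spatial_relations_among,
    taxonomy_query,
    trace_importance,
)


def kb_from(text: str):
    return parse_kb(text, base=load_upper_ontology())


def most_specific_filler_classes(kb, graph, seed_cls, relation):
    seed = next(i for i in graph.individuals.values()
                if i.origin == "seed" and seed_cls in i.class_labels)
    out = set()
    for _, r, o in graph.outgoing(seed.id, {relation}):
        out |= graph.individuals[o].most_specific_labels(kb)
    return out


class TestElaborate:
    def test_cell_sample_has_ribosome_and_chromosome_parts(self, cell_kb):
        g = elaborate(cell_kb, "Cell", 1)
        assert most_specific_filler_classes(cell_kb, g, "Cell", "has-part") == {
            "Ribosome", "Chromosome",
        }

    def test_eukaryotic_cell_inherits_and_specializes(self, cell_kb):
        g = elaborate(cell_kb, "Eukaryotic-Cell", 1)
        fillers = most_specific_filler_classes(cell_kb, g, "Eukaryotic-Cell", "has-part")
        assert fillers == {"Ribosome", "Nucleus", "Eukaryotic-Chromosome"}
        # the inherited chromosome and the eukaryotic chromosome are one
        # individual carrying both labels
        chroms = g.instances_of(cell_kb, "Chromosome")
        assert len(chroms) == 1
        assert chroms[0].class_labels == {"Chromosome", "Eukaryotic-Chromosome"}
        # the chromosome is inside the nucleus
        nucleus = g.instances_of(cell_kb, "Nucleus")[0]
        assert (chroms[0].id, "is-inside", nucleus.id) in g.triples

    def test_class_without_rules_elaborates_to_seed_only(self, cell_kb):
        g = elaborate(cell_kb, "Ribosome", 3)
        assert len(g.individuals) == 1 and not g.triples

    def test_unknown_class_raises(self, cell_kb):
        with pytest.raises(KBError, match="unknown class"):
            elaborate(cell_kb, "Mitochondrion", 1)

    def test_depth_must_be_positive(self, cell_kb):
        with pytest.raises(KBError, match="depth"):
            elaborate(cell_kb, "Cell", 0)

    def test_monotone_in_depth(self, plant_kb):
        prev: set = set()
        for d in (1, 2, 3):
            g = elaborate(plant_kb, "Plant-Cell", d)
            assert prev <= g.triples
            prev = g.triples

    def test_deterministic(self, plant_kb):
        g1 = elaborate(plant_kb, "Plant-Cell", 3)
        g2 = elaborate(plant_kb, "Plant-Cell", 3)
        assert sorted(g1.triples) == sorted(g2.triples)
        assert sorted(g1.individuals) == sorted(g2.individuals)

    def test_recursive_part_cycle_terminates(self):
        kb = kb_from(
            "class Looper is-a Entity\n"
            "rule loop of Looper\n"
            "  node x Looper root\n"
            "  node y Looper\n"
            "  edge x has-part y\n"
            "end\n"
        )
        g = elaborate(kb, "Looper", 4)
        assert len(g.individuals) == 5  # seed + one filler per level


class TestCardinalityEqualityInference:
    @pytest.fixture()
    def unlinked_kb(self):
        """Cell KB with the equality removed: the inherited chromosome and
        the eukaryotic chromosome stay separate individuals."""
        kb = load_example_kb("cell-a1-a4")
        rule = kb.rule_by_id("eukaryotic-cell-parts")
        kb.rules["Eukaryotic-Cell"] = [replace(rule, equalities=())]
        return kb

    def test_exactly_one_constraint_merges_chromosomes(self, unlinked_kb):
        unlinked_kb.add_constraint("Cell", "has-part", "Chromosome",
                                   CardinalityConstraint.exactly(1))
        g = elaborate(unlinked_kb, "Eukaryotic-Cell", 1)
        assert len(g.instances_of(unlinked_kb, "Chromosome")) == 2
        g = infer_cardinality_equalities(unlinked_kb, g)
        merged = g.instances_of(unlinked_kb, "Chromosome")
        assert len(merged) == 1
        assert merged[0].class_labels == {"Chromosome", "Eukaryotic-Chromosome"}

    def test_without_constraint_nothing_merges(self, unlinked_kb):
        g = elaborate(unlinked_kb, "Eukaryotic-Cell", 1)
        g = infer_cardinality_equalities(unlinked_kb, g)
        assert len(g.instances_of(unlinked_kb, "Chromosome")) == 2

    def test_idempotent_when_already_satisfied(self, unlinked_kb):
        unlinked_kb.add_constraint("Cell", "has-part", "Chromosome",
                                   CardinalityConstraint.exactly(1))
        g = infer_cardinality_equalities(unlinked_kb, elaborate(unlinked_kb, "Eukaryotic-Cell", 1))
        before = (sorted(g.individuals), sorted(g.triples))
        g = infer_cardinality_equalities(unlinked_kb, g)
        assert (sorted(g.individuals), sorted(g.triples)) == before


class TestRelationValues:
    def test_cell_parts(self, cell_kb):
        assert query_relation_values(cell_kb, "Cell", "has-part") == {
            ("Ribosome", "has-part"), ("Chromosome", "has-part"),
        }

    def test_structure_expands_over_subrelations(self, biomembrane_kb):
        answers = query_relation_values(biomembrane_kb, "Biomembrane", "has-structure",
                                        expand=True)
        assert ("Phospholipid-Bilayer", "has-part") in answers
        assert ("Glycoprotein", "has-part") in answers
        assert ("Selective-Permeability", "possesses") in answers
        # unexpanded query on the parent relation alone finds nothing
        assert query_relation_values(biomembrane_kb, "Biomembrane", "has-structure") == set()

    def test_spatial_relations_complete_the_structural_description(self, biomembrane_kb):
        spatial = spatial_relations_among(biomembrane_kb, "Biomembrane")
        assert ("Glycoprotein", "is-inside", "Phospholipid-Bilayer") in spatial

    def test_class_with_no_rules_has_no_values(self, cell_kb):
        assert query_relation_values(cell_kb, "Nucleus", "has-part") == set()


class TestQueryDuring:
    def test_plant_cell_is_agent_of_its_wall_synthesis(self, plant_kb):
        assert query_during(plant_kb, "Plant-Cell", "Synthesis-of-Cell-Wall", "agent") == {
            "Synthesis-of-Cell-Wall",
        }

    def test_role_never_filled_gives_empty(self, plant_kb):
        assert query_during(plant_kb, "Plant-Cell", "Synthesis-of-Cell-Wall",
                            "raw-material") == set()

    def test_only_the_step_with_the_role_is_returned(self):
        kb = kb_from(
            "class Enzyme is-a Entity\n"
            "class Pathway is-a Event\n"
            "class Step-One is-a Event\n"
            "class Step-Two is-a Event\n"
            "class Step-Three is-a Event\n"
            "rule pathway-steps of Pathway\n"
            "  node p Pathway root\n"
            "  node s1 Step-One\n"
            "  node s2 Step-Two\n"
            "  node s3 Step-Three\n"
            "  node z Enzyme\n"
            "  edge p subevent s1\n"
            "  edge p subevent s2\n"
            "  edge p subevent s3\n"
            "  edge s2 agent z\n"
            "end\n"
        )
        assert query_during(kb, "Enzyme", "Pathway", "agent") == {"Step-Two"}

    def test_non_event_target_raises(self, plant_kb):
        with pytest.raises(KBError, match="not an Event"):
            query_during(plant_kb, "Plant-Cell", "Cell-Wall", "agent")


class TestTaxonomyQuery:
    def test_subclasses_of_cell(self, plant_kb):
        assert taxonomy_query(plant_kb, "Cell", "subclasses") == {
            "Eukaryotic-Cell", "Plant-Cell", "Protoplast",
        }

    def test_is_subclass_of_is_reflexive(self, cell_kb):
        assert taxonomy_query(cell_kb, "Cell", other="Cell") is True

    def test_superclasses_of_move_through(self, upper_kb):
        sups = taxonomy_query(upper_kb, "Move-Through", "superclasses")
        assert {"Move", "Action", "Event"} <= sups


class TestCardinalityQuery:
    def test_bilayer_has_exactly_two_layers(self, biomembrane_kb):
        cc = cardinality_query(biomembrane_kb, "Phospholipid-Bilayer", "has-region",
                               "Phospholipid-Layer")
        assert cc == CardinalityConstraint.exactly(2)

    def test_unconstrained_triple_is_none(self, cell_kb):
        assert cardinality_query(cell_kb, "Cell", "has-part", "Ribosome") is None

    def test_subclass_constraint_overrides_superclass(self):
        kb = kb_from(
            "class Base is-a Entity\n"
            "class Special is-a Base\n"
            "class Widget is-a Entity\n"
            "constraint Base has-part Widget exactly 1\n"
            "constraint Special has-part Widget exactly 3\n"
        )
        assert cardinality_query(kb, "Special", "has-part", "Widget") == CardinalityConstraint.exactly(3)
        assert cardinality_query(kb, "Base", "has-part", "Widget") == CardinalityConstraint.exactly(1)


class TestDescribe:
    def test_describe_is_exactly_the_union_of_subqueries(self, cell_kb):
        d = describe(cell_kb, "Cell")
        assert d.superclasses == taxonomy_query(cell_kb, "Cell", "superclasses")
        assert d.subclasses == taxonomy_query(cell_kb, "Cell", "subclasses")
        for rel, fillers in d.relation_values:
            assert {(f, rel) for f in fillers} == query_relation_values(cell_kb, "Cell", rel)
        for (rel, filler), cc in d.cardinalities:
            assert cardinality_query(cell_kb, "Cell", rel, filler) == cc
        # nothing extra: every relation with values appears
        g = elaborate(cell_kb, "Cell")
        seed = next(i.id for i in g.individuals.values() if i.origin == "seed")
        assert {r for _, r, _ in g.outgoing(seed)} == {r for r, _ in d.relation_values}

    def test_isolated_leaf_describes_taxonomy_only(self, cell_kb):
        d = describe(cell_kb, "Nucleus")
        assert d.relation_values == () and d.cardinalities == ()
        assert "Entity" in d.superclasses

    def test_biomembrane_description_unites_structure_and_function(self, biomembrane_kb):
        d = describe(biomembrane_kb, "Biomembrane")
        values = d.relation_value_map
        assert {"Phospholipid-Bilayer", "Glycoprotein"} <= values["has-part"]
        assert {"Move-Through", "Block"} <= values["has-function"]


class TestCompare:
    def test_compare_with_itself_is_identical(self, biomembrane_kb):
        assert compare(biomembrane_kb, "Biomembrane", "Biomembrane").is_identical

    def test_eukaryotic_cell_vs_cell(self, cell_kb):
        r = compare(cell_kb, "Eukaryotic-Cell", "Cell")
        assert ("has-part", "Ribosome") in r.similarities
        assert ("has-part", "Eukaryotic-Chromosome", "Chromosome") in r.differences
        assert ("has-part", "Nucleus", None) in r.differences

    def test_restriction_to_structure_ignores_function_slots(self, biomembrane_kb):
        r = compare(biomembrane_kb, "Biomembrane", "Glycoprotein", restrict_to="has-structure")
        rels = {rel for rel, *_ in r.differences} | set(r.slots_only_in_x) | set(r.slots_only_in_y)
        assert "has-function" not in rels and "permeable-to" not in rels

    def test_symmetric_up_to_column_swap(self, cell_kb):
        a = compare(cell_kb, "Eukaryotic-Cell", "Cell")
        b = compare(cell_kb, "Cell", "Eukaryotic-Cell")
        assert a.similarities == b.similarities

        def key(t):
            return (t[0], t[1] or "", t[2] or "")

        assert sorted(((r, y, x) for r, x, y in a.differences), key=key) == \
            sorted(b.differences, key=key)


class TestFindRelationship:
    def test_dna_to_gene_is_two_part_hops(self, dna_kb):
        paths = find_relationship(dna_kb, "DNA-Molecule", "Gene")
        assert paths, "expected at least one path"
        assert paths[0].relations == ("has-part", "has-part")

    def test_same_class_gives_the_empty_path(self, dna_kb):
        assert find_relationship(dna_kb, "Gene", "Gene") == [Path(())]

    def test_taxonomic_link_ranks_before_graph_paths(self, cell_kb):
        paths = find_relationship(cell_kb, "Eukaryotic-Cell", "Cell")
        assert paths[0].relations == ("subclass-of",)

    def test_diamond_returns_both_paths_in_deterministic_order(self):
        kb = kb_from(
            "class Top is-a Entity\n"
            "class Left is-a Entity\n"
            "class Right is-a Entity\n"
            "class Bottom is-a Entity\n"
            "rule top-parts of Top\n"
            "  node x Top root\n"
            "  node l Left\n"
            "  node r Right\n"
            "  edge x has-part l\n"
            "  edge x has-region r\n"
            "end\n"
            "rule left-parts of Left\n"
            "  node x Left root\n"
            "  node b Bottom\n"
            "  edge x has-part b\n"
            "end\n"
            "rule right-parts of Right\n"
            "  node x Right root\n"
            "  node b Bottom\n"
            "  edge x has-part b\n"
            "end\n"
        )
        paths = find_relationship(kb, "Top", "Bottom", 3)
        assert len(paths) == 2
        sigs = [p.relations for p in paths]
        assert sigs == [("has-part", "has-part"), ("has-region", "has-part")]
        assert paths == find_relationship(kb, "Top", "Bottom", 3)

    def test_no_relationship_is_an_empty_list(self, dna_kb):
        assert find_relationship(dna_kb, "Gene", "DNA-Strand", 2) == []


class TestAnalogy:
    def test_replaying_the_defining_path_gives_y(self, dna_kb):
        assert analogy(dna_kb, "DNA-Molecule", "Gene", "DNA-Molecule") == {"Gene"}

    def test_same_shape_molecule_lands_two_part_hops_away(self):
        kb = kb_from(
            "class Alpha is-a Entity\nclass Beta is-a Entity\nclass Gamma is-a Entity\n"
            "class Alpha-Prime is-a Entity\nclass Beta-Prime is-a Entity\n"
            "class Gamma-Prime is-a Entity\n"
            "rule alpha-parts of Alpha\n  node x Alpha root\n  node b Beta\n"
            "  edge x has-part b\nend\n"
            "rule beta-parts of Beta\n  node x Beta root\n  node g Gamma\n"
            "  edge x has-part g\nend\n"
            "rule alpha-prime-parts of Alpha-Prime\n  node x Alpha-Prime root\n"
            "  node b Beta-Prime\n  edge x has-part b\nend\n"
            "rule beta-prime-parts of Beta-Prime\n  node x Beta-Prime root\n"
            "  node g Gamma-Prime\n  edge x has-part g\nend\n"
        )
        assert analogy(kb, "Alpha", "Gamma", "Alpha-Prime") == {"Gamma-Prime"}

    def test_untraversable_signature_gives_empty(self, dna_kb):
        assert analogy(dna_kb, "DNA-Molecule", "Gene", "Gene") == set()


class TestTraceImportance:
    def test_permeability_facilitates_the_transport_function(self, biomembrane_kb):
        paths = trace_importance(biomembrane_kb, "Biomembrane", "Selective-Permeability")
        assert len(paths) == 1
        assert paths[0].relations == ("facilitates",)

    def test_no_facilitates_edges_gives_empty(self, cell_kb):
        kb = load_example_kb("cell-a1-a4")
        assert trace_importance(kb, "Cell", "has-part") == []

    def test_facilitates_chain_of_length_two_is_found(self):
        kb = kb_from(
            "class Machine is-a Entity\n"
            "class Stiffness is-a Entity\n"
            "class Leverage is-a Entity\n"
            "rule machine-function of Machine\n"
            "  node x Machine root\n"
            "  node q Stiffness\n"
            "  node lv Leverage\n"
            "  node f Move\n"
            "  edge x possesses q\n"
            "  edge x has-function f\n"
            "  edge q facilitates lv\n"
            "  edge lv facilitates f\n"
            "end\n"
        )
        paths = trace_importance(kb, "Machine", "Stiffness")
        assert [p.relations for p in paths] == [("facilitates", "facilitates")]
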