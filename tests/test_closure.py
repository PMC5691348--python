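"""Interest closures: fixed-point traversal, cycle safety, ontology membership."""

import pytest

from pgdbnotify import oracle
from pgdbnotify.closure import ClosureEngine, gene_closure, load_relation_config, pathway_closure, term_members
from pgdbnotify.errors import OntologyError, ResolutionError
from pgdbnotify.model import Snapshot
from pgdbnotify.synth import BaseParams, generate_base

from conftest import add_obj

FIXTURE_B_GENE_CLOSURE = {"TRPA", "TRPA-MONOMER", "TRPAB", "ENZRXN-1", "RXN-1", "PWY-TRP", "REG-1"}
FIXTURE_B_PATHWAY_CLOSURE = {
    "PWY-TRP", "RXN-1", "CPD-IGP", "CPD-TRP", "ENZRXN-1", "TRPAB", "TRPA-MONOMER", "TRPA", "REG-1",
}


class TestGeneClosure:
    def test_gene_without_product_is_alone(self):
        s = Snapshot("DB", "1")
        add_obj(s, "G1", ["GENE"])
        assert gene_closure(s, "G1").members == {"G1"}

    def test_trp_neighborhood(self, fixture_b):
        assert gene_closure(fixture_b, "TRPA").members == FIXTURE_B_GENE_CLOSURE

    def test_metabolites_excluded_from_gene_closure(self, fixture_b):
        assert not {"CPD-IGP", "CPD-TRP"} & gene_closure(fixture_b, "TRPA").members

    def test_complex_of_complex_chain_depth_five(self):
        s = Snapshot("DB", "1")
        add_obj(s, "G1", ["GENE"], {"PRODUCT": ["M1"]})
        add_obj(s, "M1", ["PROTEIN"], {"COMPONENT-OF": ["C1"]})
        for level in range(1, 6):
            below = "M1" if level == 1 else f"C{level - 1}"
            parent = {"COMPONENT-OF": [f"C{level + 1}"]} if level < 5 else {}
            add_obj(s, f"C{level}", ["PROTEIN", "COMPLEX"], {"COMPONENTS": [below], **parent})
        assert gene_closure(s, "G1").members == {"G1", "M1", "C1", "C2", "C3", "C4", "C5"}

    def test_component_of_cycle_terminates(self):
        s = Snapshot("DB", "1")
        add_obj(s, "G1", ["GENE"], {"PRODUCT": ["M1"]})
        add_obj(s, "M1", ["PROTEIN"], {"COMPONENT-OF": ["A"]})
        add_obj(s, "A", ["PROTEIN", "COMPLEX"], {"COMPONENT-OF": ["B"]})
        add_obj(s, "B", ["PROTEIN", "COMPLEX"], {"COMPONENT-OF": ["A"]})
        assert gene_closure(s, "G1").members == {"G1", "M1", "A", "B"}

    def test_transcription_unit_and_its_regulation_included(self):
        s = Snapshot("DB", "1")
        add_obj(s, "G1", ["GENE"])
        add_obj(s, "TU1", ["TRANSCRIPTION-UNIT"], {"GENES": ["G1"]})
        add_obj(s, "REG-TU", ["REGULATION"], {"REGULATED-ENTITY": ["TU1"]})
        assert gene_closure(s, "G1").members == {"G1", "TU1", "REG-TU"}

    def test_unknown_gene_raises(self, fixture_b):
        with pytest.raises(ResolutionError):
            gene_closure(fixture_b, "NO-SUCH-GENE")

    def test_provenance_paths_start_at_anchor(self, fixture_b):
        result = gene_closure(fixture_b, "TRPA")
        assert result.provenance["TRPA"] == []
        for member, path in result.provenance.items():
            if member != "TRPA":
                assert path[-1][1] == member
                assert len(path) >= 1


class TestPathwayClosure:
    def test_empty_reaction_list_is_alone(self):
        s = Snapshot("DB", "1")
        add_obj(s, "PWY", ["PATHWAY"])
        assert pathway_closure(s, "PWY").members == {"PWY"}

    def test_trp_pathway_members(self, fixture_b):
        assert pathway_closure(fixture_b, "PWY-TRP").members == FIXTURE_B_PATHWAY_CLOSURE

    def test_nested_sub_pathway_expanded(self, fixture_b):
        s = fixture_b
        add_obj(s, "PWY-SUPER", ["PATHWAY"], {"REACTION-LIST": ["PWY-TRP", "RXN-2"]})
        add_obj(s, "RXN-2", ["REACTION"], {"LEFT": ["CPD-TRP"], "RIGHT": ["CPD-X"]})
        add_obj(s, "CPD-X", ["COMPOUND"])
        members = pathway_closure(s, "PWY-SUPER").members
        assert FIXTURE_B_PATHWAY_CLOSURE <= members
        assert {"PWY-SUPER", "RXN-2", "CPD-X"} <= members


class TestTermMembers:
    @pytest.fixture
    def go_snapshot(self):
        s = Snapshot("DB", "1")
        add_obj(s, "GO:1", ["GO-TERM"])
        add_obj(s, "GO:2", ["GO-TERM"], {"PARENTS": ["GO:1"]})
        add_obj(s, "GO:3", ["GO-TERM"], {"PARENTS": ["GO:1"]})
        add_obj(s, "GO:4", ["GO-TERM"])  # unrelated branch
        add_obj(s, "G1", ["GENE"], {"GO-TERMS": ["GO:2"]})
        add_obj(s, "G2", ["GENE"], {"GO-TERMS": ["GO:3"]})
        add_obj(s, "G3", ["GENE"], {"GO-TERMS": ["GO:4"]})
        return s

    def test_leaf_term_direct_annotation(self, go_snapshot):
        assert term_members(go_snapshot, "GO:2", "GO-TERM") == {"G1"}

    def test_true_path_rule_collects_descendant_annotations(self, go_snapshot):
        assert term_members(go_snapshot, "GO:1", "GO-TERM") == {"G1", "G2"}

    def test_term_with_no_annotations_below_is_empty(self, go_snapshot):
        add_obj(go_snapshot, "GO:5", ["GO-TERM"], {"PARENTS": ["GO:4"]})
        assert term_members(go_snapshot, "GO:5", "GO-TERM") == set()

    def test_parents_cycle_raises(self):
        s = Snapshot("DB", "1")
        add_obj(s, "GO:1", ["GO-TERM"], {"PARENTS": ["GO:2"]})
        add_obj(s, "GO:2", ["GO-TERM"], {"PARENTS": ["GO:1"]})
        with pytest.raises(OntologyError):
            term_members(s, "GO:1", "GO-TERM")

    def test_pathway_class_membership_via_types_chain(self):
        s = Snapshot("DB", "1")
        add_obj(s, "CLASS-ROOT", ["PATHWAY-CLASS"])
        add_obj(s, "CLASS-A", ["PATHWAY-CLASS"], {"PARENTS": ["CLASS-ROOT"]})
        add_obj(s, "PWY-1", ["PATHWAY", "CLASS-A"])
        add_obj(s, "PWY-2", ["PATHWAY", "CLASS-ROOT"])
        assert term_members(s, "CLASS-ROOT", "PATHWAY-CLASS") == {"PWY-1", "PWY-2"}
        assert term_members(s, "CLASS-A", "PATHWAY-CLASS") == {"PWY-1"}

    def test_unknown_term_raises(self, go_snapshot):
        with pytest.raises(ResolutionError):
            term_members(go_snapshot, "GO:999", "GO-TERM")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_closures_match_naive_fixed_point(self, seed):
        s = generate_base(BaseParams(n_genes=10, n_terms=6, n_pathways=3), seed)
        engine = ClosureEngine(s)
        for gene in sorted(o.id for o in s.objects.values() if "GENE" in o.classes):
            assert engine.gene_closure(gene).members == oracle.naive_gene_closure(s, gene), gene
        for pwy in sorted(o.id for o in s.objects.values() if "PATHWAY" in o.classes):
            assert engine.pathway_closure(pwy).members == oracle.naive_pathway_closure(s, pwy), pwy


def test_adding_relation_edge_is_monotone(fixture_b):
    before = gene_closure(fixture_b, "TRPA").members
    add_obj(fixture_b, "REG-2", ["REGULATION"], {"REGULATED-ENTITY": ["TRPA-MONOMER"]})
    after = gene_closure(fixture_b, "TRPA").members
    assert before <= after and "REG-2" in after


def test_gene_closure_within_its_pathway_closure(fixture_b):
    """When a gene's whole product chain serves one pathway, the pathway covers it."""
    gene_members = gene_closure(fixture_b, "TRPA").members
    pwy_members = pathway_closure(fixture_b, "PWY-TRP").members
    assert gene_members <= pwy_members


def test_relation_config_round_trip(tmp_path):
    """A config loaded from an explicit YAML path behaves like the default."""
    from importlib import resources

    text = resources.files("pgdbnotify.data").joinpath("relations.yaml").read_text()
    p = tmp_path / "relations.yaml"
    p.write_text(text)
    assert load_relation_config(str(p)) == load_relation_config(None)
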