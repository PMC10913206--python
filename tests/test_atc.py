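"""ATC scaffold construction, label normalization and concept placement."""
import pytest

from fdiforge.atc import (
    ATC_URL,
    AtcEntry,
    AtcError,
    NEC_LABEL,
    atc_label_normalize,
    build_atc_scaffold,
    check_acyclic,
    place_drug,
    place_food_or_herb,
)
from fdiforge.config import DEFAULT_CONFIG
from fdiforge.mapping import MappingResult


@pytest.fixture
def entries():
    return [
        AtcEntry("A", "ALIMENTARY TRACT AND METABOLISM"),
        AtcEntry("B", "BLOOD AND BLOOD FORMING ORGANS"),
        AtcEntry("C", "CARDIOVASCULAR SYSTEM"),
        AtcEntry("S", "SENSORY ORGANS"),
        AtcEntry("B01", "ANTITHROMBOTIC AGENTS"),
        AtcEntry("C05", "VASOPROTECTIVES"),
        AtcEntry("S01", "OPHTHALMOLOGICALS"),
    ]


@pytest.fixture
def scaffold(entries):
    return build_atc_scaffold(entries)


class TestLabelNormalize:
    def test_level1_rewording(self):
        entry = AtcEntry("A", "ALIMENTARY TRACT AND METABOLISM")
        assert atc_label_normalize(entry) == (
            "drug target of alimentary tract and metabolism"
        )

    def test_level2_lowercase_singular(self):
        assert atc_label_normalize(AtcEntry("B01", "ANTITHROMBOTIC AGENTS")) == (
            "antithrombotic agent"
        )
        assert atc_label_normalize(AtcEntry("C05", "VASOPROTECTIVES")) == (
            "vasoprotective"
        )

    def test_idempotent(self):
        once = atc_label_normalize(AtcEntry("B01", "ANTITHROMBOTIC AGENTS"))
        assert atc_label_normalize(AtcEntry("B01", once)) == once
        l1 = atc_label_normalize(AtcEntry("A", "ALIMENTARY TRACT AND METABOLISM"))
        assert atc_label_normalize(AtcEntry("A", l1)) == l1

    def test_latinate_and_exception_endings_kept(self):
        assert atc_label_normalize(AtcEntry("V03", "VARIOUS")).endswith("various")
        assert atc_label_normalize(AtcEntry("J05", "ANTIVIRALS FOR SYSTEMIC USE")) == (
            "antivirals for systemic use"  # head noun "use" has no plural s
        )

    def test_rename_override_wins(self):
        entry = AtcEntry("V", "VARIOUS")
        assert atc_label_normalize(entry, {"V": "drug target of various systems"}) == (
            "drug target of various systems"
        )


class TestScaffold:
    def test_every_class_carries_its_code_xref(self, scaffold):
        xrefs = {
            x for n in scaffold.nodes.values() for x in n.xrefs
        }
        for code in ("A", "B01", "S01"):
            assert ATC_URL.format(code=code) in xrefs

    def test_node_accounting(self, entries, scaffold):
        atc_nodes = [n for n in scaffold.nodes.values() if n.node_kind == "atc_class"]
        # one class per entry plus the not-elsewhere-classified class
        assert len(atc_nodes) == len(entries) + 1
        assert scaffold.nodes[scaffold.nec_curie].label == NEC_LABEL

    def test_level2_parent_is_its_level1_class(self, scaffold):
        b01 = scaffold.nodes[scaffold.by_code["B01"]]
        assert b01.parents == {scaffold.by_code["B"]}
        b = scaffold.nodes[scaffold.by_code["B"]]
        assert b.parents == {DEFAULT_CONFIG.chemical_entity}

    def test_empty_entry_list_keeps_roots_and_nec(self):
        sc = build_atc_scaffold([])
        kinds = [n.node_kind for n in sc.nodes.values()]
        assert kinds.count("atc_class") == 1  # the NEC class only
        assert DEFAULT_CONFIG.chemical_entity in sc.nodes

    def test_orphan_level2_rejected(self):
        with pytest.raises(AtcError, match="orphan"):
            build_atc_scaffold([AtcEntry("B01", "ANTITHROMBOTIC AGENTS")])

    def test_acyclic_and_rooted(self, scaffold):
        order = check_acyclic(scaffold.node_list())
        assert set(order) == set(scaffold.nodes)

    def test_deterministic_minting(self, entries):
        a = build_atc_scaffold(entries)
        b = build_atc_scaffold(list(reversed(entries)))
        assert a.by_code == b.by_code


class TestPlacement:
    def _drug(self, term, curie="CHEBI:28304"):
        return MappingResult(term, "drug", curie, "CHEBI", "label", term)

    def test_multi_code_drug_has_one_parent_per_code(self, scaffold):
        node = place_drug(self._drug("heparin"), {"B01", "C05", "S01"}, scaffold)
        assert node.parents == {
            scaffold.by_code["B01"], scaffold.by_code["C05"], scaffold.by_code["S01"]
        }
        assert node.node_kind == "drug"

    def test_codeless_drug_under_not_elsewhere_classified(self, scaffold):
        node = place_drug(
            MappingResult("ardeparin", "drug", "DrOn:00017208", "DRON", "label",
                          "ardeparin"),
            set(), scaffold,
        )
        assert node.parents == {scaffold.nec_curie}

    def test_single_code_single_parent(self, scaffold):
        node = place_drug(self._drug("warfarin"), {"B01"}, scaffold)
        assert len(node.parents) == 1

    def test_unknown_code_listed_in_error(self, scaffold):
        with pytest.raises(AtcError, match="Z99"):
            place_drug(self._drug("x"), {"Z99"}, scaffold)

    def test_food_under_food_product(self, scaffold):
        m = MappingResult("garlic", "food", "FoodOn:1", "FOODON", "label",
                          "garlic food product")
        node = place_food_or_herb(m, scaffold)
        assert node.parents == {DEFAULT_CONFIG.food_product}

    def test_drug_ontology_herb_under_processed_material(self, scaffold):
        m = MappingResult("licorice", "herb", "DrOn:00018111", "DRON", "label",
                          "licorice")
        node = place_food_or_herb(m, scaffold)
        assert node.parents == {DEFAULT_CONFIG.processed_material}

    def test_food_with_drug_ontology_hit_rejected(self, scaffold):
        m = MappingResult("weird", "food", "DrOn:1", "DRON", "label", "weird")
        with pytest.raises(AtcError, match="cascade"):
            place_food_or_herb(m, scaffold)

    def test_unmapped_term_skipped(self, scaffold):
        assert place_food_or_herb(MappingResult("x", "food"), scaffold) is None
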