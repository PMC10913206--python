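"""Term normalization, cascade resolution and the coverage report."""
import pytest
from hypothesis import given, settings, strategies as st

from fdiforge.mapping import (
    IndexBuildError,
    MappingError,
    TermIndex,
    build_report,
    map_term,
    normalize_term,
    round_half_up_pct,
    suggest_near_matches,
)


@pytest.fixture
def indexes():
    chebi = TermIndex("CHEBI")
    chebi.add("CHEBI:10033", "warfarin", ["coumadin"])
    dron = TermIndex("DRON")
    dron.add("DrOn:00017208", "ardeparin")
    dron.add("DrOn:00018111", "licorice")
    foodon = TermIndex("FOODON")
    foodon.add("FoodOn:03301844", "garlic food product", ["garlic"])
    return {"CHEBI": chebi, "DRON": dron, "FOODON": foodon}


class TestNormalize:
    def test_case_and_space_folding(self):
        assert normalize_term("St. John’s Wort ") == "st. john’s wort"
        assert normalize_term("Garlic") == normalize_term("garlic")
        assert normalize_term("  leafy \t vegetables ") == "leafy vegetables"

    @settings(derandomize=True, max_examples=500)
    @given(st.text(max_size=40))
    def test_idempotent(self, s):
        assert normalize_term(normalize_term(s)) == normalize_term(s)


class TestCascade:
    def test_first_ontology_hit_stops_cascade(self, indexes):
        r = map_term("Warfarin", "drug", indexes)
        assert (r.curie, r.hit_ontology, r.match_kind) == (
            "CHEBI:10033", "CHEBI", "label"
        )

    def test_fallback_to_drug_product_ontology(self, indexes):
        r = map_term("ardeparin", "drug", indexes)
        assert (r.curie, r.hit_ontology) == ("DrOn:00017208", "DRON")

    def test_synonym_outranked_by_label_but_found(self, indexes):
        r = map_term("coumadin", "drug", indexes)
        assert r.match_kind == "synonym" and r.curie == "CHEBI:10033"

    def test_food_cascade_never_reaches_drug_ontology(self, indexes):
        assert not map_term("licorice", "food", indexes).mapped
        herb = map_term("licorice", "herb", indexes)
        assert herb.hit_ontology == "DRON"

    def test_unmapped_miss(self, indexes):
        r = map_term("nonexistent", "drug", indexes)
        assert not r.mapped and r.curie is None and r.match_kind == "unmapped"

    def test_unknown_category_is_configuration_error(self, indexes):
        with pytest.raises(MappingError, match="category"):
            map_term("x", "mineral", indexes)

    def test_overrides_fill_only_unmapped_unless_forced(self, indexes):
        ov = {("warfarin", "drug"): ("X:1", "other"),
              ("ardeparine", "drug"): ("X:2", "manual hit")}
        assert map_term("warfarin", "drug", indexes, ov).curie == "CHEBI:10033"
        assert map_term("warfarin", "drug", indexes, ov, force_overrides=True).curie == "X:1"
        r = map_term("Ardeparine", "drug", indexes, ov)
        assert r.match_kind == "manual" and r.curie == "X:2"

    def test_mapping_is_pure(self, indexes):
        assert map_term("garlic", "herb", indexes) == map_term("garlic", "herb", indexes)

    def test_dron_drug_hit_implies_absent_from_chebi(self, indexes):
        for term in ("warfarin", "ardeparin", "licorice", "coumadin"):
            r = map_term(term, "drug", indexes)
            if r.hit_ontology == "DRON":
                assert indexes["CHEBI"].find(normalize_term(term)) is None


class TestIndexBuild:
    def test_ambiguous_label_fails_loudly(self):
        idx = TermIndex("CHEBI")
        idx.add("CHEBI:1", "aspirin")
        with pytest.raises(IndexBuildError, match="dedupe"):
            idx.add("CHEBI:2", "Aspirin")

    def test_malformed_curie_rejected(self):
        with pytest.raises(IndexBuildError):
            TermIndex("CHEBI").add("not a curie", "x")

    def test_tsv_roundtrip(self, tmp_path, indexes):
        p = tmp_path / "chebi.tsv"
        p.write_text("CHEBI:10033\twarfarin\tcoumadin\n", encoding="utf-8")
        idx = TermIndex.from_tsv("CHEBI", p)
        assert idx.find("warfarin") == ("CHEBI:10033", "warfarin", "label")
        assert idx.find("coumadin")[2] == "synonym"


class TestReport:
    def _results(self, indexes):
        terms = [
            ("warfarin", "drug"), ("ardeparin", "drug"), ("unknowndrug", "drug"),
            ("garlic", "food"), ("mysteryfood", "food"),
            ("licorice", "herb"), ("garlic", "herb"),
        ]
        return [map_term(t, c, indexes) for t, c in terms]

    def test_conservation_per_category(self, indexes):
        report = build_report(self._results(indexes), indexes)
        for cat, r in report.categories.items():
            assert sum(r.by_ontology.values()) + r.manual + r.unmapped == r.total

    def test_percentages_round_half_up(self):
        assert round_half_up_pct(1026, 1177) == 87
        assert round_half_up_pct(54, 121) == 45
        assert round_half_up_pct(1, 200) == 1  # 0.5 rounds up
        assert round_half_up_pct(0, 0) == 0

    def test_empty_category_flagged(self, indexes):
        report = build_report(
            [map_term("warfarin", "drug", indexes)], indexes
        )
        assert report.categories["food"].empty
        assert report.categories["food"].mapped_pct == 0

    def test_raw_coverage_can_exceed_cascade_hits(self, indexes):
        # a herb found in the food ontology never reaches the drug-product
        # ontology in the cascade, but raw lookup may still see it there
        indexes["DRON"].add("DrOn:99", "garlic ext", ["garlic"])
        report = build_report(self._results(indexes), indexes)
        herb = report.categories["herb"]
        assert herb.raw_coverage["DRON"] >= herb.by_ontology["DRON"]


def test_suggestions_ranked_and_never_exact(indexes):
    sugg = suggest_near_matches("warfarine", "drug", indexes)
    assert sugg and sugg[0][0] == "warfarin"
    assert all(d > 0 for _, _, d in sugg)
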