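"""Standoff annotation I/O and Fleiss-kappa agreement."""
import random

import pytest
from hypothesis import given, settings, strategies as st

from fdiforge.agreement import (
    AgreementTable,
    AnnotationError,
    AnnotationSpan,
    KappaUndefinedError,
    category_table,
    fleiss_kappa,
    read_standoff,
    write_standoff,
)


class TestStandoffIO:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "s1.A1.ann"
        p.write_text("T1\tHerb 17 23\tgarlic\n", encoding="utf-8")
        (span,) = read_standoff(p)
        assert span.category == "Herb" and span.surface_term == "garlic"
        assert (span.start, span.end) == (17, 23)
        assert (span.sentence_id, span.annotator_id) == ("s1", "A1")

    def test_roundtrip(self, tmp_path):
        rng = random.Random(0)
        spans = []
        for i in range(10):
            start = rng.randrange(0, 40)
            spans.append(
                AnnotationSpan("s1", start, start + 3, "Food", "xyz", "A1")
            )
        p = tmp_path / "s1.A1.ann"
        write_standoff(spans, p)
        assert read_standoff(p) == spans

    def test_inverted_offsets_rejected(self):
        with pytest.raises(AnnotationError):
            AnnotationSpan("s1", 5, 3, "Food", "ab", "A1").validate()

    def test_surface_must_match_sentence(self):
        span = AnnotationSpan("s1", 0, 6, "Herb", "garlic", "A1")
        span.validate("garlic lowers INR")  # ok
        with pytest.raises(AnnotationError, match="surface"):
            span.validate("ginger lowers INR")


class TestFleissKappa:
    def test_perfect_agreement_is_exactly_one(self):
        # unanimity in a single category everywhere: still exactly 1.0
        assert fleiss_kappa(AgreementTable(3, [[3, 0], [3, 0], [3, 0]])) == 1.0
        assert fleiss_kappa(AgreementTable(4, [[4, 0], [0, 4]])) == 1.0

    def test_hand_derived_negative_values(self):
        # frozen from hand evaluation of the closed form
        assert fleiss_kappa(AgreementTable(3, [[3, 0], [2, 1]])) == pytest.approx(-0.2)
        assert fleiss_kappa(AgreementTable(3, [[2, 1], [1, 2]])) == pytest.approx(-1 / 3)

    def test_invalid_tables_rejected(self):
        with pytest.raises(AnnotationError):
            fleiss_kappa(AgreementTable(1, [[1, 0]]))  # <2 raters
        with pytest.raises(AnnotationError):
            fleiss_kappa(AgreementTable(3, [[2, 0]]))  # row sum mismatch
        with pytest.raises(AnnotationError):
            fleiss_kappa(AgreementTable(3, []))  # no items

    def test_kappa_at_most_one_and_permutation_invariant(self):
        rng = random.Random(42)
        for _ in range(50):
            rows = []
            for _ in range(rng.randrange(2, 12)):
                a = rng.randrange(0, 4)
                rows.append([a, 3 - a])
            if all(max(r) == 3 for r in rows):
                continue
            k = fleiss_kappa(AgreementTable(3, rows))
            assert k <= 1.0
            shuffled = rows[:]
            rng.shuffle(shuffled)
            assert fleiss_kappa(AgreementTable(3, shuffled)) == pytest.approx(k)
            swapped = [[r[1], r[0]] for r in rows]
            assert fleiss_kappa(AgreementTable(3, swapped)) == pytest.approx(k)

    def test_uniform_ratings_converge_to_zero(self):
        # i.i.d. uniform category assignments: chance-corrected agreement ~ 0
        rng = random.Random(7)
        n_raters, n_cats, n_items = 4, 3, 10_000
        rows = []
        for _ in range(n_items):
            row = [0] * n_cats
            for _ in range(n_raters):
                row[rng.randrange(n_cats)] += 1
            rows.append(row)
        assert fleiss_kappa(AgreementTable(n_raters, rows)) == pytest.approx(
            0.0, abs=0.05
        )


class TestCategoryTable:
    def test_binarization_from_spans(self):
        # two raters: both mark "garlic" as Herb, only one marks "milk" as Food
        spans = [
            AnnotationSpan("s1", 0, 6, "Herb", "garlic", "A"),
            AnnotationSpan("s1", 0, 6, "Herb", "garlic", "B"),
            AnnotationSpan("s1", 10, 14, "Food", "milk", "A"),
        ]
        herb = category_table(spans, "Herb", ["A", "B"])
        assert herb.rows == [[2, 0], [0, 2]]  # garlic item, milk item
        food = category_table(spans, "Food", ["A", "B"])
        assert food.rows == [[0, 2], [1, 1]]

    def test_overlapping_extents_merge_into_one_item(self):
        spans = [
            AnnotationSpan("s1", 0, 8, "Food", "ripe ban", "A"),
            AnnotationSpan("s1", 5, 11, "Food", "banana", "B"),
        ]
        table = category_table(spans, "Food", ["A", "B"])
        assert table.rows == [[2, 0]]

    def test_degenerate_single_category_is_unanimity(self):
        # every rater using one single category everywhere means every row is
        # unanimous, so the expected-agreement-1 guard is shadowed by the
        # exact-unanimity short circuit and the result is 1.0
        spans = [
            AnnotationSpan("s1", 0, 4, "Food", "milk", "A"),
            AnnotationSpan("s1", 0, 4, "Food", "milk", "B"),
        ]
        table = category_table(spans, "Food", ["A", "B"])
        assert fleiss_kappa(table) == 1.0
        assert issubclass(KappaUndefinedError, ZeroDivisionError)


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.integers(min_value=0, max_value=5).map(lambda a: [a, 5 - a]),
        min_size=1,
        max_size=30,
    )
)
def test_kappa_never_exceeds_one(rows):
    """kappa <= 1 with equality exactly at unanimity, over random tables."""
    table = AgreementTable(5, rows)
    unanimous = all(max(r) == 5 for r in rows)
    k = fleiss_kappa(table)
    assert k <= 1.0 + 1e-12
    if unanimous:
        assert k == 1.0
    else:
        assert k < 1.0
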