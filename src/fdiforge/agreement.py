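"""Manual term annotations and inter-annotator agreement.

Annotations of interaction sentences are stored as BRAT-style standoff spans
(category + character offsets).  Agreement between a fixed panel of raters is
quantified per category with Fleiss' kappa: free spans are reduced to a
rating table by taking the union of all annotators' span extents (overlapping
extents merged) as items, and asking for each item whether each annotator
marked it with the category in question.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

CATEGORIES = (
    "Food",
    "FoodComponent",
    "Herb",
    "Enzyme",
    "InteractionMechanism",
    "PhysiologicalEffect",
    "MealTime",
)


class AnnotationError(ValueError):
    pass


class KappaUndefinedError(ZeroDivisionError):
    """Raised when expected agreement is 1 (a single category used everywhere
    but rows not unanimous cannot occur; see fleiss_kappa)."""


@dataclass(frozen=True)
class AnnotationSpan:
    sentence_id: str
    start: int  # 0-based, half-open, Unicode code points
    end: int
    category: str
    surface_term: str
    annotator_id: str

    def validate(self, sentence_text: str | None = None) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"span {self.sentence_id}[{self.start},{self.end}): "
                "offsets must satisfy 0 <= start < end"
            )
        if self.category not in CATEGORIES:
            raise AnnotationError(f"unknown category {self.category!r}")
        if sentence_text is not None:
            if self.end > len(sentence_text):
                raise AnnotationError(
                    f"span {self.sentence_id}[{self.start},{self.end}) "
                    f"exceeds sentence length {len(sentence_text)}"
                )
            actual = sentence_text[self.start : self.end]
            if actual != self.surface_term:
                raise AnnotationError(
                    f"span {self.sentence_id}[{self.start},{self.end}): surface "
                    f"{self.surface_term!r} != sentence substring {actual!r}"
                )


@dataclass
class AgreementTable:
    """Per-item category-count rows for a fixed number of raters."""

    n_raters: int
    rows: list[list[int]]  # each row sums to n_raters

    def validate(self) -> None:
        if self.n_raters < 2:
            raise AnnotationError("need at least 2 raters")
        if not self.rows:
            raise AnnotationError("need at least 1 item")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise AnnotationError(f"row {i} has inconsistent width")
            if sum(row) != self.n_raters:
                raise AnnotationError(
                    f"row {i} sums to {sum(row)}, expected {self.n_raters}"
                )


_ANN_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_standoff(
    path: str | Path,
    sentence_id: str | None = None,
    annotator_id: str | None = None,
    sentence_text: str | None = None,
) -> list[AnnotationSpan]:
    """Read a BRAT ``.ann`` file: lines ``Tn<TAB>Category start end<TAB>surface``.

    sentence_id / annotator_id default to the first two dot-separated parts of
    the filename stem (``<sentence>.<annotator>.ann``).
    """
    path = Path(path)
    if sentence_id is None or annotator_id is None:
        parts = path.stem.split(".")
        sentence_id = sentence_id or parts[0]
        annotator_id = annotator_id or (parts[1] if len(parts) > 1 else "A1")
    spans: list[AnnotationSpan] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        m = _ANN_LINE.match(line)
        if not m:
            raise AnnotationError(f"{path}:{lineno}: unparseable standoff line")
        _tid, category, start, end, surface = m.groups()
        span = AnnotationSpan(
            sentence_id, int(start), int(end), category, surface, annotator_id
        )
        span.validate(sentence_text)
        spans.append(span)
    return spans


def write_standoff(spans: Sequence[AnnotationSpan], path: str | Path) -> None:
    lines = [
        f"T{i}\t{s.category} {s.start} {s.end}\t{s.surface_term}"
        for i, s in enumerate(spans, 1)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def _merged_extents(spans: Iterable[AnnotationSpan]) -> list[tuple[str, int, int]]:
    """Union of span extents per sentence, overlapping extents merged."""
    by_sentence: dict[str, list[tuple[int, int]]] = {}
    for s in spans:
        by_sentence.setdefault(s.sentence_id, []).append((s.start, s.end))
    items: list[tuple[str, int, int]] = []
    for sid in sorted(by_sentence):
        merged: list[list[int]] = []
        for start, end in sorted(by_sentence[sid]):
            if merged and start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        items.extend((sid, a, b) for a, b in merged)
    return items


def category_table(
    spans: Sequence[AnnotationSpan], category: str, annotators: Sequence[str]
) -> AgreementTable:
    """Binarized rating table for one category.

    Items are the merged extents over *all* annotators' spans (any category);
    each annotator rates an item as `category` if one of their spans of that
    category overlaps the item's extent, else not-`category`.
    """
    if category not in CATEGORIES:
        raise AnnotationError(f"unknown category {category!r}")
    items = _merged_extents(spans)
    if not items:
        raise AnnotationError("no annotated spans, cannot build a table")
    rows = []
    for sid, start, end in items:
        yes = 0
        for ann in annotators:
            hit = any(
                s.annotator_id == ann
                and s.sentence_id == sid
                and s.category == category
                and s.start < end
                and s.end > start
                for s in spans
            )
            yes += int(hit)
        rows.append([yes, len(annotators) - yes])
    return AgreementTable(n_raters=len(annotators), rows=rows)


def fleiss_kappa(table: AgreementTable) -> float:
    """Fleiss' chance-corrected agreement for a fixed rater panel.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar) with per-item agreement
    P_i = (sum_j n_ij^2 - n) / (n (n - 1)) and category propensities
    p_j = sum_i n_ij / (N n).  Returns exactly 1.0 when every item is
    unanimous; raises KappaUndefinedError when expected agreement equals 1
    (all ratings in one single category), since the statistic is then 0/0.
    """
    table.validate()
    n = table.n_raters
    rows = table.rows
    if all(max(row) == n for row in rows):
        return 1.0
    big_n = len(rows)
    p_bar = sum((sum(v * v for v in row) - n) / (n * (n - 1)) for row in rows) / big_n
    totals = [sum(row[j] for row in rows) for j in range(len(rows[0]))]
    p_j = [t / (big_n * n) for t in totals]
    pe_bar = sum(p * p for p in p_j)
    if pe_bar >= 1.0:
        raise KappaUndefinedError("kappa undefined (expected agreement = 1)")
    return (p_bar - pe_bar) / (1.0 - pe_bar)


def kappa_by_category(
    spans: Sequence[AnnotationSpan], annotators: Sequence[str] | None = None
) -> dict[str, float | None]:
    """Fleiss' kappa per category present in the span set.

    Categories whose table is degenerate report None.
    """
    if annotators is None:
        annotators = sorted({s.annotator_id for s in spans})
    out: dict[str, float | None] = {}
    for cat in sorted({s.category for s in spans}):
        table = category_table(spans, cat, annotators)
        try:
            out[cat] = fleiss_kappa(table)
        except KappaUndefinedError:
            out[cat] = None
    return out
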