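"""Resolve food / herb / drug terms to reference-ontology concepts.

Terms are looked up in local label/synonym indexes standing in for the
reference ontologies (a chemical-entity ontology for drugs, a food ontology
for foods and herbs, a drug-product ontology as fallback).  The lookup
contract is deliberately minimal — ``find(normalized term) -> (curie, label,
kind)`` — so a live ontology-lookup-service adapter can replace the local
indexes later without touching callers.

Per-category cascade (first hit wins):

* drug: chemical-entity index, then drug-product index
* food: food index only
* herb: food index, then drug-product index

Manual overrides are consulted last and by default only fill terms the
cascade left unmapped.
"""
from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

ONTOLOGY_IDS = ("CHEBI", "FOODON", "DRON")

CASCADE: dict[str, tuple[str, ...]] = {
    "drug": ("CHEBI", "DRON"),
    "food": ("FOODON",),
    "herb": ("FOODON", "DRON"),
}

_CURIE_RE = re.compile(r"^[A-Za-z]+:[A-Za-z0-9_]+$")


class MappingError(ValueError):
    pass


class IndexBuildError(MappingError):
    """Ambiguous index: one normalized key resolving to two CURIEs."""


def normalize_term(raw: str) -> str:
    """Canonical lookup key: casefold, collapse whitespace, strip surrounding
    punctuation.  Idempotent; interior punctuation (apostrophes, periods in
    abbreviations) is preserved."""
    s = unicodedata.normalize("NFC", raw).casefold()
    s = re.sub(r"\s+", " ", s)
    prev = None
    while s != prev:  # alternate whitespace/punctuation stripping to a fixed point
        prev = s
        s = s.strip().strip(",;:!?()[]{}\"")
    return s


def round_half_up_pct(numerator: int, denominator: int) -> int:
    """Integer percentage with round-half-up (so 69.5 -> 70)."""
    if denominator == 0:
        return 0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class TermIndex:
    """Label/synonym lookup table for one reference ontology."""

    ontology_id: str
    labels: dict[str, tuple[str, str]] = field(default_factory=dict)
    synonyms: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, curie: str, canonical_label: str, synonyms: Sequence[str] = ()) -> None:
        if not _CURIE_RE.match(curie):
            raise IndexBuildError(f"{self.ontology_id}: malformed CURIE {curie!r}")
        key = normalize_term(canonical_label)
        prev = self.labels.get(key)
        if prev is not None and prev[0] != curie:
            raise IndexBuildError(
                f"{self.ontology_id}: label key {key!r} maps to both "
                f"{prev[0]} and {curie}; dedupe the index"
            )
        self.labels[key] = (curie, canonical_label)
        for syn in synonyms:
            skey = normalize_term(syn)
            if not skey:
                continue
            sprev = self.synonyms.get(skey)
            if sprev is not None and sprev[0] != curie:
                raise IndexBuildError(
                    f"{self.ontology_id}: synonym key {skey!r} maps to both "
                    f"{sprev[0]} and {curie}; dedupe the index"
                )
            self.synonyms[skey] = (curie, canonical_label)

    def find(self, normalized: str) -> tuple[str, str, str] | None:
        """(curie, canonical label, 'label'|'synonym') or None.

        Exact canonical label outranks exact synonym; no fuzzy matching.
        """
        hit = self.labels.get(normalized)
        if hit:
            return hit[0], hit[1], "label"
        hit = self.synonyms.get(normalized)
        if hit:
            return hit[0], hit[1], "synonym"
        return None

    def keys(self) -> list[str]:
        return sorted(set(self.labels) | set(self.synonyms))

    @classmethod
    def from_tsv(cls, ontology_id: str, path: str | Path) -> "TermIndex":
        """Load ``curie<TAB>canonical_label<TAB>syn1|syn2|...`` rows."""
        idx = cls(ontology_id)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise MappingError(f"{path}:{lineno}: need curie<TAB>label")
                curie, label = parts[0], parts[1]
                syns = parts[2].split("|") if len(parts) > 2 and parts[2] else []
                idx.add(curie, label, syns)
        return idx


@dataclass(frozen=True)
class MappingResult:
    term: str
    category: str  # drug | food | herb
    curie: str | None = None
    hit_ontology: str | None = None
    match_kind: str = "unmapped"  # label | synonym | manual | unmapped
    label: str | None = None

    @property
    def mapped(self) -> bool:
        return self.match_kind != "unmapped"


Overrides = Mapping[tuple[str, str], tuple[str, str]]


def read_overrides(path: str | Path) -> dict[tuple[str, str], tuple[str, str]]:
    """Manual-mapping TSV: ``term<TAB>category<TAB>curie<TAB>label``."""
    out: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MappingError(
                    f"{path}:{lineno}: need term<TAB>category<TAB>curie<TAB>label"
                )
            term, category, curie, label = parts[:4]
            if category not in CASCADE:
                raise MappingError(f"{path}:{lineno}: unknown category {category!r}")
            out[(normalize_term(term), category)] = (curie, label)
    return out


def map_term(
    term: str,
    category: str,
    indexes: Mapping[str, TermIndex],
    overrides: Overrides | None = None,
    force_overrides: bool = False,
) -> MappingResult:
    """Resolve one term through the category's cascade, overrides last.

    A pure function of (normalized term, category, indexes, overrides).
    """
    if category not in CASCADE:
        raise MappingError(f"unknown category {category!r}")
    key = normalize_term(term)
    override = (overrides or {}).get((key, category))
    if override and force_overrides:
        return MappingResult(term, category, override[0], None, "manual", override[1])
    for ontology_id in CASCADE[category]:
        idx = indexes.get(ontology_id)
        if idx is None:
            continue
        hit = idx.find(key)
        if hit:
            curie, label, kind = hit
            return MappingResult(term, category, curie, ontology_id, kind, label)
    if override:
        return MappingResult(term, category, override[0], None, "manual", override[1])
    return MappingResult(term, category)


def map_terms(
    terms: Iterable[tuple[str, str]],
    indexes: Mapping[str, TermIndex],
    overrides: Overrides | None = None,
    force_overrides: bool = False,
) -> list[MappingResult]:
    return [
        map_term(t, c, indexes, overrides, force_overrides) for t, c in terms
    ]


@dataclass
class CategoryReport:
    total: int
    by_ontology: dict[str, int]  # cascade-semantics hits
    manual: int
    unmapped: int
    mapped_pct: int  # round-half-up integer percent
    empty: bool = False
    raw_coverage: dict[str, int] = field(default_factory=dict)  # lookup ignoring cascade


@dataclass
class MappingReport:
    categories: dict[str, CategoryReport]

    def as_dict(self) -> dict:
        return {
            cat: {
                "total": r.total,
                "by_ontology": dict(r.by_ontology),
                "manual": r.manual,
                "unmapped": r.unmapped,
                "mapped_pct": r.mapped_pct,
                "empty": r.empty,
                "raw_coverage": dict(r.raw_coverage),
            }
            for cat, r in self.categories.items()
        }


def build_report(
    results: Sequence[MappingResult],
    indexes: Mapping[str, TermIndex] | None = None,
) -> MappingReport:
    """Per-category mapping tallies and rounded coverage percentages.

    ``by_ontology`` counts first-hit (cascade) resolutions, so the
    per-ontology counts plus manual plus unmapped partition the total.
    ``raw_coverage`` additionally reports, per ontology in the category's
    cascade, how many distinct terms the ontology could resolve on its own —
    the two views differ exactly when cascades overlap.
    """
    categories: dict[str, CategoryReport] = {}
    for cat in CASCADE:
        cat_results = [r for r in results if r.category == cat]
        total = len(cat_results)
        by_ont = {o: 0 for o in CASCADE[cat]}
        manual = 0
        unmapped = 0
        for r in cat_results:
            if r.match_kind == "unmapped":
                unmapped += 1
            elif r.match_kind == "manual":
                manual += 1
            else:
                by_ont[r.hit_ontology] = by_ont.get(r.hit_ontology, 0) + 1
        mapped = total - unmapped
        raw: dict[str, int] = {}
        if indexes:
            for ont in CASCADE[cat]:
                idx = indexes.get(ont)
                if idx is None:
                    continue
                raw[ont] = sum(
                    1
                    for r in cat_results
                    if idx.find(normalize_term(r.term)) is not None
                )
        categories[cat] = CategoryReport(
            total=total,
            by_ontology=by_ont,
            manual=manual,
            unmapped=unmapped,
            mapped_pct=round_half_up_pct(mapped, total),
            empty=total == 0,
            raw_coverage=raw,
        )
    return MappingReport(categories)


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance; used only to rank curator suggestions."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def suggest_near_matches(
    term: str,
    category: str,
    indexes: Mapping[str, TermIndex],
    max_distance: int = 2,
    limit: int = 5,
) -> list[tuple[str, str, int]]:
    """Edit-distance suggestions (key, ontology, distance) for curators.

    Suggestions are never auto-applied; they feed the manual-override table.
    """
    key = normalize_term(term)
    out: list[tuple[str, str, int]] = []
    for ontology_id in CASCADE.get(category, ()):
        idx = indexes.get(ontology_id)
        if idx is None:
            continue
        for cand in idx.keys():
            d = levenshtein(key, cand)
            if 0 < d <= max_distance:
                out.append((cand, ontology_id, d))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out[:limit]
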