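"""End-to-end assembly: records + annotations + indexes -> knowledge base.

The stages mirror the enrichment workflow: ingest the two sources, resolve
every food/herb/drug term through the per-category cascade, build the ATC
scaffold and place the mapped concepts under it, then compile deduplicated
interaction concepts with provenance.  Only entities that participate in at
least one mapped interaction enter the knowledge base.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .atc import AtcEntry, Scaffold, build_atc_scaffold, place_drug, place_food_or_herb
from .config import DEFAULT_CONFIG, KbConfig
from .ingest import DrugRecord, HedrineRecord, interaction_corpus
from .kb import KnowledgeBase, compile_pairs, link_sources
from .mapping import (
    MappingReport,
    MappingResult,
    Overrides,
    TermIndex,
    build_report,
    map_term,
    normalize_term,
)

#: (record_id, surface term, category) — the stored manual annotations
Annotation = tuple[str, str, str]


@dataclass
class BuildResult:
    kb: KnowledgeBase
    report: MappingReport
    scaffold: Scaffold
    skipped: list[str] = field(default_factory=list)  # unmapped terms, logged


def build_kb(
    drugbank_records: Sequence[DrugRecord],
    hedrine_records: Sequence[HedrineRecord],
    annotations: Sequence[Annotation],
    indexes: Mapping[str, TermIndex],
    atc_entries: Sequence[AtcEntry],
    drug_codes: Mapping[str, set[str]] | None = None,
    overrides: Overrides | None = None,
    config: KbConfig = DEFAULT_CONFIG,
) -> BuildResult:
    drug_codes = drug_codes or {}
    corpus = interaction_corpus(drugbank_records)
    corpus_ids = {r.source_id for r in corpus}

    ann_by_record: dict[str, list[tuple[str, str]]] = {}
    for rec_id, term, category in annotations:
        if category not in ("food", "herb"):
            raise ValueError(f"annotation category must be food|herb, got {category!r}")
        if rec_id in corpus_ids:
            ann_by_record.setdefault(rec_id, []).append((term, category))

    # distinct terms per category (normalized identity)
    term_specs: dict[tuple[str, str], str] = {}  # (norm, category) -> surface

    def note(term: str, category: str) -> None:
        term_specs.setdefault((normalize_term(term), category), term)

    for rec in corpus:
        note(rec.drug_name, "drug")
    for rec_id, pairs in ann_by_record.items():
        for term, category in pairs:
            note(term, category)
    for h in hedrine_records:
        note(h.drug_name, "drug")
        note(h.plant_name, "herb")

    results: dict[tuple[str, str], MappingResult] = {}
    for (norm, category), surface in sorted(term_specs.items()):
        results[(norm, category)] = map_term(
            surface, category, indexes, overrides
        )
    report = build_report(list(results.values()), indexes)

    def lookup(term: str, category: str) -> MappingResult:
        return results[(normalize_term(term), category)]

    skipped: list[str] = []
    raw_pairs: list[tuple[str, str, str]] = []  # (food curie, drug curie, source ref)
    pair_mappings: dict[str, MappingResult] = {}  # curie -> a mapping that hit it
    drug_mappings: dict[str, tuple[MappingResult, str]] = {}  # curie -> (mapping, term)

    for rec in corpus:
        dm = lookup(rec.drug_name, "drug")
        if not dm.mapped:
            skipped.append(f"drug term {rec.drug_name!r} unmapped ({rec.source_id})")
            continue
        for term, category in ann_by_record.get(rec.source_id, []):
            tm = lookup(term, category)
            if not tm.mapped:
                skipped.append(f"{category} term {term!r} unmapped ({rec.source_id})")
                continue
            raw_pairs.append((tm.curie, dm.curie, rec.source_id))
            pair_mappings[tm.curie] = tm
            drug_mappings[dm.curie] = (dm, rec.drug_name)

    for h in hedrine_records:
        dm = lookup(h.drug_name, "drug")
        tm = lookup(h.plant_name, "herb")
        ref = f"Hedrine:{h.entry_id}"
        if not dm.mapped:
            skipped.append(f"drug term {h.drug_name!r} unmapped ({ref})")
            continue
        if not tm.mapped:
            skipped.append(f"herb term {h.plant_name!r} unmapped ({ref})")
            continue
        raw_pairs.append((tm.curie, dm.curie, ref))
        pair_mappings[tm.curie] = tm
        drug_mappings[dm.curie] = (dm, h.drug_name)

    scaffold = build_atc_scaffold(atc_entries, config)
    kb = KnowledgeBase(config=config)
    for node in scaffold.node_list():
        kb.add_concept(node)

    norm_codes = {normalize_term(k): v for k, v in drug_codes.items()}
    for curie in sorted(drug_mappings):
        dm, term = drug_mappings[curie]
        codes = norm_codes.get(normalize_term(term), set())
        kb.add_concept(place_drug(dm, codes, scaffold))
    for curie in sorted(pair_mappings):
        node = place_food_or_herb(pair_mappings[curie], scaffold)
        if node is not None:
            kb.add_concept(node)

    labels = {c: n.label for c, n in kb.concepts.items()}
    fdis, sources = compile_pairs(raw_pairs, labels, config)
    kb.fdis = fdis
    kb.sources = {s.curie: s for s in sources.values()}
    kb.is_about = link_sources(fdis, sources)
    kb.validate()
    return BuildResult(kb, report, scaffold, skipped)
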