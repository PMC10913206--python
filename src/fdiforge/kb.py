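"""Precompiled interaction concepts, provenance, and the knowledge base.

Each (food, drug) pair observed in any source becomes exactly one
*precompiled interaction concept*: an ontology class logically defined as

    'food drug interaction'
      and (has_participant some <food>)
      and (has_input some <drug>)

The food participates in the interaction process; only the drug's state is
altered, hence the more specific has_input relation on the drug side.  Pairs
reported by several sources collapse to one concept that accumulates all of
their provenance.  Each distinct source page/entry becomes one provenance
class under "information source for interaction", linked to the interactions
it reports with is_about.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .atc import ConceptNode, check_acyclic
from .config import DEFAULT_CONFIG, HAS_INPUT, HAS_PARTICIPANT, KbConfig

EN_DASH = "–"

DRUGBANK_URL = "https://go.drugbank.com/drugs/{drug_id}"


class CompileError(ValueError):
    pass


@dataclass(frozen=True)
class EquivalenceAxiom:
    """Genus plus the two existential restrictions, in fixed order."""

    genus: str
    participant_restriction: tuple[str, str]  # (relation, food curie)
    input_restriction: tuple[str, str]  # (relation, drug curie)


@dataclass
class FdiConcept:
    curie: str
    label: str
    food_curie: str
    drug_curie: str
    source_curies: set[str] = field(default_factory=set)

    def axiom(self, config: KbConfig = DEFAULT_CONFIG) -> EquivalenceAxiom:
        return EquivalenceAxiom(
            config.fdi_genus,
            (HAS_PARTICIPANT, self.food_curie),
            (HAS_INPUT, self.drug_curie),
        )


@dataclass
class SourceConcept:
    curie: str
    label: str  # e.g. "DrugBank:DB00682" or "Hedrine:H123"
    url: str | None = None


def make_label(food_label: str, drug_label: str) -> str:
    """Interaction-class label: "FDI <food>–<drug>" (en dash, no spaces)."""
    if not food_label or not drug_label:
        raise CompileError("food and drug labels must be non-empty")
    return f"FDI {food_label}{EN_DASH}{drug_label}"


def source_url(source_ref: str) -> str | None:
    """Web page for a provenance label, when one exists."""
    if source_ref.startswith("DrugBank:"):
        return DRUGBANK_URL.format(drug_id=source_ref.split(":", 1)[1])
    return None


@dataclass
class KnowledgeBase:
    """Validated container for the compiled ontology content."""

    concepts: dict[str, ConceptNode] = field(default_factory=dict)
    fdis: list[FdiConcept] = field(default_factory=list)
    sources: dict[str, SourceConcept] = field(default_factory=dict)
    is_about: set[tuple[str, str]] = field(default_factory=set)  # (source, fdi)
    config: KbConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    # -- assembly -----------------------------------------------------------
    def add_concept(self, node: ConceptNode) -> None:
        node.validate()
        existing = self.concepts.get(node.curie)
        if existing is None:
            self.concepts[node.curie] = node
        else:
            existing.parents |= node.parents
            existing.xrefs |= node.xrefs

    def validate(self) -> None:
        check_acyclic(self.concepts.values())
        fdi_curies = set()
        pairs = set()
        for fdi in self.fdis:
            if fdi.food_curie not in self.concepts:
                raise CompileError(f"{fdi.curie}: unknown food {fdi.food_curie}")
            if fdi.drug_curie not in self.concepts:
                raise CompileError(f"{fdi.curie}: unknown drug {fdi.drug_curie}")
            if not fdi.source_curies:
                raise CompileError(f"{fdi.curie}: interaction without provenance")
            if (fdi.food_curie, fdi.drug_curie) in pairs:
                raise CompileError(
                    f"duplicate pair ({fdi.food_curie}, {fdi.drug_curie})"
                )
            pairs.add((fdi.food_curie, fdi.drug_curie))
            fdi_curies.add(fdi.curie)
        for src_curie, fdi_curie in self.is_about:
            if src_curie not in self.sources:
                raise CompileError(f"is_about from unknown source {src_curie}")
            if fdi_curie not in fdi_curies:
                raise CompileError(f"is_about to unknown interaction {fdi_curie}")
        linked = {s for s, _ in self.is_about}
        for curie in self.sources:
            if curie not in linked:
                raise CompileError(f"source {curie} describes no interaction")

    # -- convenience views --------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[ConceptNode]:
        return [n for n in self.concepts.values() if n.node_kind == kind]

    def fdi_by_pair(self) -> dict[tuple[str, str], FdiConcept]:
        return {(f.food_curie, f.drug_curie): f for f in self.fdis}

    # -- JSON round-trip (CLI hand-off between stages) ----------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "concepts": [
                {
                    "curie": n.curie,
                    "label": n.label,
                    "parents": sorted(n.parents),
                    "xrefs": sorted(n.xrefs),
                    "node_kind": n.node_kind,
                }
                for n in sorted(self.concepts.values(), key=lambda n: n.curie)
            ],
            "fdis": [
                {
                    "curie": f.curie,
                    "label": f.label,
                    "food_curie": f.food_curie,
                    "drug_curie": f.drug_curie,
                    "source_curies": sorted(f.source_curies),
                }
                for f in self.fdis
            ],
            "sources": [
                {"curie": s.curie, "label": s.label, "url": s.url}
                for s in sorted(self.sources.values(), key=lambda s: s.curie)
            ],
            "is_about": sorted(list(p) for p in self.is_about),
        }
        Path(path).write_text(
            json.dumps(doc, indent=2, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path, config: KbConfig = DEFAULT_CONFIG) -> "KnowledgeBase":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        kb = cls(config=config)
        for c in doc["concepts"]:
            kb.concepts[c["curie"]] = ConceptNode(
                c["curie"], c["label"], set(c["parents"]), set(c["xrefs"]), c["node_kind"]
            )
        kb.fdis = [
            FdiConcept(
                f["curie"], f["label"], f["food_curie"], f["drug_curie"],
                set(f["source_curies"]),
            )
            for f in doc["fdis"]
        ]
        kb.sources = {
            s["curie"]: SourceConcept(s["curie"], s["label"], s.get("url"))
            for s in doc["sources"]
        }
        kb.is_about = {tuple(p) for p in doc["is_about"]}
        return kb


def build_source_concepts(
    source_refs: Iterable[str], config: KbConfig = DEFAULT_CONFIG
) -> dict[str, SourceConcept]:
    """One provenance concept per distinct source page/entry.

    Labels are the source references themselves ("DrugBank:DB00682",
    "Hedrine:H123"); drug-database pages additionally carry their URL.
    Minting is deterministic: labels sorted, IDs sequential from the
    configured base.
    """
    out: dict[str, SourceConcept] = {}
    for i, ref in enumerate(sorted(set(source_refs))):
        curie = config.mint(config.source_id_base + i)
        out[ref] = SourceConcept(curie, ref, source_url(ref))
    return out


def compile_pairs(
    pairs: Sequence[tuple[str, str, str]],
    labels: Mapping[str, str],
    config: KbConfig = DEFAULT_CONFIG,
) -> tuple[list[FdiConcept], dict[str, SourceConcept]]:
    """Deduplicate (food_curie, drug_curie, source_ref) triples into
    interaction concepts plus provenance concepts.

    All source references of a collapsed pair accumulate on the surviving
    concept.  Minting is deterministic: concepts are ordered by
    (drug label, food label) and numbered from the configured base.
    """
    for food, drug, _ref in pairs:
        if food not in labels:
            raise CompileError(f"pair references unknown food concept {food}")
        if drug not in labels:
            raise CompileError(f"pair references unknown drug concept {drug}")
    by_pair: dict[tuple[str, str], set[str]] = {}
    for food, drug, ref in pairs:
        by_pair.setdefault((food, drug), set()).add(ref)
    sources = build_source_concepts(
        (ref for refs in by_pair.values() for ref in refs), config
    )
    ordered = sorted(
        by_pair, key=lambda p: (labels[p[1]], labels[p[0]])  # (drug, food) labels
    )
    fdis = []
    for i, (food, drug) in enumerate(ordered):
        curie = config.mint(config.fdi_id_base + i)
        fdis.append(
            FdiConcept(
                curie,
                make_label(labels[food], labels[drug]),
                food,
                drug,
                {sources[r].curie for r in by_pair[(food, drug)]},
            )
        )
    return fdis, sources


def link_sources(
    fdis: Iterable[FdiConcept], sources: Mapping[str, SourceConcept]
) -> set[tuple[str, str]]:
    """is_about edges, direction source -> interaction; set semantics make
    duplicate link requests idempotent."""
    known = {s.curie for s in sources.values()}
    edges: set[tuple[str, str]] = set()
    for fdi in fdis:
        for src in fdi.source_curies:
            if src not in known:
                raise CompileError(f"{fdi.curie}: dangling source {src}")
            edges.add((src, fdi.curie))
    return edges
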