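"""Serialize the knowledge base as a ROBOT-style template and as OWL.

Every precompiled interaction class is emitted with an equivalent-class
axiom — the intersection of the interaction genus and two existential
restrictions (has_participant on the food, has_input on the drug).  All other
classes get plain subclass axioms; database cross-references are oboInOwl
hasDbXref annotations.  Provenance links use is_about between class IRIs as
an annotation-level assertion (the whole model is class-level by design;
there are no individuals to relate).

The template spreadsheet mirrors the OWL content: a human header row, a
template-string row (ID, LABEL, SC %, TYPE, EC %), then one row per entity.
Interaction rows leave the parent column empty because their logical
definition already asserts the genus.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, SKOS

from .atc import ConceptNode
from .config import DEFAULT_CONFIG, HAS_INPUT, HAS_PARTICIPANT, IS_ABOUT, KbConfig
from .kb import FdiConcept, KnowledgeBase, SourceConcept

OBO_IN_OWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")
HAS_DB_XREF = OBO_IN_OWL.hasDbXref

#: labels as displayed in the model diagrams; spaced forms go out as altLabels
RELATION_LABELS = {
    HAS_PARTICIPANT: ("has_participant", "has participant"),
    HAS_INPUT: ("has_input", "has input"),
    IS_ABOUT: ("is_about", "is about"),
}


class OwlError(ValueError):
    pass


def curie_to_iri(curie: str, config: KbConfig = DEFAULT_CONFIG) -> URIRef:
    prefix, _, local = curie.partition(":")
    ns = config.prefixes.get(prefix)
    if ns is None:
        raise OwlError(f"no declared prefix for CURIE {curie!r}")
    return URIRef(ns + local)


def iri_to_curie(iri: str, config: KbConfig = DEFAULT_CONFIG) -> str:
    best = None
    for prefix, ns in config.prefixes.items():
        if iri.startswith(ns) and (best is None or len(ns) > len(best[1])):
            best = (prefix, ns)
    if best is None:
        raise OwlError(f"IRI {iri} matches no declared prefix")
    return f"{best[0]}:{iri[len(best[1]):]}"


# --------------------------------------------------------------------------
# ROBOT-style template
# --------------------------------------------------------------------------

TEMPLATE_HUMAN_HEADER = ("ID", "Label", "Parent", "Type", "Equivalence")
TEMPLATE_STRINGS = ("ID", "LABEL", "SC %", "TYPE", "EC %")


def _quote(label: str) -> str:
    """Manchester-syntax term reference: quote multiword/underscore labels."""
    return f"'{label}'" if (" " in label or "-" in label or "–" in label) else label


def manchester_equivalence(fdi: FdiConcept, kb: KnowledgeBase) -> str:
    cfg = kb.config
    food = kb.concepts[fdi.food_curie].label
    drug = kb.concepts[fdi.drug_curie].label
    return (
        f"{_quote(cfg.fdi_genus_label)}"
        f" and {_quote(RELATION_LABELS[HAS_PARTICIPANT][0])} some {_quote(food)}"
        f" and {_quote(RELATION_LABELS[HAS_INPUT][0])} some {_quote(drug)}"
    )


def write_robot_template(kb: KnowledgeBase, path: str | Path) -> None:
    """TSV with the two header rows, then one row per concept/relation."""
    kb.validate()
    label_of = {c: n.label for c, n in kb.concepts.items()}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TEMPLATE_HUMAN_HEADER)
        w.writerow(TEMPLATE_STRINGS)
        if kb.concepts or kb.fdis or kb.sources:
            for curie, (label, _alt) in sorted(RELATION_LABELS.items()):
                w.writerow([curie, label, "", "owl:ObjectProperty", ""])
        for node in sorted(kb.concepts.values(), key=lambda n: n.curie):
            parents = " and ".join(
                _quote(label_of[p]) for p in sorted(node.parents)
            )
            w.writerow([node.curie, node.label, parents, "owl:Class", ""])
        for src in sorted(kb.sources.values(), key=lambda s: s.curie):
            w.writerow(
                [src.curie, src.label, _quote(kb.config.source_root_label),
                 "owl:Class", ""]
            )
        for fdi in kb.fdis:
            # parent left empty: the logical definition asserts the genus
            w.writerow(
                [fdi.curie, fdi.label, "", "owl:Class",
                 manchester_equivalence(fdi, kb)]
            )


# --------------------------------------------------------------------------
# OWL graph
# --------------------------------------------------------------------------


def _bind(graph: Graph, config: KbConfig) -> None:
    for prefix, ns in config.prefixes.items():
        graph.bind(prefix, Namespace(ns))
    graph.bind("owl", OWL)
    graph.bind("skos", SKOS)


def kb_to_graph(kb: KnowledgeBase) -> Graph:
    """Build the RDF graph; deterministic skolem-style blank-node ids keep
    serializations diffable across runs."""
    kb.validate()
    cfg = kb.config
    g = Graph()
    _bind(g, cfg)

    for curie, (label, alt) in RELATION_LABELS.items():
        iri = curie_to_iri(curie, cfg)
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.label, Literal(label)))
        g.add((iri, SKOS.altLabel, Literal(alt)))

    def declare(iri: URIRef, label: str) -> None:
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(label)))

    # genus and provenance root are classes even if not ConceptNodes
    genus_iri = curie_to_iri(cfg.fdi_genus, cfg)
    declare(genus_iri, cfg.fdi_genus_label)
    source_root_iri = curie_to_iri(cfg.source_root, cfg)
    declare(source_root_iri, cfg.source_root_label)

    for node in sorted(kb.concepts.values(), key=lambda n: n.curie):
        iri = curie_to_iri(node.curie, cfg)
        declare(iri, node.label)
        for parent in sorted(node.parents):
            g.add((iri, RDFS.subClassOf, curie_to_iri(parent, cfg)))
        for xref in sorted(node.xrefs):
            g.add((iri, HAS_DB_XREF, Literal(xref)))

    part_iri = curie_to_iri(HAS_PARTICIPANT, cfg)
    input_iri = curie_to_iri(HAS_INPUT, cfg)
    for fdi in kb.fdis:
        iri = curie_to_iri(fdi.curie, cfg)
        declare(iri, fdi.label)
        local = fdi.curie.split(":", 1)[1]
        r_food = BNode(f"rfood_{local}")
        g.add((r_food, RDF.type, OWL.Restriction))
        g.add((r_food, OWL.onProperty, part_iri))
        g.add((r_food, OWL.someValuesFrom, curie_to_iri(fdi.food_curie, cfg)))
        r_drug = BNode(f"rdrug_{local}")
        g.add((r_drug, RDF.type, OWL.Restriction))
        g.add((r_drug, OWL.onProperty, input_iri))
        g.add((r_drug, OWL.someValuesFrom, curie_to_iri(fdi.drug_curie, cfg)))
        inter = BNode(f"eq_{local}")
        g.add((inter, RDF.type, OWL.Class))
        Collection(
            g,
            BNode(f"list_{local}"),
            [genus_iri, r_food, r_drug],
        )
        g.add((inter, OWL.intersectionOf, BNode(f"list_{local}")))
        g.add((iri, OWL.equivalentClass, inter))

    for src in sorted(kb.sources.values(), key=lambda s: s.curie):
        iri = curie_to_iri(src.curie, cfg)
        declare(iri, src.label)
        g.add((iri, RDFS.subClassOf, source_root_iri))
        if src.url:
            g.add((iri, HAS_DB_XREF, Literal(src.url)))

    about_iri = curie_to_iri(IS_ABOUT, cfg)
    for src_curie, fdi_curie in sorted(kb.is_about):
        g.add(
            (curie_to_iri(src_curie, cfg), about_iri, curie_to_iri(fdi_curie, cfg))
        )
    return g


def emit_owl(
    kb: KnowledgeBase, path: str | Path, dialect: str = "turtle"
) -> Graph:
    """Serialize; dialect 'turtle' (.ttl) or 'rdfxml' (.owl)."""
    fmt = {"turtle": "turtle", "rdfxml": "xml"}.get(dialect)
    if fmt is None:
        raise OwlError(f"unknown dialect {dialect!r} (use turtle|rdfxml)")
    g = kb_to_graph(kb)
    g.serialize(destination=str(path), format=fmt)
    return g


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return {"ttl": "turtle", "owl": "xml", "rdf": "xml", "xml": "xml"}.get(
        suffix.lstrip("."), "turtle"
    )


def parse_owl(
    path: str | Path, config: KbConfig = DEFAULT_CONFIG
) -> tuple[KnowledgeBase, list[str]]:
    """Reconstruct the knowledge base from an emitted file.

    Inverse of emit_owl up to blank-node renaming.  Classes with a
    non-conforming equivalence pattern (e.g. a missing has_input conjunct)
    are listed in the returned problem report, never silently dropped.
    """
    g = Graph()
    g.parse(str(path), format=_guess_format(path))
    return graph_to_kb(g, config)


def graph_to_kb(
    g: Graph, config: KbConfig = DEFAULT_CONFIG
) -> tuple[KnowledgeBase, list[str]]:
    cfg = config
    kb = KnowledgeBase(config=cfg)
    problems: list[str] = []

    part_iri = curie_to_iri(HAS_PARTICIPANT, cfg)
    input_iri = curie_to_iri(HAS_INPUT, cfg)
    about_iri = curie_to_iri(IS_ABOUT, cfg)
    genus_iri = curie_to_iri(cfg.fdi_genus, cfg)
    source_root_iri = curie_to_iri(cfg.source_root, cfg)

    def label_of(iri) -> str:
        lab = g.value(iri, RDFS.label)
        return str(lab) if lab is not None else ""

    classes = sorted(
        s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)
    )
    relation_iris = {curie_to_iri(c, cfg) for c in RELATION_LABELS}
    skip = {genus_iri, source_root_iri} | relation_iris

    # sources: direct subclasses of the provenance root
    source_iris = {
        s for s in g.subjects(RDFS.subClassOf, source_root_iri)
        if isinstance(s, URIRef)
    }

    fdi_pairs: dict[URIRef, tuple[str, str]] = {}
    for cls in classes:
        eq = g.value(cls, OWL.equivalentClass)
        if eq is None:
            continue
        lst = g.value(eq, OWL.intersectionOf)
        if lst is None:
            problems.append(f"{cls}: equivalentClass without intersectionOf")
            continue
        members = list(Collection(g, lst))
        food = drug = None
        saw_genus = False
        for m in members:
            if m == genus_iri:
                saw_genus = True
            elif (m, RDF.type, OWL.Restriction) in g:
                prop = g.value(m, OWL.onProperty)
                filler = g.value(m, OWL.someValuesFrom)
                if prop == part_iri:
                    food = filler
                elif prop == input_iri:
                    drug = filler
        if not saw_genus or food is None or drug is None:
            missing = []
            if not saw_genus:
                missing.append("genus")
            if food is None:
                missing.append("has_participant restriction")
            if drug is None:
                missing.append("has_input restriction")
            problems.append(f"{cls}: malformed logical definition, missing "
                            + ", ".join(missing))
            continue
        fdi_pairs[cls] = (iri_to_curie(str(food), cfg), iri_to_curie(str(drug), cfg))

    about_edges = [
        (s, o) for s, o in g.subject_objects(about_iri)
        if isinstance(s, URIRef) and isinstance(o, URIRef)
    ]
    sources_of: dict[URIRef, set[str]] = {}

    for src in sorted(source_iris):
        curie = iri_to_curie(str(src), cfg)
        url = None
        for x in g.objects(src, HAS_DB_XREF):
            url = str(x)
        kb.sources[curie] = SourceConcept(curie, label_of(src), url)
    for s, o in about_edges:
        kb.is_about.add((iri_to_curie(str(s), cfg), iri_to_curie(str(o), cfg)))
        sources_of.setdefault(o, set()).add(iri_to_curie(str(s), cfg))

    food_root = curie_to_iri(cfg.food_product, cfg)
    processed_root = curie_to_iri(cfg.processed_material, cfg)
    chem_root = curie_to_iri(cfg.chemical_entity, cfg)
    material_root = curie_to_iri(cfg.material_entity, cfg)

    def infer_kind(cls: URIRef, parents: set[str], xrefs: set[str]) -> str:
        if cls in {food_root, processed_root, chem_root, material_root}:
            return "scaffold"
        if any("whocc.no/atc_ddd_index" in x for x in xrefs):
            return "atc_class"
        curie = iri_to_curie(str(cls), cfg)
        if curie.startswith("FIDEO:") and cfg.chemical_entity in parents:
            return "atc_class"  # the not-elsewhere-classified class
        if cfg.food_product in parents:
            return "food"
        if cfg.processed_material in parents:
            return "herb"
        return "drug"

    for cls in classes:
        if cls in skip or cls in source_iris or cls in fdi_pairs:
            continue
        curie = iri_to_curie(str(cls), cfg)
        parents = {
            iri_to_curie(str(p), cfg)
            for p in g.objects(cls, RDFS.subClassOf)
            if isinstance(p, URIRef)
        }
        xrefs = {str(x) for x in g.objects(cls, HAS_DB_XREF)}
        kb.concepts[curie] = ConceptNode(
            curie, label_of(cls), parents, xrefs, infer_kind(cls, parents, xrefs)
        )

    for cls in sorted(fdi_pairs):
        curie = iri_to_curie(str(cls), cfg)
        food, drug = fdi_pairs[cls]
        kb.fdis.append(
            FdiConcept(curie, label_of(cls), food, drug, sources_of.get(cls, set()))
        )
    return kb, problems


def graph_counts(g: Graph, config: KbConfig = DEFAULT_CONFIG) -> dict[str, int]:
    """Entity tallies of an emitted graph (for consistency checks)."""
    about_iri = curie_to_iri(IS_ABOUT, config)
    return {
        "classes": sum(
            1 for s in set(g.subjects(RDF.type, OWL.Class)) if isinstance(s, URIRef)
        ),
        "object_properties": sum(
            1 for _ in set(g.subjects(RDF.type, OWL.ObjectProperty))
        ),
        "equivalence_axioms": sum(1 for _ in g.subject_objects(OWL.equivalentClass)),
        "is_about_assertions": sum(1 for _ in g.subject_objects(about_iri)),
    }
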