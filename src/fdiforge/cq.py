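"""Competency-question engine: SPARQL over the emitted OWL graph.

The questions an interaction knowledge base is designed to answer:

* CQ1 — which foods potentially interact with a given drug?
* CQ2 — which drugs potentially interact with a given food?
* CQ3 — which drugs *of a given therapeutic class* interact with a food?
* CQ5 — which knowledge sources report a given (food, drug) interaction?

Because every interaction is a precompiled class whose logical definition
carries the food and drug as existential restrictions, the queries
destructure owl:equivalentClass -> owl:intersectionOf -> owl:Restriction and
close over the asserted hierarchy with rdfs:subClassOf* property paths; no
description-logic reasoner is needed.  Mechanism, clinical-importance,
food-category and alternative-drug questions (CQ4, CQ6, CQ7, CQ8) are not
representable in this knowledge base and report so explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Graph, URIRef

from .config import DEFAULT_CONFIG, KbConfig
from .owl import curie_to_iri, iri_to_curie

_PREFIX_BLOCK = """
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
"""

# foods whose interaction class has a has_input filler at-or-below the drug
_CQ1 = _PREFIX_BLOCK + """
SELECT DISTINCT ?food ?label WHERE {
  ?fdi owl:equivalentClass ?eq .
  ?eq owl:intersectionOf ?list .
  ?list rdf:rest*/rdf:first ?rfood .
  ?rfood a owl:Restriction ; owl:onProperty ?hasParticipant ;
         owl:someValuesFrom ?food .
  ?list rdf:rest*/rdf:first ?rdrug .
  ?rdrug a owl:Restriction ; owl:onProperty ?hasInput ;
         owl:someValuesFrom ?din .
  ?din rdfs:subClassOf* ?drug .
  OPTIONAL { ?food rdfs:label ?label }
}
"""

_CQ2 = _PREFIX_BLOCK + """
SELECT DISTINCT ?drug ?label WHERE {
  ?fdi owl:equivalentClass ?eq .
  ?eq owl:intersectionOf ?list .
  ?list rdf:rest*/rdf:first ?rfood .
  ?rfood a owl:Restriction ; owl:onProperty ?hasParticipant ;
         owl:someValuesFrom ?fin .
  ?fin rdfs:subClassOf* ?food .
  ?list rdf:rest*/rdf:first ?rdrug .
  ?rdrug a owl:Restriction ; owl:onProperty ?hasInput ;
         owl:someValuesFrom ?drug .
  OPTIONAL { ?drug rdfs:label ?label }
}
"""

_CQ3 = _PREFIX_BLOCK + """
SELECT DISTINCT ?drug ?label WHERE {
  ?fdi owl:equivalentClass ?eq .
  ?eq owl:intersectionOf ?list .
  ?list rdf:rest*/rdf:first ?rfood .
  ?rfood a owl:Restriction ; owl:onProperty ?hasParticipant ;
         owl:someValuesFrom ?fin .
  ?fin rdfs:subClassOf* ?food .
  ?list rdf:rest*/rdf:first ?rdrug .
  ?rdrug a owl:Restriction ; owl:onProperty ?hasInput ;
         owl:someValuesFrom ?drug .
  ?drug rdfs:subClassOf* ?cls .
  OPTIONAL { ?drug rdfs:label ?label }
}
"""

_CQ5 = _PREFIX_BLOCK + """
SELECT DISTINCT ?source ?label WHERE {
  ?source ?isAbout ?fdi .
  ?fdi owl:equivalentClass ?eq .
  ?eq owl:intersectionOf ?list .
  ?list rdf:rest*/rdf:first ?rfood .
  ?rfood a owl:Restriction ; owl:onProperty ?hasParticipant ;
         owl:someValuesFrom ?food .
  ?list rdf:rest*/rdf:first ?rdrug .
  ?rdrug a owl:Restriction ; owl:onProperty ?hasInput ;
         owl:someValuesFrom ?drug .
  OPTIONAL { ?source rdfs:label ?label }
}
"""

NOT_REPRESENTABLE = {
    "CQ4": "interaction mechanisms are not represented in this knowledge base",
    "CQ6": "clinical-importance levels are not represented in this knowledge base",
    "CQ7": "food categories are not represented in this knowledge base",
    "CQ8": "alternative drugs are not representable: only drugs with at least "
           "one interaction are included",
}


@dataclass
class CqResult:
    question_id: str
    bindings: list[tuple[str, str]]  # (curie, label), deduplicated, label-sorted
    query_text: str
    warnings: list[str] = field(default_factory=list)


def _known(graph: Graph, iri: URIRef) -> bool:
    return any(graph.triples((iri, None, None))) or any(
        graph.triples((None, None, iri))
    )


def _run(
    graph: Graph,
    question_id: str,
    query: str,
    bindings: dict[str, URIRef],
    config: KbConfig,
    warn_missing: list[URIRef],
) -> CqResult:
    warnings = [
        f"unknown CURIE {iri_to_curie(str(iri), config)}"
        for iri in warn_missing
        if not _known(graph, iri)
    ]
    rel = {
        "hasParticipant": curie_to_iri("RO:0000057", config),
        "hasInput": curie_to_iri("RO:0002233", config),
        "isAbout": curie_to_iri("IAO:0000136", config),
    }
    rows = graph.query(query, initBindings={**rel, **bindings})
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for row in rows:
        curie = iri_to_curie(str(row[0]), config)
        if curie in seen:
            continue
        seen.add(curie)
        out.append((curie, str(row[1]) if row[1] is not None else ""))
    out.sort(key=lambda t: (t[1], t[0]))
    return CqResult(question_id, out, query, warnings)


def foods_for_drug(
    graph: Graph, drug_curie: str, config: KbConfig = DEFAULT_CONFIG
) -> CqResult:
    """CQ1: foods whose interaction involves the drug or one of its
    subclasses."""
    drug = curie_to_iri(drug_curie, config)
    return _run(graph, "CQ1", _CQ1, {"drug": drug}, config, [drug])


def drugs_for_food(
    graph: Graph, food_curie: str, config: KbConfig = DEFAULT_CONFIG
) -> CqResult:
    """CQ2: mirror of CQ1 with roles swapped."""
    food = curie_to_iri(food_curie, config)
    return _run(graph, "CQ2", _CQ2, {"food": food}, config, [food])


def drugs_in_class_for_food(
    graph: Graph,
    food_curie: str,
    class_curie: str,
    config: KbConfig = DEFAULT_CONFIG,
) -> CqResult:
    """CQ3: drugs interacting with the food, restricted to descendants of a
    therapeutic (ATC scaffold) class."""
    food = curie_to_iri(food_curie, config)
    cls = curie_to_iri(class_curie, config)
    return _run(graph, "CQ3", _CQ3, {"food": food, "cls": cls}, config, [food, cls])


def sources_for_interaction(
    graph: Graph,
    food_curie: str,
    drug_curie: str,
    config: KbConfig = DEFAULT_CONFIG,
) -> CqResult:
    """CQ5: provenance concepts that report the (food, drug) interaction."""
    food = curie_to_iri(food_curie, config)
    drug = curie_to_iri(drug_curie, config)
    res = _run(
        graph, "CQ5", _CQ5, {"food": food, "drug": drug}, config, [food, drug]
    )
    if not res.bindings and not res.warnings:
        res.warnings.append(
            f"no interaction recorded for ({food_curie}, {drug_curie})"
        )
    return res


def unsupported(question_id: str) -> CqResult:
    """Explicit non-answers for questions this model cannot express."""
    if question_id not in NOT_REPRESENTABLE:
        raise ValueError(f"unknown competency question {question_id!r}")
    return CqResult(
        question_id, [], "", [NOT_REPRESENTABLE[question_id]]
    )


# --------------------------------------------------------------------------
# Brute-force oracle over the in-memory KB (pre-serialization); used by the
# test suite to cross-check every SPARQL answer.
# --------------------------------------------------------------------------


def _descendants(kb, root: str) -> set[str]:
    children: dict[str, set[str]] = {}
    for node in kb.concepts.values():
        for p in node.parents:
            children.setdefault(p, set()).add(node.curie)
    out = {root}
    stack = [root]
    while stack:
        cur = stack.pop()
        for ch in children.get(cur, ()):
            if ch not in out:
                out.add(ch)
                stack.append(ch)
    return out


def brute_foods_for_drug(kb, drug_curie: str) -> set[str]:
    subs = _descendants(kb, drug_curie)
    return {f.food_curie for f in kb.fdis if f.drug_curie in subs}


def brute_drugs_for_food(kb, food_curie: str) -> set[str]:
    subs = _descendants(kb, food_curie)
    return {f.drug_curie for f in kb.fdis if f.food_curie in subs}


def brute_drugs_in_class_for_food(kb, food_curie: str, class_curie: str) -> set[str]:
    return brute_drugs_for_food(kb, food_curie) & _descendants(kb, class_curie)


def brute_sources_for_interaction(kb, food_curie: str, drug_curie: str) -> set[str]:
    for f in kb.fdis:
        if f.food_curie == food_curie and f.drug_curie == drug_curie:
            return set(f.source_curies)
    return set()
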