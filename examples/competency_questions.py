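"""Ask the competency questions over a tiny hand-built knowledge base.

Builds a three-concept knowledge base (garlic, warfarin, heparin with two
interactions and two provenance entries), emits it as OWL and answers:
which foods interact with warfarin (CQ1), which drugs interact with garlic
(CQ2), which antithrombotic agents interact with garlic (CQ3), and who
reports the garlic-warfarin interaction (CQ5).
"""
import tempfile
from pathlib import Path

from fdiforge.atc import AtcEntry, build_atc_scaffold, place_drug, place_food_or_herb
from fdiforge.cq import (
    drugs_for_food,
    drugs_in_class_for_food,
    foods_for_drug,
    sources_for_interaction,
)
from fdiforge.kb import KnowledgeBase, compile_pairs, link_sources
from fdiforge.mapping import MappingResult
from fdiforge.owl import emit_owl

scaffold = build_atc_scaffold(
    [AtcEntry("B", "BLOOD AND BLOOD FORMING ORGANS"),
     AtcEntry("B01", "ANTITHROMBOTIC AGENTS")]
)
kb = KnowledgeBase()
for node in scaffold.node_list():
    kb.add_concept(node)

warfarin = MappingResult("warfarin", "drug", "CHEBI:10033", "CHEBI", "label", "warfarin")
heparin = MappingResult("heparin", "drug", "CHEBI:28304", "CHEBI", "label", "heparin")
garlic = MappingResult("garlic", "food", "FoodOn:03301844", "FOODON", "label",
                       "garlic food product")
kb.add_concept(place_drug(warfarin, {"B01"}, scaffold))
kb.add_concept(place_drug(heparin, {"B01"}, scaffold))
kb.add_concept(place_food_or_herb(garlic, scaffold))

pairs = [
    ("FoodOn:03301844", "CHEBI:10033", "DrugBank:DB00682"),
    ("FoodOn:03301844", "CHEBI:10033", "Hedrine:H0001"),
    ("FoodOn:03301844", "CHEBI:28304", "Hedrine:H0002"),
]
labels = {c: n.label for c, n in kb.concepts.items()}
kb.fdis, sources = compile_pairs(pairs, labels)
kb.sources = {s.curie: s for s in sources.values()}
kb.is_about = link_sources(kb.fdis, sources)

with tempfile.TemporaryDirectory() as tmp:
    graph = emit_owl(kb, Path(tmp) / "kb.ttl")

b01 = scaffold.by_code["B01"]
for res in (
    foods_for_drug(graph, "CHEBI:10033"),
    drugs_for_food(graph, "FoodOn:03301844"),
    drugs_in_class_for_food(graph, "FoodOn:03301844", b01),
    sources_for_interaction(graph, "FoodOn:03301844", "CHEBI:10033"),
):
    print(res.question_id, "->", [label for _, label in res.bindings])
# CQ1 lists the one food paired with warfarin; CQ2/CQ3 list both
# antithrombotic drugs paired with garlic; CQ5 names the database page and
# the structured entry that report the garlic-warfarin interaction.
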