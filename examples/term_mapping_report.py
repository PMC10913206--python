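"""Resolve drug/food/herb terms through the ontology cascade.

Drugs are looked up in the chemical-entity index and fall back to the
drug-product index; foods only in the food index; herbs in the food index
with a drug-product fallback.  The report tallies hits per ontology and a
rounded coverage percentage per category.
"""
import json

from fdiforge.mapping import TermIndex, build_report, map_terms

chebi = TermIndex("CHEBI")
chebi.add("CHEBI:10033", "warfarin", ["coumadin"])
chebi.add("CHEBI:28304", "heparin")
dron = TermIndex("DRON")
dron.add("DrOn:00017208", "ardeparin")
dron.add("DrOn:00018111", "licorice")
foodon = TermIndex("FOODON")
foodon.add("FoodOn:03301844", "garlic food product", ["garlic"])
foodon.add("FoodOn:03301123", "grapefruit food product", ["grapefruit"])
indexes = {"CHEBI": chebi, "DRON": dron, "FOODON": foodon}

terms = [
    ("Warfarin", "drug"),      # chemical-entity label hit
    ("coumadin", "drug"),      # synonym hit
    ("ardeparin", "drug"),     # absent from ChEBI, found in the drug ontology
    ("unknowndrug", "drug"),   # miss
    ("grapefruit", "food"),
    ("licorice", "herb"),      # only the drug ontology knows it
    ("garlic", "herb"),
]
results = map_terms(terms, indexes)
for r in results:
    print(f"{r.term:12s} {r.category:5s} -> {r.curie or 'unmapped':18s}"
          f" via {r.hit_ontology or '-'} ({r.match_kind})")

report = build_report(results, indexes)
print(json.dumps(report.as_dict()["drug"], indent=2))
# by_ontology counts first-hit (cascade) resolutions; raw_coverage shows what
# each ontology could resolve on its own, so the two differ when cascades
# overlap. mapped_pct is rounded half-up, matching how coverage ratios are
# conventionally reported.
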