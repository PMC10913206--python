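# fdiforge

Food–drug interactions — grapefruit juice potentiating a statin, vitamin-K
rich vegetables blunting warfarin — are scattered across drug databases as
free-text recommendation fields and across herb–drug resources as structured
entries. `fdiforge` compiles both kinds of records into a single OWL
knowledge base of *precompiled interaction concepts*, one ontology class per
(food, drug) pair, so that pharmacists, ontology curators and knowledge-graph
builders can query interactions with plain SPARQL instead of re-reading
prose.

## The model

Each interaction is a defined class: an interaction process involving a food
and altering the state of a drug,

```
FDI <food>–<drug>  ≡  'food drug interaction'
                       ⊓ ∃ has_participant . <food>     (RO:0000057)
                       ⊓ ∃ has_input . <drug>           (RO:0002233)
```

The food merely participates; only the drug's state changes during the
process, hence the more specific `has_input` on the drug side. Around these
classes the builder assembles:

* **a drug scaffold** from the first two ATC levels (anatomical main groups
  and therapeutic subgroups), with class names normalized to ontology
  conventions (lower-case, singular head noun, level-1 groups reworded as
  "drug target of …") and each class cross-referenced to its ATC code's web
  page; drugs with no ATC code sit under "not elsewhere classified drug";
* **food and herb placement**: terms resolved in the food ontology hang
  directly under "food product" (intermediate hierarchy flattened), herbs
  that only resolve in the drug-product ontology hang under "processed
  material";
* **term mapping** through a per-category cascade over local label/synonym
  indexes — drugs: chemical-entity index then drug-product index; foods:
  food index; herbs: food index then drug-product index — with a manual
  override table for the remainder and a coverage report
  (hits per ontology, round-half-up percentages);
* **provenance**: every source page/entry becomes an "information source for
  interaction" class linked to the interactions it reports with `is_about`
  (IAO:0000136), so cross-source agreement is queryable;
* **deduplication**: a pair reported by both sources collapses to one
  concept that accumulates all provenance (unique pairs follow
  inclusion–exclusion over the per-source pair sets).

The result is emitted both as a ROBOT-style template spreadsheet (two header
rows, `ID / LABEL / SC % / TYPE / EC %`, Manchester-syntax logical
definitions; interaction rows leave the parent column empty because their
definition already asserts the genus) and as OWL (Turtle or RDF/XML).
Competency questions — foods for a drug, drugs for a food, drugs of a
therapeutic class for a food, sources for a pair — are answered with SPARQL
that destructures the equivalence axioms and closes over the hierarchy with
`rdfs:subClassOf*`; no DL reasoner is required. Inter-annotator agreement on
the manual term annotations that feed the pipeline is measured per category
with Fleiss' kappa.

## Worked example

`examples/competency_questions.py` builds a three-drug knowledge base by
hand (garlic paired with warfarin and heparin, warfarin's pairing reported
by both a drug-database page and a structured entry), emits OWL and asks the
four supported competency questions:

```
CQ1 -> ['garlic food product']
CQ2 -> ['heparin', 'warfarin']
CQ3 -> ['heparin', 'warfarin']
CQ5 -> ['DrugBank:DB00682', 'Hedrine:H0001']
```

CQ1 lists the foods interacting with warfarin; CQ2 the drugs interacting
with garlic; CQ3 restricts CQ2 to descendants of the "antithrombotic agent"
ATC class (both drugs carry code B01); CQ5 names the two provenance entries
reporting the garlic–warfarin pair. `examples/build_knowledge_base.py` runs
the full pipeline on a seeded synthetic bundle:

```
entity totals: {'drugs': 24, 'foods_herbs': 19, 'fdis': 31, 'sources': 29}
expected unique pairs: 31 (23 + 11 per source, 3 shared)
one interaction concept: FIDEO:002000000 = FDI apple food product–amietincypran
```

31 unique pairs = 23 + 11 − 3 shared, the inclusion–exclusion identity the
compiler must reproduce. The other examples demonstrate the mapping cascade
report and the kappa computation. A thin CLI mirrors the stages
(`forge ingest | agreement | map | build | emit | stats | query | fixtures`).

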