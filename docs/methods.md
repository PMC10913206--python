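# Methods

## Scope and model

The package compiles food–drug interaction (FDI) records from two source
shapes — a drug-database XML export whose per-drug `food-interactions` field
holds free-text recommendation sentences, and a structured herb–drug CSV —
into an OWL knowledge base. Interactions are *classes*, not instances: each
(food, drug) pair becomes one precompiled concept whose logical definition
is the intersection of the genus `'food drug interaction'` with
`has_participant some <food>` (RO:0000057) and `has_input some <drug>`
(RO:0002233). The asymmetric relation choice encodes the modeling
assumption that both entities take part in the interaction process but only
the drug's state is altered by it. Representing interactions as defined
classes keeps the knowledge base reasoner-free: everything a competency
question needs is asserted at compile time, and `rdfs:subClassOf*` property
paths supply the only closure required.

## Ingestion and sentence filtering

Sentence segmentation splits on sentence-final `.`/`!`/`?` followed by
whitespace and an uppercase (or quote/parenthesis) opener; recommendation
items are additionally split at the XML list-item boundaries. Segmentation
is deterministic and classification is total: every sentence is labelled,
and interaction/non-interaction counts partition the corpus. Sentences that
assert the *absence* of an interaction ("Take with or without food", "Food
does not affect …") are flagged non-interactions via a configurable phrase
list — the sources decided such cases editorially, so the rule is explicit
and overridable here. Bare timing instructions ("Take on an empty stomach")
are interactions with food in general: they carry a `generic_food_flag`
rather than a named food.

## Annotation agreement

Manual annotations are stored as BRAT-style standoff spans with 0-based
half-open Unicode-code-point offsets. Agreement is Fleiss' kappa per
category; free spans are reduced to a rating table by taking the union of
all annotators' span extents (overlapping extents merged) as items and
rating each item category/not-category per annotator — the standard
reduction from span annotation to a fixed-panel rating table. Unanimity on
every item returns exactly 1.0 before the formula is evaluated; this also
covers the degenerate single-category table, where the chance-agreement
term would otherwise make the statistic 0/0. The uniform-ratings property
(kappa → 0) is verified stochastically at 10 000 items with a fixed seed
and ±0.05 tolerance.

## Term mapping

Lookups run over local label/synonym indexes (TSV), one per reference
ontology. The lookup contract — `find(normalized term)` returning
`(CURIE, canonical label, label|synonym)` — is the interface a live
ontology-lookup-service adapter could later satisfy; nothing above it knows
whether the index is local. Normalization is casefold + whitespace collapse
+ surrounding-punctuation strip, iterated to a fixed point so the function
is idempotent; interior punctuation (abbreviation periods, apostrophes) is
preserved. Within an ontology an exact canonical-label match outranks an
exact synonym match; there is no fuzzy matching — an edit-distance
suggestion list is produced for curators but never auto-applied, and the
manual-override table (term, category, CURIE, label) fills only unmapped
terms unless explicitly forced. An index key resolving to two CURIEs aborts
the index build: a silent arbitrary choice would corrupt the knowledge
base. The coverage report counts cascade (first-hit) resolutions per
ontology — these plus manual plus unmapped partition each category's total
— and, separately, raw per-ontology lookup coverage, which may double-count
a term both ontologies know.

## ATC scaffold

Only ATC levels 1–2 are used: enough hierarchy to group drugs by
anatomical/therapeutic class without importing the full classification.
Label normalization lower-cases, singularizes the final token (trailing
`s` stripped unless the token ends in `-ss`, `-us`, `-is` or sits on an
exception list) and prefixes level-1 names with "drug target of ", since an
anatomical group is not itself a drug type; the transformation is
idempotent, and a rename-override table handles source names the rule
cannot fix. Every scaffold class carries a `hasDbXref` to
`https://www.whocc.no/atc_ddd_index/?code=<CODE>`. The scaffold always
contains four root concepts (material entity, chemical entity, food
product, processed material) plus a "not elsewhere classified drug" class
for drugs without a code; scaffold IDs are minted deterministically in code
sort order. Foods keep only the direct edge to "food product" — the
intermediate food-ontology hierarchy is deliberately flattened; retaining
it is future work tied to food-category questions.

## Compilation and identifiers

Pairs are deduplicated on (food CURIE, drug CURIE); provenance references
of a collapsed pair accumulate on the surviving concept, so every concept
has ≥ 1 source and cross-source agreement is preserved. Minting is
deterministic: interaction concepts are ordered by (drug label, food label)
and numbered from a configurable base with a configurable zero-padded width
(default 9); provenance concepts are numbered in sorted-label order from a
separate base. Labels are `FDI <food>–<drug>` with U+2013 and no
surrounding spaces. The genus and the "information source for interaction"
root are config values in the FIDEO namespace because no canonical IDs
exist for them.

## Serialization

The OWL graph is built with rdflib. Equivalence axioms use
`owl:equivalentClass` → `owl:intersectionOf` list → two
`owl:Restriction`s; blank nodes get deterministic skolem-style ids derived
from the concept's local ID so serializations diff cleanly across runs.
`is_about` is asserted as a plain triple between class IRIs
(annotation-level): the model is entirely class-level and has no
individuals to relate. The parser is the emitter's inverse up to blank-node
renaming, with one documented loss: a herb placed under "food product" is
indistinguishable from a food there, so it reads back as a food — exactly
the distinction the model itself gives up; herbs under "processed material"
survive. Non-conforming equivalence shapes (e.g. a missing `has_input`
conjunct) are collected into a problem report, never dropped. The
ROBOT-style template mirrors the graph: human header row, template-string
row (`ID, LABEL, SC %, TYPE, EC %`), one row per entity, Manchester syntax
with single-quoted multiword labels in the equivalence column, and an empty
parent cell for interaction rows whose definition already asserts the
genus. An empty knowledge base yields exactly the two header rows.

## Statistics

Totals, per-food and per-drug interaction-count marginals (each must sum to
the interaction total), distribution summaries (mean to one decimal,
type-7 linear-interpolation quartiles, maximum) and top-k tables with
round-half-up coverage percentages. Ties in top-k break by count descending
then label ascending. Published distribution means for this kind of table
are not exactly recomputable from the printed totals, so distribution
values are validated on constructed fixtures only; the top-k sums,
coverage percentages and maxima are validated against the published ranked
tables, which are exact arithmetic.

## Synthetic bundles

The generator emulates: free-text recommendation fields built from the
observed sentence patterns (including non-interaction and timing
sentences), a structured herb–drug CSV, term indexes with per-category hit
rates (defaults 0.87 for drugs and 0.45 for foods, the coverage levels
reported for real reference ontologies; 0.6 for herbs, between the two), a
forced number of cross-source shared pairs, and an ATC table with a
configurable fraction of code-less drugs (default 0.2, matching the
roughly 1-in-5 share reported for real corpora). Default sizes (30 XML
drugs, 20 CSV entries, 5+10 ATC classes) keep every test and the
acceptance run in seconds on one CPU while exercising all code paths;
counts scale linearly for larger experiments. Ground truth (per-source and
unique pair counts, mapping tallies under the pipeline's term identity,
marginals, source counts, ATC split) is computed during construction,
never by running the pipeline, so end-to-end recovery is a genuine test.
What the fixtures do *not* emulate: real label variability (misspellings,
multilingual names), pharmacological plausibility of pairs, and the
long-tailed interaction-count distributions of real corpora — passing
tests demonstrate correctness of the plumbing and the invariants, not
performance on real database exports, which are license-gated.

## Known limitations

Interaction mechanisms, clinical-importance levels, food categories and
alternative-drug suggestions are out of scope; the corresponding
competency questions return explicit "not representable" responses.
Sentence segmentation is rule-based and English-only. The herb/food
distinction is partially lost by design (see Serialization). Fuzzy term
matching is deliberately absent from the automatic path.
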