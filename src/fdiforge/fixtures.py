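"""Synthetic source bundles with known ground truth.

Generates the five input kinds the pipeline consumes — drug XML with
free-text recommendation fields, structured herb-drug CSV, label/synonym
term-index TSVs for the three reference ontologies, an ATC level-1/2 table
and a drug-to-ATC-code table — from a seeded specification, together with a
GroundTruth object computed *by construction* (never by running the
pipeline).  Identical seeds yield byte-identical bundles.

The free text is built from the recommendation patterns observed in real
drug databases ("Avoid X.", "Take with food.", "Take on an empty stomach.",
"Take with or without food. ...") so the sentence filter is exercised; the
vocabulary is a pool of plausible food/herb/drug names whose identity, not
meaning, is what matters.

A second, non-random bundle (:func:`paper_tables_fixture`) carries published
worked-example inputs — ranked interaction-count tables, mapping tallies and
a five-item recommendation field — as machine-readable data for arithmetic
checks.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .ingest import DrugRecord, serialize_drugbank_xml

_FOOD_WORDS = [
    "grapefruit", "orange", "spinach", "kale", "broccoli", "banana", "cheese",
    "yogurt", "coffee", "tea", "cranberry", "pomegranate", "apple", "grape",
    "milk", "avocado", "tomato", "carrot", "oat", "walnut", "almond", "salmon",
    "beef", "liver", "soybean", "lentil", "mushroom", "onion", "leek", "fig",
    "date", "plum", "peach", "melon", "papaya", "mango", "guava", "quince",
]
_HERB_WORDS = [
    "garlic", "ginger", "ginkgo", "ginseng", "valerian", "echinacea",
    "feverfew", "kava", "licorice", "chamomile", "peppermint", "sage",
    "rosemary", "thyme", "fennel", "milk thistle", "hawthorn", "goldenseal",
    "saw palmetto", "black cohosh", "devils claw", "yarrow", "nettle",
    "dandelion", "burdock", "angelica", "skullcap", "vervain", "hops",
    "passionflower",
]
_DRUG_SYLLABLES = ["var", "fa", "rin", "lo", "pril", "mex", "tan", "zo", "dip",
                   "ine", "sta", "tin", "cy", "clo", "vir", "ami", "dar", "one",
                   "flu", "ox", "etin", "ke", "to", "nazole", "pro", "pran",
                   "olol", "meth", "o", "trexate"]
_ATC1_NAMES = [
    "ALIMENTARY TRACT AND METABOLISM", "BLOOD AND BLOOD FORMING ORGANS",
    "CARDIOVASCULAR SYSTEM", "DERMATOLOGICALS", "GENITO URINARY SYSTEM",
    "SYSTEMIC HORMONAL PREPARATIONS", "ANTIINFECTIVES FOR SYSTEMIC USE",
    "ANTINEOPLASTIC AND IMMUNOMODULATING AGENTS", "MUSCULO-SKELETAL SYSTEM",
    "NERVOUS SYSTEM", "ANTIPARASITIC PRODUCTS", "RESPIRATORY SYSTEM",
    "SENSORY ORGANS", "VARIOUS",
]
_ATC1_CODES = "ABCDGHJLMNPRSV"
_ATC2_HEADS = [
    "ANTITHROMBOTIC AGENTS", "ANTACIDS", "DIURETICS", "BETA BLOCKING AGENTS",
    "ANTIMYCOTICS", "ANTIHISTAMINES", "VASOPROTECTIVES", "PSYCHOLEPTICS",
    "ANALGESICS", "ANTIEPILEPTICS", "OPHTHALMOLOGICALS", "CORTICOSTEROIDS",
    "IMMUNOSUPPRESSANTS", "VACCINES", "LIPID MODIFYING AGENTS",
]


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 0
    n_drugbank_drugs: int = 30
    n_hedrine_entries: int = 20
    pct_with_interactions: float = 0.8
    mapping_hit_rate: dict[str, float] = field(
        default_factory=lambda: {"drug": 0.87, "food": 0.45, "herb": 0.6}
    )
    n_shared_pairs: int = 3
    n_atc1: int = 5
    n_atc2: int = 10
    pct_drugs_without_atc: float = 0.2

    def validate(self) -> None:
        for name in ("pct_with_interactions", "pct_drugs_without_atc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise FixtureError(f"{name} must be in [0,1], got {v}")
        for cat, v in self.mapping_hit_rate.items():
            if not 0 <= v <= 1:
                raise FixtureError(f"mapping_hit_rate[{cat}] out of [0,1]: {v}")
        if self.n_atc1 > len(_ATC1_CODES):
            raise FixtureError(f"n_atc1 cannot exceed {len(_ATC1_CODES)}")


@dataclass
class GroundTruth:
    """Expected pipeline outcomes, computed by construction."""

    n_drugbank_records: int = 0
    n_drugbank_with_interactions: int = 0
    n_hedrine_entries: int = 0
    term_totals: dict[str, int] = field(default_factory=dict)
    term_mapped: dict[str, int] = field(default_factory=dict)
    drugbank_pairs: int = 0  # distinct mapped pairs from the XML source
    hedrine_pairs: int = 0
    unique_pairs: int = 0  # union; inclusion-exclusion with shared_pairs
    shared_pairs: int = 0
    per_food: dict[str, int] = field(default_factory=dict)  # curie -> count
    per_drug: dict[str, int] = field(default_factory=dict)
    n_sources: int = 0
    drugs_with_atc: int = 0
    drugs_without_atc: int = 0

    def validate(self) -> None:
        if self.unique_pairs != self.drugbank_pairs + self.hedrine_pairs - self.shared_pairs:
            raise FixtureError("inclusion-exclusion identity violated")
        if sum(self.per_food.values()) != self.unique_pairs:
            raise FixtureError("per-food marginal != unique pairs")
        if sum(self.per_drug.values()) != self.unique_pairs:
            raise FixtureError("per-drug marginal != unique pairs")

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True), encoding="utf-8"
        )


def _drug_name(rng: random.Random, taken: set[str]) -> str:
    while True:
        n = rng.randint(3, 4)
        name = "".join(rng.choice(_DRUG_SYLLABLES) for _ in range(n))
        if name not in taken:
            taken.add(name)
            return name


def _pool(words: list[str], n: int) -> list[str]:
    out = list(words)
    i = 2
    while len(out) < n:
        out.extend(f"{w} {i}" for w in words)
        i += 1
    return out[:n]


def generate(spec: FixtureSpec, out_dir: str | Path) -> GroundTruth:
    """Write a complete input bundle under ``out_dir``; return its truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- vocabularies -----------------------------------------------------
    taken: set[str] = set()
    db_drugs = [_drug_name(rng, taken) for _ in range(spec.n_drugbank_drugs)]
    n_hed_drugs = max(1, spec.n_hedrine_entries // 2)
    hed_only_drugs = [_drug_name(rng, taken) for _ in range(n_hed_drugs)]
    foods = _pool(_FOOD_WORDS, max(10, spec.n_drugbank_drugs))
    herbs = _pool(_HERB_WORDS, max(10, spec.n_hedrine_entries))

    # ---- mapping status per distinct term --------------------------------
    all_drugs = db_drugs + hed_only_drugs
    drug_mapped = {d: rng.random() < spec.mapping_hit_rate["drug"] for d in all_drugs}
    food_mapped = {f: rng.random() < spec.mapping_hit_rate["food"] for f in foods}
    herb_mapped = {h: rng.random() < spec.mapping_hit_rate["herb"] for h in herbs}
    # mapped drugs split between the chemical and drug-product ontologies
    drug_in_chebi = {d: rng.random() < 0.8 for d in all_drugs}
    # mapped herbs split between the food and drug-product ontologies
    herb_in_foodon = {h: rng.random() < 0.5 for h in herbs}

    curies: dict[tuple[str, str], str] = {}
    chebi_rows, foodon_rows, dron_rows = [], [], []
    counter = 1000
    for d in all_drugs:
        if drug_mapped[d]:
            if drug_in_chebi[d]:
                curie = f"CHEBI:{counter}"
                chebi_rows.append((curie, d, ""))
            else:
                curie = f"DrOn:{counter:08d}"
                dron_rows.append((curie, d, ""))
            curies[(d, "drug")] = curie
            counter += 1
    for f in foods:
        if food_mapped[f]:
            curie = f"FoodOn:{counter:08d}"
            foodon_rows.append((curie, f"{f} food product", f))
            curies[(f, "food")] = curie
            counter += 1
    for h in herbs:
        if herb_mapped[h]:
            if herb_in_foodon[h]:
                curie = f"FoodOn:{counter:08d}"
                foodon_rows.append((curie, h, ""))
            else:
                curie = f"DrOn:{counter:08d}"
                dron_rows.append((curie, h, ""))
            curies[(h, "herb")] = curie
            counter += 1

    # ---- drug-database records with recommendation text ------------------
    n_with = round(spec.n_drugbank_drugs * spec.pct_with_interactions)
    with_interactions = set(db_drugs[:n_with])
    records: list[DrugRecord] = []
    annotations: list[tuple[str, str, str]] = []
    db_pairs: set[tuple[str, str]] = set()  # (term-curie, drug-curie)
    db_pair_terms: list[tuple[str, str, str]] = []  # (term, category, drug)
    for i, d in enumerate(db_drugs, 1):
        rec_id = f"DrugBank:DB{i:05d}"
        items: list[str] = []
        if d in with_interactions:
            k = rng.randint(1, 3)
            terms: list[tuple[str, str]] = []
            for _ in range(k):
                if rng.random() < 0.7:
                    terms.append((rng.choice(foods), "food"))
                else:
                    terms.append((rng.choice(herbs), "herb"))
            for term, category in dict(terms).items():
                items.append(f"Avoid {term}. It may alter the effect of {d}.")
                annotations.append((rec_id, term, category))
                db_pair_terms.append((term, category, d))
            if rng.random() < 0.3:
                items.append("Take on an empty stomach.")
            if rng.random() < 0.2:
                items.append(
                    "Take with or without food. Food does not affect the "
                    "bioavailability."
                )
        records.append(DrugRecord(rec_id, d, items, "drugbank"))
    serialize_drugbank_xml(records, out / "drugbank.xml")

    for term, category, d in db_pair_terms:
        tc = curies.get((term, category))
        dc = curies.get((d, "drug"))
        if tc and dc:
            db_pairs.add((tc, dc))

    # ---- structured herb-drug entries, with forced cross-source overlap --
    shared_candidates = sorted(
        (term, d)
        for term, category, d in db_pair_terms
        if (term, category) in curies and (d, "drug") in curies
    )
    # dedupe on the mapped pair so shared pairs are counted once
    seen_pairs: set[tuple[str, str]] = set()
    shared_pool: list[tuple[str, str]] = []
    for term, d in shared_candidates:
        cat = "food" if (term, "food") in curies else "herb"
        pair = (curies[(term, cat)], curies[(d, "drug")])
        if pair not in seen_pairs:
            seen_pairs.add(pair)
            shared_pool.append((term, d))
    if spec.n_shared_pairs > len(shared_pool):
        raise FixtureError(
            f"n_shared_pairs={spec.n_shared_pairs} exceeds the "
            f"{len(shared_pool)} mappable cross-source candidates"
        )
    shared = rng.sample(shared_pool, spec.n_shared_pairs)

    hed_rows: list[tuple[str, str, str]] = []  # (entry_id, plant, drug)
    hed_pairs: set[tuple[str, str]] = set()
    entry_no = 1
    for term, d in shared:
        hed_rows.append((f"H{entry_no:04d}", term, d))
        entry_no += 1
    while len(hed_rows) < spec.n_hedrine_entries:
        plant = rng.choice(herbs)
        drug = rng.choice(hed_only_drugs)
        hed_rows.append((f"H{entry_no:04d}", plant, drug))
        entry_no += 1
    for _eid, plant, drug in hed_rows:
        # hedrine plants resolve through the herb cascade; a shared term
        # annotated as food in the XML still lands on the same food-index CURIE
        tc = curies.get((plant, "herb")) or curies.get((plant, "food"))
        dc = curies.get((drug, "drug"))
        if tc and dc:
            hed_pairs.add((tc, dc))

    with open(out / "hedrine.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("entry_id,plant_name,drug_name,mechanism_text,clinical_importance\n")
        for eid, plant, drug in hed_rows:
            fh.write(f"{eid},{plant},{drug},,\n")

    with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
        for rec_id, term, category in annotations:
            fh.write(f"{rec_id}\t{term}\t{category}\n")

    for name, rows in (
        ("chebi.tsv", chebi_rows), ("foodon.tsv", foodon_rows), ("dron.tsv", dron_rows)
    ):
        with open(out / name, "w", encoding="utf-8") as fh:
            for curie, lab, syn in rows:
                fh.write(f"{curie}\t{lab}\t{syn}\n")
    (out / "overrides.tsv").write_text("", encoding="utf-8")

    # ---- ATC table and drug->code assignments ----------------------------
    atc_rows: list[tuple[str, str]] = []
    level1 = list(_ATC1_CODES[: spec.n_atc1])
    for i, code in enumerate(level1):
        atc_rows.append((code, _ATC1_NAMES[i % len(_ATC1_NAMES)]))
    level2: list[str] = []
    for i in range(spec.n_atc2):
        code = f"{level1[i % len(level1)]}{i + 1:02d}"
        atc_rows.append((code, _ATC2_HEADS[i % len(_ATC2_HEADS)]))
        level2.append(code)
    with open(out / "atc.tsv", "w", encoding="utf-8") as fh:
        for code, name in atc_rows:
            fh.write(f"{code}\t{name}\n")

    drug_code_rows: list[tuple[str, list[str]]] = []
    n_with_atc = 0
    drugs_in_pairs = sorted(
        {d for _t, _c, d in db_pair_terms if (d, "drug") in curies}
        | {drug for _e, _p, drug in hed_rows if (drug, "drug") in curies}
    )
    with_atc_drugs: set[str] = set()
    for d in drugs_in_pairs:
        if rng.random() >= spec.pct_drugs_without_atc:
            codes = rng.sample(level2, rng.randint(1, min(3, len(level2))))
            drug_code_rows.append((d, sorted(codes)))
            with_atc_drugs.add(d)
    with open(out / "drug_codes.tsv", "w", encoding="utf-8") as fh:
        for d, codes in drug_code_rows:
            fh.write(f"{d}\t{'|'.join(codes)}\n")

    # ---- ground truth, by construction -----------------------------------
    union = db_pairs | hed_pairs
    per_food: dict[str, int] = {}
    per_drug: dict[str, int] = {}
    for fc, dc in sorted(union):
        per_food[fc] = per_food.get(fc, 0) + 1
        per_drug[dc] = per_drug.get(dc, 0) + 1

    db_source_ids = set()
    for i, d in enumerate(db_drugs, 1):
        rec_id = f"DrugBank:DB{i:05d}"
        has_pair = any(
            (curies.get((t, c)) and curies.get((dd, "drug")))
            for r, t, c in annotations
            for dd in [d]
            if r == rec_id
        )
        if has_pair:
            db_source_ids.add(rec_id)
    hed_source_ids = {
        eid
        for eid, plant, drug in hed_rows
        if (curies.get((plant, "herb")) or curies.get((plant, "food")))
        and curies.get((drug, "drug"))
    }

    drugs_in_kb = sorted({dc for _fc, dc in union})
    mapped_with_atc = {
        curies[(d, "drug")] for d in with_atc_drugs if (d, "drug") in curies
    }
    n_atc = sum(1 for dc in drugs_in_kb if dc in mapped_with_atc)

    # term tallies use the same identity the mapping stage sees: distinct
    # (term, category) among corpus drugs, annotated foods/herbs, structured
    # drugs and plants — not the whole vocabulary pools
    drug_terms = sorted(with_interactions | {drug for _e, _p, drug in hed_rows})
    food_terms = sorted({t for _r, t, c in annotations if c == "food"})
    herb_terms = sorted(
        {t for _r, t, c in annotations if c == "herb"}
        | {plant for _e, plant, _d in hed_rows}
    )
    truth = GroundTruth(
        n_drugbank_records=len(db_drugs),
        n_drugbank_with_interactions=len(
            [r for r in records if r.recommendations]
        ),
        n_hedrine_entries=len(hed_rows),
        term_totals={
            "drug": len(drug_terms),
            "food": len(food_terms),
            "herb": len(herb_terms),
        },
        term_mapped={
            "drug": sum(1 for d in drug_terms if (d, "drug") in curies),
            "food": sum(1 for f in food_terms if (f, "food") in curies),
            "herb": sum(
                1
                for h in herb_terms
                if (h, "herb") in curies or (h, "food") in curies
            ),
        },
        drugbank_pairs=len(db_pairs),
        hedrine_pairs=len(hed_pairs),
        unique_pairs=len(union),
        shared_pairs=len(db_pairs & hed_pairs),
        per_food=per_food,
        per_drug=per_drug,
        n_sources=len(db_source_ids) + len(hed_source_ids),
        drugs_with_atc=n_atc,
        drugs_without_atc=len(drugs_in_kb) - n_atc,
    )
    truth.validate()
    truth.write_json(out / "groundtruth.json")
    return truth


def read_annotations_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            rec_id, term, category = line.split("\t")
            out.append((rec_id, term, category))
    return out


# --------------------------------------------------------------------------
# Published worked-example inputs
# --------------------------------------------------------------------------

#: ranked interaction counts of the ten foods most often involved
TOP10_FOOD_COUNTS = (326, 254, 168, 117, 96, 63, 48, 46, 36, 33)
TOP10_FOOD_LABELS = (
    "alcoholic beverage", "hypericum perforatum", "grapefruit food product",
    "food product", "turmeric food product", "glycyrrhiza glabra extract",
    "ginkgo biloba extract", "garlic food product", "ginger food product",
    "milk thistle extract",
)
#: ranked interaction counts of the eleven drugs most often involved
TOP11_DRUG_COUNTS = (17, 17, 15, 13, 12, 11, 11, 10, 10, 10, 10)
TOP11_DRUG_LABELS = (
    "cyclosporin", "warfarin", "paracetamol", "glyburide", "trioxsalen",
    "bortezomib", "phenelzine", "gliclazide", "levothyroxine",
    "tranylcypromine", "verapamil",
)
#: knowledge-base interaction total the ranked tables are percentages of
TOTAL_FDIS = 1702
#: automatic term-mapping tallies (mapped, total) per category
MAPPING_TALLIES = {
    "drug_chebi": (1026, 1177),
    "drug_dron_raw": (702, 1177),
    "food_foodon": (54, 121),
    "herb_foodon": (3, 15),
    "herb_dron": (6, 15),
}
#: per-source interaction counts before cross-source deduplication
PER_SOURCE_PAIRS = {"drugbank": 1245, "hedrine": 654}
#: provenance-concept counts per source
PER_SOURCE_SOURCES = {"drugbank": 662, "hedrine": 223}

#: the five recommendation items of the warfarin food-interactions field
WARFARIN_RECOMMENDATIONS = (
    "Avoid drastic dietary changes.",
    "Avoid foods rich in vitamin K. Vitamin K in foods such as leafy "
    "vegetables can reduce warfarin efficacy.",
    "Avoid grapefruit products. They may interfere with warfarin metabolism "
    "and increase INR, increasing the risk of bleeding.",
    "Avoid herbs and supplements with anticoagulant/antiplatelet activity. "
    "Examples include garlic, ginger, bilberry, danshen, piracetam, and "
    "ginkgo biloba.",
    "Avoid St. John’s Wort. This drug may reduce warfarin efficacy.",
)


def paper_tables_fixture(out_dir: str | Path) -> dict:
    """Write the published worked-example inputs as machine-readable files.

    Returns the same content as a dict: ranked count tables, mapping
    tallies, per-source pair totals, and a one-drug XML whose
    food-interactions field holds the five warfarin recommendation items.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "top_foods": [
            {"label": l, "count": c}
            for l, c in zip(TOP10_FOOD_LABELS, TOP10_FOOD_COUNTS)
        ],
        "top_drugs": [
            {"label": l, "count": c}
            for l, c in zip(TOP11_DRUG_LABELS, TOP11_DRUG_COUNTS)
        ],
        "total_fdis": TOTAL_FDIS,
        "mapping_tallies": {k: list(v) for k, v in MAPPING_TALLIES.items()},
        "per_source_pairs": dict(PER_SOURCE_PAIRS),
        "per_source_sources": dict(PER_SOURCE_SOURCES),
    }
    (out / "tables.json").write_text(
        json.dumps(doc, indent=2, ensure_ascii=False), encoding="utf-8"
    )
    serialize_drugbank_xml(
        [DrugRecord("DrugBank:DB00682", "warfarin", list(WARFARIN_RECOMMENDATIONS))],
        out / "warfarin.xml",
    )
    return doc
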