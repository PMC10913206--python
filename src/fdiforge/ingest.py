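"""Ingest interaction records from drug-database exports.

Two source dialects are supported:

* an XML dump in which each drug carries a free-text ``food-interactions``
  field made of recommendation sentences
  (``<drugs><drug><drugbank-id>..</drugbank-id><name>..</name>
  <food-interactions><food-interaction>..</food-interaction>..</food-interactions></drug></drugs>``);
* a structured CSV of herb-drug interaction entries with header
  ``entry_id,plant_name,drug_name,mechanism_text,clinical_importance``.

Free text is segmented into sentences and each sentence is classified:
statements that assert the *absence* of an interaction (e.g. "Take with or
without food") are flagged non-interactions, and bare timing instructions
("Take on an empty stomach") are kept as interactions with a generic "food"
object.
"""
from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree


class IngestError(ValueError):
    """Unrecoverable input problem (malformed file, missing column)."""


@dataclass
class DrugRecord:
    """One source drug with its interaction-recommendation texts."""

    source_id: str  # CURIE-like, e.g. "DrugBank:DB00682"
    drug_name: str
    recommendations: list[str] = field(default_factory=list)
    source_tag: str = "drugbank"  # "drugbank" | "hedrine"

    @property
    def excluded(self) -> bool:
        """True when the record carries no interaction text at all."""
        return not self.recommendations


@dataclass
class HedrineRecord:
    entry_id: str
    plant_name: str
    drug_name: str
    mechanism_text: str | None = None
    clinical_importance: str | None = None


@dataclass
class InteractionSentence:
    record_id: str
    index: int  # 0-based within the record
    text: str
    is_interaction: bool
    generic_food_flag: bool  # timing-only sentence, annotated with generic "food"


#: Phrases whose presence marks a sentence as asserting *no* interaction.
DEFAULT_NON_INTERACTION_PHRASES: tuple[str, ...] = (
    "with or without food",
    "does not affect",
    "no effect on",
    "not affected by food",
    "no known interaction",
)

#: Timing-only instructions: an interaction with food in general, no named food.
DEFAULT_GENERIC_FOOD_PHRASES: tuple[str, ...] = (
    "empty stomach",
    "take with food",
    "take with a meal",
    "take with meals",
    "before meals",
    "after meals",
    "before a meal",
    "after a meal",
)

# sentence-final punctuation followed by whitespace and an uppercase opener
_SENTENCE_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z“\"'(])")


def parse_drugbank_xml(path: str | Path) -> list[DrugRecord]:
    """Parse a drug XML dump into records, one per ``<drug>`` element.

    Records whose ``food-interactions`` field is absent or empty are returned
    with an empty recommendation list (their ``excluded`` property is True);
    the caller filters them out of the interaction corpus.  A drug element
    without an identifier is collected into the raised error only if *no*
    record at all can be built; otherwise parsing continues and the offending
    elements are reported via the returned records' companion
    :func:`drugbank_parse_errors`.
    """
    records, _errors = _parse_drugbank(path)
    return records


def drugbank_parse_errors(path: str | Path) -> list[str]:
    """Record-level problems (e.g. missing drug id) found while parsing."""
    _records, errors = _parse_drugbank(path)
    return errors


def _parse_drugbank(path: str | Path) -> tuple[list[DrugRecord], list[str]]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IngestError(f"malformed XML in {path}: {exc}") from exc
    records: list[DrugRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for drug in tree.getroot().iterfind("drug"):
        drug_id = _text(drug.find("drugbank-id"))
        name = _text(drug.find("name"))
        if not drug_id:
            errors.append(
                f"drug element at line {drug.sourceline}: missing drugbank-id"
            )
            continue
        source_id = f"DrugBank:{drug_id}"
        if source_id in seen:
            errors.append(f"duplicate drug id {source_id}")
            continue
        seen.add(source_id)
        recs = [
            _text(fi)
            for fi in drug.iterfind("food-interactions/food-interaction")
            if _text(fi)
        ]
        records.append(DrugRecord(source_id, name, recs, "drugbank"))
    return records, errors


def _text(el) -> str:
    return (el.text or "").strip() if el is not None else ""


HEDRINE_COLUMNS = (
    "entry_id",
    "plant_name",
    "drug_name",
    "mechanism_text",
    "clinical_importance",
)


def parse_hedrine_csv(
    path: str | Path,
) -> tuple[list[HedrineRecord], list[str]]:
    """Parse a structured herb-drug CSV; returns (records, error report).

    Rows missing the plant or drug name are rejected into the error report
    rather than silently dropped.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return [], []
        missing = [c for c in HEDRINE_COLUMNS[:3] if c not in reader.fieldnames]
        if missing:
            raise IngestError(f"missing required column(s): {', '.join(missing)}")
        records: list[HedrineRecord] = []
        errors: list[str] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            entry_id = (row.get("entry_id") or "").strip()
            plant = (row.get("plant_name") or "").strip()
            drug = (row.get("drug_name") or "").strip()
            if not entry_id or not plant or not drug:
                errors.append(f"line {lineno}: missing entry_id/plant_name/drug_name")
                continue
            if entry_id in seen:
                errors.append(f"line {lineno}: duplicate entry_id {entry_id}")
                continue
            seen.add(entry_id)
            records.append(
                HedrineRecord(
                    entry_id,
                    plant,
                    drug,
                    (row.get("mechanism_text") or "").strip() or None,
                    (row.get("clinical_importance") or "").strip() or None,
                )
            )
    return records, errors


def segment_sentences(text: str) -> list[str]:
    """Deterministic sentence split on .!? followed by an uppercase opener."""
    text = text.strip()
    if not text:
        return []
    return [s for s in _SENTENCE_BOUNDARY.split(text) if s.strip()]


def classify_sentence(
    sentence: str,
    non_interaction_phrases: Sequence[str] = DEFAULT_NON_INTERACTION_PHRASES,
    generic_food_phrases: Sequence[str] = DEFAULT_GENERIC_FOOD_PHRASES,
) -> tuple[bool, bool]:
    """Return (is_interaction, generic_food_flag) for one sentence."""
    low = sentence.lower()
    if any(p in low for p in non_interaction_phrases):
        return False, False
    if any(p in low for p in generic_food_phrases):
        return True, True
    return True, False


def split_recommendations(
    record: DrugRecord,
    non_interaction_phrases: Sequence[str] = DEFAULT_NON_INTERACTION_PHRASES,
    generic_food_phrases: Sequence[str] = DEFAULT_GENERIC_FOOD_PHRASES,
) -> list[InteractionSentence]:
    """Segment and classify every recommendation of a record.

    Recommendation items are already list-item boundaries in the XML; each
    item is further segmented into sentences.  Every sentence receives a
    classification — nothing is dropped silently.
    """
    out: list[InteractionSentence] = []
    idx = 0
    for item in record.recommendations:
        for sent in segment_sentences(item):
            is_int, generic = classify_sentence(
                sent, non_interaction_phrases, generic_food_phrases
            )
            out.append(InteractionSentence(record.source_id, idx, sent, is_int, generic))
            idx += 1
    return out


def interaction_corpus(records: Iterable[DrugRecord]) -> list[DrugRecord]:
    """Records retained for compilation: non-empty interaction text.

    Input order is preserved (ids are unique within a corpus), which keeps
    downstream ID minting deterministic.
    """
    return [r for r in records if not r.excluded]


def write_corpus_jsonl(records: Iterable[DrugRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "source_id": r.source_id,
                        "drug_name": r.drug_name,
                        "recommendations": r.recommendations,
                        "source_tag": r.source_tag,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> list[DrugRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                records.append(
                    DrugRecord(
                        d["source_id"],
                        d["drug_name"],
                        list(d["recommendations"]),
                        d.get("source_tag", "drugbank"),
                    )
                )
    return records


def serialize_drugbank_xml(records: Iterable[DrugRecord], path: str | Path) -> None:
    """Write records back to the XML dialect (round-trip inverse of parse)."""
    root = etree.Element("drugs")
    for r in records:
        drug = etree.SubElement(root, "drug")
        etree.SubElement(drug, "drugbank-id").text = r.source_id.split(":", 1)[-1]
        etree.SubElement(drug, "name").text = r.drug_name
        if r.recommendations:
            fis = etree.SubElement(drug, "food-interactions")
            for item in r.recommendations:
                etree.SubElement(fis, "food-interaction").text = item
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )
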