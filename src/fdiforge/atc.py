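"""ATC-derived drug scaffold and placement of drugs, foods and herbs.

Only the first two ATC levels are used: level 1 (one letter, anatomical main
group) and level 2 (letter + two digits, therapeutic subgroup).  Class names
from the source table are normalized to ontology conventions (lower case,
singular head noun), level-1 names are reworded as "drug target of ...", and
every scaffold class carries a database cross-reference to its ATC code's
web page.  Drugs without any ATC code are parented under an intermediate
"not elsewhere classified drug" class.  Foods and FoodOn-mapped herbs hang
directly under "food product" (the intermediate food-ontology hierarchy is
flattened away); herbs that only resolve in the drug-product ontology hang
under "processed material".
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_CONFIG, KbConfig
from .mapping import MappingResult

ATC_URL = "https://www.whocc.no/atc_ddd_index/?code={code}"
NEC_LABEL = "not elsewhere classified drug"

_LEVEL1_RE = re.compile(r"^[A-V]$")
_LEVEL2_RE = re.compile(r"^[A-V][0-9]{2}$")

#: final tokens never singularized by s-stripping (mass nouns & latinate forms
#: are guarded structurally by the -ss/-us/-is endings check)
PLURAL_EXCEPTIONS = frozenset({"miscellaneous", "various"})


class AtcError(ValueError):
    pass


@dataclass(frozen=True)
class AtcEntry:
    code: str
    name: str

    @property
    def level(self) -> int:
        if _LEVEL1_RE.match(self.code):
            return 1
        if _LEVEL2_RE.match(self.code):
            return 2
        raise AtcError(f"code {self.code!r} is neither level 1 nor level 2")

    def validate(self) -> None:
        self.level  # raises on bad pattern
        if not self.name.strip():
            raise AtcError(f"code {self.code}: empty name")


@dataclass
class ConceptNode:
    """One class of the output knowledge base."""

    curie: str
    label: str
    parents: set[str] = field(default_factory=set)
    xrefs: set[str] = field(default_factory=set)
    node_kind: str = "scaffold"  # atc_class|drug|food|herb|fdi|source|scaffold

    def validate(self) -> None:
        if not self.label:
            raise AtcError(f"{self.curie}: empty label")
        if self.curie in self.parents:
            raise AtcError(f"{self.curie}: self-parenting")


def read_atc_tsv(path: str | Path) -> list[AtcEntry]:
    """Load ``code<TAB>name`` rows (levels 1-2)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AtcError(f"{path}:{lineno}: need code<TAB>name")
            entry = AtcEntry(parts[0].strip(), parts[1].strip())
            entry.validate()
            entries.append(entry)
    return entries


def read_drug_codes_tsv(path: str | Path) -> dict[str, set[str]]:
    """Load ``drug_term<TAB>code1|code2|...`` assignments of level-2 codes."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            codes = set(parts[1].split("|")) - {""} if len(parts) > 1 else set()
            out[parts[0].strip()] = codes
    return out


def _singularize(token: str) -> str:
    if token in PLURAL_EXCEPTIONS:
        return token
    if token.endswith(("ss", "us", "is")):
        return token
    if token.endswith("s") and len(token) > 2:
        return token[:-1]
    return token


LEVEL1_PREFIX = "drug target of "


def atc_label_normalize(entry: AtcEntry, renames: Mapping[str, str] | None = None) -> str:
    """Ontology-style label for an ATC class.

    Lower-cased; the head (final) noun is converted to singular; level-1
    anatomical-group names, which do not denote drug types, are reworded as
    "drug target of <name>".  Idempotent.  ``renames`` (code -> replacement
    label) overrides the rule for the handful of source names that are not
    drug-type phrases.
    """
    if renames and entry.code in renames:
        return renames[entry.code]
    name = re.sub(r"\s+", " ", entry.name.strip()).lower()
    tokens = name.split(" ")
    tokens[-1] = _singularize(tokens[-1])
    label = " ".join(tokens)
    if entry.level == 1 and not label.startswith(LEVEL1_PREFIX):
        label = LEVEL1_PREFIX + label
    return label


@dataclass
class Scaffold:
    """The drug/food upper structure: roots, ATC classes, the NEC class."""

    nodes: dict[str, ConceptNode]
    by_code: dict[str, str]  # ATC code -> scaffold CURIE
    nec_curie: str
    config: KbConfig

    def node_list(self) -> list[ConceptNode]:
        return list(self.nodes.values())


def build_atc_scaffold(
    entries: Sequence[AtcEntry],
    config: KbConfig = DEFAULT_CONFIG,
    renames: Mapping[str, str] | None = None,
) -> Scaffold:
    """Build the upper structure from ATC level-1/2 entries.

    One class per entry: level-2 classes are children of their level-1 class,
    level-1 classes children of the chemical-entity root; every ATC class
    carries an xref to its code's page.  A "not elsewhere classified drug"
    class under the root collects drugs with no ATC code.  IDs are minted
    deterministically in code sort order.
    """
    for e in entries:
        e.validate()
    codes = {e.code for e in entries}
    if len(codes) != len(entries):
        raise AtcError("duplicate ATC codes in input")
    for e in entries:
        if e.level == 2 and e.code[0] not in codes:
            raise AtcError(f"orphan level-2 code {e.code}: no level-1 entry {e.code[0]}")

    cfg = config
    nodes: dict[str, ConceptNode] = {}
    # fixed roots
    for curie, label, parents in (
        (cfg.material_entity, cfg.material_entity_label, set()),
        (cfg.chemical_entity, cfg.chemical_entity_label, {cfg.material_entity}),
        (cfg.food_product, cfg.food_product_label, {cfg.material_entity}),
        (cfg.processed_material, cfg.processed_material_label, {cfg.material_entity}),
    ):
        nodes[curie] = ConceptNode(curie, label, set(parents), set(), "scaffold")

    by_code: dict[str, str] = {}
    counter = cfg.scaffold_id_base
    for entry in sorted(entries, key=lambda e: e.code):
        curie = cfg.mint(counter)
        counter += 1
        parent = cfg.chemical_entity if entry.level == 1 else by_code[entry.code[0]]
        nodes[curie] = ConceptNode(
            curie,
            atc_label_normalize(entry, renames),
            {parent},
            {ATC_URL.format(code=entry.code)},
            "atc_class",
        )
        by_code[entry.code] = curie

    nec_curie = cfg.mint(counter)
    nodes[nec_curie] = ConceptNode(
        nec_curie, NEC_LABEL, {cfg.chemical_entity}, set(), "atc_class"
    )
    return Scaffold(nodes, by_code, nec_curie, cfg)


def place_drug(
    mapping: MappingResult, atc_codes: Iterable[str], scaffold: Scaffold
) -> ConceptNode:
    """Create the drug node, parented by its level-2 classes (or the
    not-elsewhere-classified class when it has no ATC code)."""
    if not mapping.mapped:
        raise AtcError(f"cannot place unmapped term {mapping.term!r}")
    codes = sorted(set(atc_codes))
    missing = [c for c in codes if c not in scaffold.by_code]
    if missing:
        raise AtcError(f"ATC code(s) absent from scaffold: {', '.join(missing)}")
    parents = {scaffold.by_code[c] for c in codes} or {scaffold.nec_curie}
    return ConceptNode(
        mapping.curie, mapping.label or mapping.term, parents, set(), "drug"
    )


def place_food_or_herb(mapping: MappingResult, scaffold: Scaffold) -> ConceptNode | None:
    """Create the food/herb node under its flattened parent.

    Foods and FoodOn-mapped herbs go directly under "food product"; herbs
    resolved only in the drug-product ontology go under "processed material".
    Unmapped terms yield None (caller logs).  A food with a drug-product-
    ontology hit violates the food cascade and is rejected.
    """
    if not mapping.mapped:
        return None
    cfg = scaffold.config
    if mapping.category == "food":
        if mapping.hit_ontology == "DRON":
            raise AtcError(
                f"food term {mapping.term!r} resolved in the drug-product "
                "ontology; the food cascade forbids this"
            )
        parent = cfg.food_product
        kind = "food"
    elif mapping.category == "herb":
        parent = (
            cfg.processed_material if mapping.hit_ontology == "DRON" else cfg.food_product
        )
        kind = "herb"
    else:
        raise AtcError(f"not a food/herb mapping: category {mapping.category!r}")
    return ConceptNode(mapping.curie, mapping.label or mapping.term, {parent}, set(), kind)


def check_acyclic(nodes: Iterable[ConceptNode]) -> list[str]:
    """Topological order of the parent graph; raises on cycles or dangling
    parents."""
    node_map = {n.curie: n for n in nodes}
    for n in node_map.values():
        for p in n.parents:
            if p not in node_map:
                raise AtcError(f"{n.curie}: parent {p} not in node set")
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(curie: str) -> None:
        st = state.get(curie, 0)
        if st == 1:
            raise AtcError(f"cycle through {curie}")
        if st == 2:
            return
        state[curie] = 1
        for p in sorted(node_map[curie].parents):
            visit(p)
        state[curie] = 2
        order.append(curie)

    for curie in sorted(node_map):
        visit(curie)
    return order
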