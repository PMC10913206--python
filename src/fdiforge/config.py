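"""Shared configuration: root concepts, relations, prefix map, ID minting.

Every anchor concept the knowledge base hangs off (the chemical-entity root
for drugs, the food-product root for foods, the interaction genus, ...) is a
plain config value so that a deployment can re-root the ontology without
touching code.
"""
from __future__ import annotations

from dataclasses import dataclass, field


#: Default CURIE prefix -> IRI namespace expansion.
DEFAULT_PREFIXES: dict[str, str] = {
    "FIDEO": "http://purl.obolibrary.org/obo/FIDEO_",
    "CHEBI": "http://purl.obolibrary.org/obo/CHEBI_",
    "FoodOn": "http://purl.obolibrary.org/obo/FOODON_",
    "DrOn": "http://purl.obolibrary.org/obo/DRON_",
    "RO": "http://purl.obolibrary.org/obo/RO_",
    "IAO": "http://purl.obolibrary.org/obo/IAO_",
    "BFO": "http://purl.obolibrary.org/obo/BFO_",
    "OBI": "http://purl.obolibrary.org/obo/OBI_",
    "oboInOwl": "http://www.geneontology.org/formats/oboInOwl#",
}

#: Relation used to attach the participating food to an interaction process.
HAS_PARTICIPANT = "RO:0000057"
#: Relation used to attach the affected drug (its state changes) to the process.
HAS_INPUT = "RO:0002233"
#: Relation from an information artifact (database page) to what it describes.
IS_ABOUT = "IAO:0000136"


@dataclass(frozen=True)
class KbConfig:
    """Anchor CURIEs and ID-minting policy for a knowledge-base build."""

    # root under which all drugs (and the ATC scaffold) live
    chemical_entity: str = "CHEBI:24431"
    chemical_entity_label: str = "chemical entity"
    # root for foods and FoodOn-mapped herbs; sits directly under material entity
    food_product: str = "FoodOn:00001002"
    food_product_label: str = "food product"
    material_entity: str = "BFO:0000040"
    material_entity_label: str = "material entity"
    # parent for herbs that only resolve in the drug ontology
    processed_material: str = "OBI:0000047"
    processed_material_label: str = "processed material"
    # genus of every precompiled interaction class
    fdi_genus: str = "FIDEO:000000001"
    fdi_genus_label: str = "food drug interaction"
    # parent of all provenance concepts
    source_root: str = "FIDEO:000000002"
    source_root_label: str = "information source for interaction"

    #: width of the zero-padded numeric part of minted FIDEO CURIEs
    id_width: int = 9
    #: first numeric ID for ATC scaffold classes
    scaffold_id_base: int = 100
    #: first numeric ID for precompiled interaction classes
    fdi_id_base: int = 2_000_000
    #: first numeric ID for provenance (source) concepts
    source_id_base: int = 6_000_000

    prefixes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFIXES))

    def mint(self, number: int) -> str:
        return f"FIDEO:{number:0{self.id_width}d}"


DEFAULT_CONFIG = KbConfig()
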