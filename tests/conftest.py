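import pytest

from fdiforge.atc import read_atc_tsv, read_drug_codes_tsv
from fdiforge.fixtures import FixtureSpec, generate, read_annotations_tsv
from fdiforge.ingest import parse_drugbank_xml, parse_hedrine_csv
from fdiforge.mapping import TermIndex
from fdiforge.owl import emit_owl
from fdiforge.pipeline import build_kb


def load_indexes(bundle_dir):
    return {
        o: TermIndex.from_tsv(o, bundle_dir / f"{o.lower()}.tsv")
        for o in ("CHEBI", "FOODON", "DRON")
    }


def run_pipeline(bundle_dir):
    db_records = parse_drugbank_xml(bundle_dir / "drugbank.xml")
    hed_records, errors = parse_hedrine_csv(bundle_dir / "hedrine.csv")
    assert not errors
    return build_kb(
        db_records,
        hed_records,
        read_annotations_tsv(bundle_dir / "annotations.tsv"),
        load_indexes(bundle_dir),
        read_atc_tsv(bundle_dir / "atc.tsv"),
        read_drug_codes_tsv(bundle_dir / "drug_codes.tsv"),
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seeded synthetic input bundle plus its construction-time truth."""
    out = tmp_path_factory.mktemp("bundle")
    truth = generate(FixtureSpec(seed=1), out)
    return out, truth


@pytest.fixture(scope="session")
def built(bundle):
    """Pipeline output (BuildResult) for the session bundle."""
    bundle_dir, truth = bundle
    return run_pipeline(bundle_dir), truth


@pytest.fixture(scope="session")
def kb(built):
    return built[0].kb


@pytest.fixture(scope="session")
def graph(kb, tmp_path_factory):
    out = tmp_path_factory.mktemp("owl") / "kb.ttl"
    return emit_owl(kb, out, "turtle")
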