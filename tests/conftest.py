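import pathlib

import pytest

from pgdbnotify.model import DbObject, Snapshot, read_snapshot

DATA = pathlib.Path(__file__).parent / "data"


def add_obj(snap: Snapshot, oid: str, types: list[str], slots: dict[str, list[str]] | None = None) -> DbObject:
    """Build one object from plain text values (no annotations)."""
    obj = snap.add(DbObject(oid))
    for t in types:
        obj.add_value("TYPES", t)
    for slot, values in (slots or {}).items():
        for v in values:
            obj.add_value(slot, v)
    return obj


@pytest.fixture
def fixture_a_path() -> str:
    return str(DATA / "fixture_a.dat")


@pytest.fixture
def fixture_a(fixture_a_path) -> Snapshot:
    return read_snapshot(fixture_a_path)


@pytest.fixture
def fixture_b() -> Snapshot:
    """Hand-built trp-operon-style neighborhood.

    trpA → TrpA monomer → TrpAB complex → enzymatic activity → reaction →
    pathway, with a regulation object on the complex and two substrate
    metabolites on the reaction.
    """
    s = Snapshot("ECOLI", "1.0")
    add_obj(s, "TRPA", ["GENE"], {"COMMON-NAME": ["trpA"], "PRODUCT": ["TRPA-MONOMER"], "CITATIONS": ["PMID:101"]})
    add_obj(s, "TRPA-MONOMER", ["PROTEIN"],
            {"COMMON-NAME": ["TrpA monomer"], "GENE": ["TRPA"], "COMPONENT-OF": ["TRPAB"]})
    add_obj(s, "TRPAB", ["PROTEIN", "COMPLEX"],
            {"COMMON-NAME": ["tryptophan synthase"], "COMPONENTS": ["TRPA-MONOMER"], "CATALYZES": ["ENZRXN-1"]})
    add_obj(s, "ENZRXN-1", ["ENZYMATIC-REACTION"], {"ENZYME": ["TRPAB"], "REACTION": ["RXN-1"]})
    add_obj(s, "RXN-1", ["REACTION"], {"LEFT": ["CPD-IGP"], "RIGHT": ["CPD-TRP"], "IN-PATHWAY": ["PWY-TRP"]})
    add_obj(s, "PWY-TRP", ["PATHWAY"],
            {"COMMON-NAME": ["tryptophan biosynthesis"], "REACTION-LIST": ["RXN-1"],
             "COMMENT": ["Mini-review for trp biosynthesis."]})
    add_obj(s, "REG-1", ["REGULATION"], {"REGULATED-ENTITY": ["TRPAB"]})
    add_obj(s, "CPD-IGP", ["COMPOUND"], {"COMMON-NAME": ["indole-3-glycerol-phosphate"]})
    add_obj(s, "CPD-TRP", ["COMPOUND"], {"COMMON-NAME": ["L-tryptophan"]})
    add_obj(s, "PUB-1", ["PUBLICATION"],
            {"PMID": ["101"], "AUTHORS": ["Yanofsky C"], "YEAR": ["1999"], "TITLE": ["The trp operon"]})
    s.validate()
    return s
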