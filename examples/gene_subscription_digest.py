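"""From a gene subscription to a rendered digest.

Builds a trp-operon-style neighborhood (gene → monomer → complex → activity
→ reaction → pathway, plus regulation), adds one citation to the enzyme
complex in the "new" release, and shows that a subscription to the *gene*
fires — the complex is in the gene's interest closure — producing one
markdown digest with links and the new publication.
"""

from pgdbnotify import (
    DbObject,
    Registry,
    Snapshot,
    Subscription,
    build_reports,
    render,
    run_notifications,
    subscribe,
)
from pgdbnotify.synth import copy_snapshot


def obj(s: Snapshot, oid: str, types: list[str], **slots: list[str]) -> DbObject:
    o = s.add(DbObject(oid))
    for t in types:
        o.add_value("TYPES", t)
    for slot, values in slots.items():
        for v in values:
            o.add_value(slot.replace("_", "-"), v)
    return o


def main() -> None:
    old = Snapshot("ECOLI", "27.0")
    obj(old, "TRPA", ["GENE"], COMMON_NAME=["trpA"], PRODUCT=["TRPA-MONOMER"])
    obj(old, "TRPA-MONOMER", ["PROTEIN"], GENE=["TRPA"], COMPONENT_OF=["TRPAB"])
    obj(old, "TRPAB", ["PROTEIN", "COMPLEX"], COMMON_NAME=["tryptophan synthase"],
        COMPONENTS=["TRPA-MONOMER"], CATALYZES=["ENZRXN-1"])
    obj(old, "ENZRXN-1", ["ENZYMATIC-REACTION"], REACTION=["RXN-1"])
    obj(old, "RXN-1", ["REACTION"], IN_PATHWAY=["PWY-TRP"])
    obj(old, "PWY-TRP", ["PATHWAY"], COMMON_NAME=["tryptophan biosynthesis"], REACTION_LIST=["RXN-1"])
    obj(old, "REG-1", ["REGULATION"], REGULATED_ENTITY=["TRPAB"])
    obj(old, "PUB-9", ["PUBLICATION"], PMID=["555"], AUTHORS=["Curator A"],
        YEAR=["2017"], TITLE=["New structure of tryptophan synthase"])

    new = copy_snapshot(old)
    new.version = "27.5"
    new.objects["TRPAB"].add_value("CITATIONS", "PMID:555")

    registry = subscribe(Registry(), Subscription("biologist@example.org", "ECOLI", "GENE", "TRPA", "NONE"))
    items = run_notifications(registry, old, new)
    print(f"{len(items)} subscription(s) fired; triggers: {sorted(items[0].trigger_ids)}\n")
    # The gene object itself is untouched: the new citation sits on the
    # complex, which the gene's closure covers.

    reports = build_reports(
        items,
        url_template="https://biocyc.example.org/{db}/object/{id}",
        manage_url="https://biocyc.example.org/manage-notifications",
        snapshot=new,
        old_version=old.version,
    )
    print(render(reports[0], "markdown"))


if __name__ == "__main__":
    main()
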