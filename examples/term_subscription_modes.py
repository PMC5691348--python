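"""The two ontology-term subscription modes.

A small GO DAG with the true-path rule: annotating a gene to a child term
makes it a member of the parent term too.  NEW-MEMBERS fires on membership
growth alone; MEMBER-CHANGES applies the citation criterion to every
current member gene.
"""

from pgdbnotify import DbObject, Snapshot, Subscription, diff_snapshot, evaluate_term
from pgdbnotify.synth import copy_snapshot


def main() -> None:
    old = Snapshot("ECOLI", "27.0")

    def obj(s, oid, types, **slots):
        o = s.add(DbObject(oid))
        for t in types:
            o.add_value("TYPES", t)
        for slot, values in slots.items():
            for v in values:
                o.add_value(slot.replace("_", "-"), v)

    obj(old, "GO:0001906", ["GO-TERM"], COMMON_NAME=["cell killing"])
    obj(old, "GO:0031640", ["GO-TERM"], COMMON_NAME=["killing of cells of another organism"],
        PARENTS=["GO:0001906"])
    obj(old, "G1", ["GENE"], GO_TERMS=["GO:0031640"])
    obj(old, "G2", ["GENE"])

    new = copy_snapshot(old)
    new.version = "27.5"
    # a curator annotates G2 to the child term and adds evidence to G1
    new.objects["G2"].add_value("GO-TERMS", "GO:0031640")
    new.objects["G1"].add_value("CITATIONS", "PMID:31415")

    d = diff_snapshot(old, new)
    for mode in ("NEW-MEMBERS", "MEMBER-CHANGES"):
        sub = Subscription("biologist@example.org", "ECOLI", "GO-TERM", "GO:0001906", mode)
        item = evaluate_term(sub, old, new, d)
        if item is None:
            print(f"{mode}: silent")
        else:
            print(f"{mode}: fired — new members {sorted(item.new_members) or '-'}, "
                  f"triggers {sorted(item.trigger_ids) or '-'}")
    # NEW-MEMBERS reports G2 joining the parent term (true-path rule);
    # MEMBER-CHANGES reports G1, whose record gained a citation.


if __name__ == "__main__":
    main()
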