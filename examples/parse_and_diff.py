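"""Parse two releases of a tiny attribute-value flatfile and diff them.

Writes a two-record database, edits it the way a curator would (one typo
fix, one new citation), and prints the classified slot-level differences.
"""

import tempfile

from pgdbnotify import diff_snapshot, read_snapshot

OLD = """\
UNIQUE-ID - TRPA
TYPES - GENE
COMMON-NAME - trpa
PRODUCT - TRPA-MONOMER
CITATIONS - PMID:101
//
UNIQUE-ID - TRPA-MONOMER
TYPES - PROTEIN
GENE - TRPA
//
"""

# the typo "trpa" is fixed and a newly curated publication is attached
NEW = OLD.replace("COMMON-NAME - trpa", "COMMON-NAME - trpA").replace(
    "CITATIONS - PMID:101", "CITATIONS - PMID:101\nCITATIONS - PMID:202"
)


def main() -> None:
    with tempfile.TemporaryDirectory() as tmp:
        for name, text in (("old.dat", OLD), ("new.dat", NEW)):
            with open(f"{tmp}/{name}", "w") as fh:
                fh.write(text)
        old = read_snapshot(f"{tmp}/old.dat", "ECOLI", "27.0")
        new = read_snapshot(f"{tmp}/new.dat", "ECOLI", "27.5")

    d = diff_snapshot(old, new)
    for obj_id, od in d.diffs.items():
        print(f"{obj_id}: {od.status}, new citations: {sorted(od.new_citations) or 'none'}")
        for sd in od.slot_diffs:
            print(f"  [{sd.category}] +{sd.added} -{sd.removed}")
    # Only PMID:202 counts as new evidence; the typo fix is a visible diff
    # but carries no citation, so it would not trigger a notification.


if __name__ == "__main__":
    main()
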