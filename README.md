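# pgdbnotify

Citation-triggered update notifications for curated pathway/genome databases
(PGDBs) such as the BioCyc family.  Curated databases are re-released
periodically, and a researcher who cares about a handful of genes or
pathways has no practical way to learn which of the thousands of record
edits in a new release actually concern them.  `pgdbnotify` is the engine
for closing that loop: given two releases of a database and a registry of
user subscriptions, it decides which subscriptions warrant notification and
renders one concise, linked digest per user per database.

## The method

**Subscriptions.**  Users register interest in specific **genes** or
**pathways**, or in **GO terms** and **pathway classes**.  A gene or pathway
designation implicitly covers its *interest closure* — for a gene *g*: its
product, complexes containing the product (transitively), enzymatic
activities of product or complexes, the activities' reactions, pathways
containing those reactions, every regulation object acting on any member,
and transcription units containing *g*.  For a pathway: its reactions
(sub-pathways expanded recursively), their metabolites, catalyzing
activities, the enzymes behind them down to monomers, those monomers'
genes, and regulation of any member.  Term subscriptions carry a mode:
*new-members* (fire when the term's member set grows, with GO membership
propagated through the is-a DAG by the true-path rule) or *member-changes*
(apply the gene/pathway criterion to every current member).

**Significance filter.**  Between releases an object changes for many
reasons — typo fixes, rewordings, merges of redundant frames, consistency
repairs — most of which readers do not want mail about.  The filter exploits
a curation invariant: significant changes are always accompanied by a
citation, attached either to the changed attribute or to the object as a
whole.  A subscription anchored at object *a* fires iff

&nbsp;&nbsp;&nbsp;&nbsp;∃ *m* ∈ closure(*a*) : cit_new(*m*) ∖ (cit_old(*m*) ∪ cit_merged(*m*)) ≠ ∅

where cit(*m*) is the set of normalized publication keys on *m* at any
level, and cit_merged subtracts citations inherited from frames merged into
*m*.  Merges, deletions, typo edits and annotation removals therefore never
fire.  Once an anchor fires, *all* differences on its closure members are
collected for the digest, since the specific fields behind a new citation
are generally unknowable.

**Input format.**  Releases are read from the attribute-value flatfile
dialect used by Pathway Tools-style `.dat` exports (records of slots with
per-value annotations); merge provenance is a `MERGED-FROM` slot on the
surviving frame.  The subscription registry is a plain TSV.

## Worked example

`examples/gene_subscription_digest.py` builds a trp-operon-style
neighborhood, adds one citation to the enzyme *complex* in the new release,
and evaluates a subscription to the *gene*:

```
1 subscription(s) fired; triggers: ['TRPAB']

# Update notifications: ECOLI (release 27.0 → 27.5)

## Gene: [trpA](https://biocyc.example.org/ECOLI/object/TRPA)

- Changed: [tryptophan synthase](https://biocyc.example.org/ECOLI/object/TRPAB) — citations

New publications:

- [Curator A 2017: New structure of tryptophan synthase (PMID:555)](https://biocyc.example.org/ECOLI/object/PUB-9)

[Manage your notification subscriptions](https://biocyc.example.org/manage-notifications)
```

The gene record itself never changed: the subscription fired because the
complex `TRPAB` lies in `trpA`'s interest closure and gained publication
`PMID:555`, which was absent from the previous release.  The digest links
the anchor and each changed related object, names the change categories
(here: citations), lists the new publications, and carries a manage link.

Other examples: `examples/parse_and_diff.py` (flatfile parsing and
classified diffs), `examples/term_subscription_modes.py` (the two GO-term
modes), `examples/synthetic_release_pair.py` (seeded fixture generation
checked against the brute-force oracle).

## Command line

```bash
pgdb-notify gen-fixture --seed 3 --edits 8 --out-old old.dat --out-new new.dat --truth truth.json
pgdb-notify subscribe --registry reg.tsv --user u@example.org --database SYNDB --kind GENE --target G0001
pgdb-notify diff --old old.dat --new new.dat --out diff.json
pgdb-notify notify --old old.dat --new new.dat --registry reg.tsv --outdir reports/
```

`notify` exits 0 with "0 reports" when nothing fires; parse and validation
errors exit 2 and name the offending file line or registry row.

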