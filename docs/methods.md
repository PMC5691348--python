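# Methods

## Problem setting

A curated pathway/genome database (PGDB) is an object database whose frames
describe genes, gene products, protein complexes, enzymatic activities,
reactions, metabolites, pathways, regulation, transcription units,
publications, and two ontologies (a GO DAG annotating genes; a pathway-class
hierarchy typing pathways).  Releases appear periodically; between releases
curators and programmatic updates touch many frames.  The engine's job is to
decide, per user subscription, whether the changes in a new release are
significant enough to notify about, and to say so concisely.

## Data model and flatfile dialect

A `Snapshot` is one release: a database id, a version label, and an ordered
map of `DbObject`s.  An object is an id plus ordered slots; each slot holds
an ordered list of values, and each value can carry per-value annotations
(uppercase label → list of strings).  Classes are the values of the `TYPES`
slot.  Serialization uses an attribute-value dialect modeled on Pathway
Tools `.dat` exports: `UNIQUE-ID - <id>` opens a record, `//` closes it,
`SLOT - value` lines repeat to accumulate values, `^LABEL - value` annotates
the most recent value, `/text` continues it.  The reader/writer pair
round-trips the model exactly (object set, class lists, slot and value
order, annotations, merge provenance); byte-identity of hand-authored
comments is explicitly not a goal.  Encoding is UTF-8 with LF newlines, and
slot-value comparison downstream is exact (case- and whitespace-sensitive),
so a typo fix is visible as a diff yet correctly non-triggering.

Merge provenance is an explicit `MERGED-FROM` slot on the surviving frame.
Provenance cannot be inferred from ids after the fact, and without it a
merge — which unions the sources' citations into the survivor — would be
indistinguishable from genuinely new evidence.

## Citation identity

A citation token may carry qualifiers after `:` separators (evidence codes,
curator tags).  The normalized key is the token's prefix before the first
`:`, except `PMID:<digits>` accessions which keep their prefix; keys are
uppercased and stripped of surrounding brackets/whitespace, and
normalization is idempotent.  The trigger is the *publication*, not its
evidence annotation, so qualifiers are deliberately ignored; a citation that
merely moves between attributes of one object is likewise not new, because
an object's citation set unions the object level and every value level.

## Interest closures

Closure traversal is a fixed point over a configurable relation set
(`src/pgdbnotify/data/relations.yaml`; an alternative YAML can be supplied
to remap slot names for schema variants).  Gene rules: gene→`PRODUCT`;
protein/complex→`COMPONENT-OF` (complexes of complexes expand because the
fixed point re-applies rules to new members); protein/complex→`CATALYZES`;
activity→`REACTION`; reaction→`IN-PATHWAY`; plus, in reverse, every
`REGULATION` whose `REGULATED-ENTITY` names any member, and every
`TRANSCRIPTION-UNIT` whose `GENES` slot names the anchor gene (regulation of
that unit then joins at the next iteration).  Pathways reached from a gene
are members but not expansion roots — expanding them would make one gene
subscription cover most of the database.  Pathway rules: pathway→
`REACTION-LIST` (sub-pathways recurse), reaction→`LEFT`/`RIGHT`, activities
catalyzing member reactions, enzymes behind those activities, complexes
broken down via `COMPONENTS` to monomers, monomers→`GENE`, and regulation of
any member.  Regulation membership is by regulated entity only; the
regulator and its own neighborhood stay out.

The engine builds one reverse index per snapshot (slot → value → holders),
so evaluating hundreds of subscriptions over a large release is linear in
practice.  Traversal is breadth-first over sorted frontiers: deterministic,
and cycle-safe by construction (membership is checked before expansion, so
component-of cycles terminate).  Provenance records the first discovered
relation path from the anchor to each member.

GO-term membership applies the true-path rule: genes annotated to the term
or any descendant in the is-a DAG (`PARENTS` links) are members.  The
engine propagates annotations through the DAG because an annotation to a
child is, biologically, an annotation to the parent; membership queries on
a cyclic `PARENTS` graph raise an ontology error.  Pathway-class membership
follows each pathway's `TYPES` into the class hierarchy's `PARENTS` chain.

## Diffing and the significance filter

Slots are compared as multisets of (text, annotations) pairs: order changes
alone are not diffs, reworded values appear as remove+add (no fuzzy
matching — triggering never depends on diff granularity, only on
citations).  Each changed object carries `new_citations` = citations(new) ∖
citations(old) ∖ ⋃ citations(merge sources).  The merge subtraction applies
whenever the new frame is a merge target, whether the survivor pre-existed
or is a fresh frame; this is what makes merges silent.  Removed frames are
retained in the snapshot diff (status `REMOVED`, or `MERGED-AWAY` when the
new release's merge map names them) for report completeness, but can never
trigger.

A gene/pathway subscription fires iff some member of the anchor's closure —
computed on the **new** snapshot, since current structure defines current
interests — has non-empty `new_citations`.  A brand-new object with no
citations never triggers.  `NEW-MEMBERS` term mode fires on membership
growth alone (the membership change *is* the subscribed event; it does not
additionally require a citation); annotation removals never fire.
`MEMBER-CHANGES` composes the gene/pathway criterion over all current
members.  A subscription whose anchor was merged away or deleted yields a
logged warning, not a firing.

Change categories shown to readers come from a configurable slot→category
map (`COMMENT` → "textual summary", `GO-TERMS` → "GO term annotations",
regulation slots → "regulation", …; unmapped slots render as their lowercase
name).  The report module reuses this map verbatim so wording cannot drift
from classification.

## Reports

All fired items of one (user, database) pair form one digest.  Markdown is
canonical; HTML is emitted from the same block structure, guaranteeing
identical link targets and visible strings.  Per item: a linked anchor
heading, one linked line per changed closure member with its categories; a
member already rendered under an earlier item of the same digest collapses
into a single "also changed (listed above)" line.  New publications are
listed once per digest, resolved against `PUBLICATION` frames ("Authors
Year: Title (PMID)") or shown as the raw key; removed/merged-away members
are named without links.  The footer is the manage/unsubscribe link.  No
timestamps appear in report bodies, so outputs are byte-deterministic and
invariant under permutations of registry row order.  A regression guard
keeps a digest with k items and m distinct changed members within
10 + 4k + 3m non-blank lines.

## Synthetic fixtures and ground truth

`generate_base(params, seed)` emulates a miniature release: defaults are 8
genes (monomer each; 60% carry a complex chain of depth ≤ 2, occasionally
sharing a monomer with another gene's complex; 90% an activity+reaction
wired into a pathway; 40% a transcription unit; 50% a regulation object),
3 pathways (the second nested inside the first), an 8-term GO DAG with 1–2
parents per term and 1–2 annotations per gene, a pathway-class tree, a
publication pool (1–2 citations per gene, half qualified with evidence
codes, occasionally attribute-level), 10 metabolites, and 4 unreferenced
"orphan" proteins that serve as merge/deletion fodder so reference rewiring
is never needed.  Acceptance-scale runs use 18 genes (≈190 objects); the
scale check uses 1550 genes (≥10,000 objects) with 504 subscriptions —
sizes chosen so every structural path is exercised while a full run of the
suite stays fast.

Edit scripts draw from nine kinds mirroring real curation events.  Targets
are sampled without replacement (conflicting edits on one object are a
script error), and typos are confined to `COMMON-NAME` values: a "typo"
inside a citation token would mint a new publication key, which is not a
typo edit but a citation event.  Ground truth — the changed-id set and the
exact subscriptions that must fire — is computed by `oracle.py`, which
re-derives closures, term membership and triggering with naive
rescan-until-stable loops and inline slot names, sharing no code with the
closure/diff/notify modules.

What the generator does **not** emulate: realistic curation rates, schema
drift between releases, frame renames without merge provenance, citation
formats beyond `key[:qualifier…]` tokens, and multi-database registries
against real content.  Passing tests therefore demonstrate the engine's
logic (triggering, exclusions, closures, determinism), not its behavior on
any particular production database export.

## Numerical and design choices

- Determinism everywhere: sorted iteration orders, a single integer seed per
  generated artifact, no wall-clock values in outputs.
- Subscriptions may dangle (target absent from a release): warning, not
  error, because ids are legitimately merged away between releases.
- One evaluation per subscription entry even when member sets overlap;
  de-duplication happens at rendering.
- A user may hold both term modes for the same term (distinct entries).
- Registry persistence is TSV (diff-able, spreadsheet-editable); bulk
  subscription reads a plain one-id-per-line file.
- CLI exit codes: 0 success (including "nothing fired"), 1 usage,
  2 parse/validation.

## Known limitations

- No fuzzy matching of reworded text; a rewritten summary shows as
  remove+add in diffs.
- Whether a citation moved between two *different* objects counts as new is
  decided per object (it does, on the receiving object).
- Substrate-level regulation pulls in the regulation object but not the
  regulating metabolite's neighborhood.
- The flatfile reader targets the dialect described above, not full
  Pathway Tools schema fidelity (no Lisp-expression values).
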