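"""Seeded synthetic fixtures: base snapshots, edit scripts, ground truth.

The generator emulates the object inventory a small curated pathway/genome
database release contains: genes with products, protein complexes (nested up
to a configurable depth), enzymatic activities, reactions with substrate
metabolites, pathways (with one nested sub-pathway when possible),
transcription units, regulation objects, publications, a GO DAG with gene
annotations, and a pathway-class tree.  Edit scripts mirror the taxonomy of
curation events between releases: citation additions (object- or
attribute-level), typo fixes, summary rewordings, object merges with
citation union, deletions, GO-annotation additions/removals, and brand-new
objects with or without citations.

Everything is driven by a single integer seed; the same seed reproduces the
same snapshot byte-for-byte.  ``apply_script`` also returns ground truth —
the changed-object ids and (given a registry) the exact subscriptions that
must fire, computed by the independent brute-force oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import oracle
from .errors import ScriptError
from .model import DbObject, SlotValue, Snapshot, citations_of, normalize_citation
from .subscriptions import Registry, Subscription

EDIT_KINDS = (
    "ADD-CITATION",
    "TYPO",
    "REWORD-SUMMARY",
    "MERGE",
    "DELETE-OBJECT",
    "ADD-GO-ANNOTATION",
    "REMOVE-GO-ANNOTATION",
    "NEW-OBJECT-WITH-CITATION",
    "NEW-OBJECT-NO-CITATION",
)

#: edit kinds that by design never produce a notification on their own
EXCLUSION_KINDS = ("TYPO", "REWORD-SUMMARY", "MERGE", "DELETE-OBJECT", "REMOVE-GO-ANNOTATION")


@dataclass
class BaseParams:
    n_genes: int = 8
    complex_depth: int = 2
    n_pathways: int = 3
    n_terms: int = 8
    n_compounds: int = 10
    n_orphans: int = 4


@dataclass(frozen=True)
class Edit:
    kind: str
    targets: tuple[str, ...]
    payload: tuple = ()


@dataclass
class EditScript:
    seed: int
    edits: list[Edit] = field(default_factory=list)


@dataclass
class TruthLog:
    """What a correct engine must report for an (old, new) pair."""

    changed_ids: set[str] = field(default_factory=set)
    fired: set[Subscription] | None = None


def generate_base(params: BaseParams | None = None, seed: int = 0) -> Snapshot:
    """Deterministic schema-valid snapshot; same seed, same snapshot."""
    p = params or BaseParams()
    if min(p.n_genes, p.n_pathways, p.n_terms, p.n_compounds) < 1:
        raise ScriptError("all base counts must be positive")
    rng = random.Random(seed)
    s = Snapshot("SYNDB", "1.0")

    n_pubs = p.n_genes + 4
    pubs = []
    for i in range(1, n_pubs + 1):
        pub = s.add(DbObject(f"PUB-{i:04d}"))
        pub.add_value("TYPES", "PUBLICATION")
        pub.add_value("PMID", str(100000 + i))
        pub.add_value("AUTHORS", f"Researcher {chr(65 + i % 26)}")
        pub.add_value("YEAR", str(2000 + i % 20))
        pub.add_value("TITLE", f"Curated study {i} of a synthetic metabolic system")
        pubs.append(pub)

    def pub_token(pub: DbObject, qualified: bool) -> str:
        pmid = pub.first_value("PMID")
        return f"PMID:{pmid}:EV-EXP-IDA" if qualified else f"PMID:{pmid}"

    terms = []
    for i in range(1, p.n_terms + 1):
        term = s.add(DbObject(f"GO:{i:07d}"))
        term.add_value("TYPES", "GO-TERM")
        term.add_value("COMMON-NAME", f"synthetic process {i}")
        if i > 1:
            for parent in rng.sample(terms, min(len(terms), rng.randint(1, 2))):
                term.add_value("PARENTS", parent.id)
        terms.append(term)

    root = s.add(DbObject("PWY-CLASS-ROOT"))
    root.add_value("TYPES", "PATHWAY-CLASS")
    root.add_value("COMMON-NAME", "Pathways")
    classes = [root]
    for i in range(1, max(3, p.n_pathways) + 1):
        cls = s.add(DbObject(f"PWY-CLASS-{i:04d}"))
        cls.add_value("TYPES", "PATHWAY-CLASS")
        cls.add_value("COMMON-NAME", f"pathway class {i}")
        cls.add_value("PARENTS", (classes[0] if i <= 2 else rng.choice(classes[1:])).id)
        classes.append(cls)

    compounds = []
    for i in range(1, p.n_compounds + 1):
        cpd = s.add(DbObject(f"CPD-{i:04d}"))
        cpd.add_value("TYPES", "COMPOUND")
        cpd.add_value("COMMON-NAME", f"metabolite-{i}")
        compounds.append(cpd)

    pathways = []
    for i in range(1, p.n_pathways + 1):
        pwy = s.add(DbObject(f"PWY-{i:04d}"))
        pwy.add_value("TYPES", "PATHWAY")
        pwy.add_value("TYPES", rng.choice(classes[1:]).id)
        pwy.add_value("COMMON-NAME", f"synthetic pathway {i}")
        pwy.add_value("COMMENT", f"Mini-review summary for pathway {i}.")
        pathways.append(pwy)
    if p.n_pathways >= 2:
        # one nested sub-pathway so recursive expansion is always exercised
        pathways[0].add_value("REACTION-LIST", pathways[1].id)

    monomers: list[DbObject] = []
    for i in range(1, p.n_genes + 1):
        gene = s.add(DbObject(f"G{i:04d}"))
        gene.add_value("TYPES", "GENE")
        name_sv = gene.add_value("COMMON-NAME", f"gene{i}")
        gene.add_value("PRODUCT", f"G{i:04d}-MONOMER")
        gene.add_value("COMMENT", f"Mini-review summary for gene{i}.")
        for pub in rng.sample(pubs, rng.randint(1, 2)):
            gene.add_value("CITATIONS", pub_token(pub, rng.random() < 0.5))
        if rng.random() < 0.3:
            name_sv.annotations["CITATIONS"] = [pub_token(rng.choice(pubs), False)]
        for term in rng.sample(terms, rng.randint(1, 2)):
            gene.add_value("GO-TERMS", term.id)

        mono = s.add(DbObject(f"G{i:04d}-MONOMER"))
        mono.add_value("TYPES", "PROTEIN")
        mono.add_value("COMMON-NAME", f"Gene{i} monomer")
        mono.add_value("GENE", gene.id)
        if rng.random() < 0.4:
            mono.add_value("CITATIONS", pub_token(rng.choice(pubs), rng.random() < 0.5))
        monomers.append(mono)

        enzyme = mono
        if rng.random() < 0.6:
            depth = rng.randint(1, p.complex_depth)
            below: DbObject = mono
            for level in range(1, depth + 1):
                cplx = s.add(DbObject(f"CPLX-{i:04d}-{level}"))
                cplx.add_value("TYPES", "PROTEIN")
                cplx.add_value("TYPES", "COMPLEX")
                cplx.add_value("COMMON-NAME", f"complex {i}.{level}")
                cplx.add_value("COMPONENTS", below.id)
                if level == 1 and len(monomers) > 1 and rng.random() < 0.4:
                    other = rng.choice(monomers[:-1])
                    cplx.add_value("COMPONENTS", other.id)
                    other.add_value("COMPONENT-OF", cplx.id)
                below.add_value("COMPONENT-OF", cplx.id)
                below = cplx
            enzyme = below

        if rng.random() < 0.9:
            enzrxn = s.add(DbObject(f"ENZRXN-{i:04d}"))
            enzrxn.add_value("TYPES", "ENZYMATIC-REACTION")
            enzrxn.add_value("COMMON-NAME", f"activity of gene{i} product")
            enzrxn.add_value("ENZYME", enzyme.id)
            enzrxn.add_value("REACTION", f"RXN-{i:04d}")
            enzyme.add_value("CATALYZES", enzrxn.id)

            rxn = s.add(DbObject(f"RXN-{i:04d}"))
            rxn.add_value("TYPES", "REACTION")
            left, right = rng.sample(compounds, 2)
            rxn.add_value("LEFT", left.id)
            rxn.add_value("RIGHT", right.id)
            pwy = rng.choice(pathways)
            rxn.add_value("IN-PATHWAY", pwy.id)
            pwy.add_value("REACTION-LIST", rxn.id)

        tu = None
        if rng.random() < 0.4:
            tu = s.add(DbObject(f"TU-{i:04d}"))
            tu.add_value("TYPES", "TRANSCRIPTION-UNIT")
            tu.add_value("COMMON-NAME", f"transcription unit {i}")
            tu.add_value("GENES", gene.id)

        if rng.random() < 0.5:
            reg = s.add(DbObject(f"REG-{i:04d}"))
            reg.add_value("TYPES", "REGULATION")
            reg.add_value("COMMON-NAME", f"regulation {i}")
            entity = rng.choice([e for e in (mono, enzyme, tu) if e is not None])
            reg.add_value("REGULATED-ENTITY", entity.id)
            reg.add_value("REGULATOR", rng.choice(monomers).id)
            if rng.random() < 0.5:
                reg.add_value("CITATIONS", pub_token(rng.choice(pubs), False))

    # unreferenced duplicates: merge/delete fodder for edit scripts
    for i in range(1, p.n_orphans + 1):
        orphan = s.add(DbObject(f"ORPHAN-{i:04d}"))
        orphan.add_value("TYPES", "PROTEIN")
        orphan.add_value("COMMON-NAME", f"uncharacterized protein {i}")
        orphan.add_value("CITATIONS", pub_token(rng.choice(pubs), False))

    s.validate()
    return s


def copy_snapshot(s: Snapshot) -> Snapshot:
    objects = {
        oid: DbObject(
            oid,
            {
                slot: [SlotValue(sv.value, {k: list(v) for k, v in sv.annotations.items()}) for sv in values]
                for slot, values in obj.slots.items()
            },
        )
        for oid, obj in s.objects.items()
    }
    return Snapshot(s.database_id, s.version, objects)


def _touched(edit: Edit) -> set[str]:
    if edit.kind in ("NEW-OBJECT-WITH-CITATION", "NEW-OBJECT-NO-CITATION"):
        return {edit.targets[0]}  # only the created id changes
    return set(edit.targets)


def apply_script(
    old: Snapshot,
    script: EditScript,
    registry: Registry | None = None,
) -> tuple[Snapshot, TruthLog]:
    """Apply an edit script; returns the new release plus ground truth.

    Ground truth is derived by the brute-force oracle, never by the engine
    under test.  Conflicting edits (two edits touching one object) raise
    :class:`ScriptError`.
    """
    new = copy_snapshot(old)
    new.version = old.version + "+edits"
    truth = TruthLog()

    for edit in script.edits:
        overlap = truth.changed_ids & _touched(edit)
        if overlap:
            raise ScriptError(f"conflicting edits on {sorted(overlap)}")
        for target in edit.targets:
            missing = target not in new.objects
            if edit.kind in ("NEW-OBJECT-WITH-CITATION", "NEW-OBJECT-NO-CITATION"):
                if target == edit.targets[0] and not missing:
                    raise ScriptError(f"new-object id {target} already exists")
                if target != edit.targets[0] and missing:
                    raise ScriptError(f"edit {edit.kind} references missing object {target}")
            elif missing:
                raise ScriptError(f"edit {edit.kind} targets missing object {target}")

        if edit.kind == "ADD-CITATION":
            (token, level) = edit.payload
            obj = new.objects[edit.targets[0]]
            if level == "attribute":
                slot = next(
                    (sl for sl in obj.slots if sl not in ("CITATIONS", "TYPES")),
                    next(sl for sl in obj.slots),
                )
                obj.slots[slot][0].annotations.setdefault("CITATIONS", []).append(token)
            else:
                obj.add_value("CITATIONS", token)
        elif edit.kind == "TYPO":
            obj = new.objects[edit.targets[0]]
            sv = obj.slots["COMMON-NAME"][0]
            sv.value = sv.value[:-1] + ("x" if sv.value[-1] != "x" else "y")
        elif edit.kind == "REWORD-SUMMARY":
            obj = new.objects[edit.targets[0]]
            obj.slots["COMMENT"][0].value = f"Reworded mini-review text for {obj.id}."
        elif edit.kind == "MERGE":
            loser_id, survivor_id = edit.targets
            loser = new.objects[loser_id]
            survivor = new.objects[survivor_id]
            for key in sorted(citations_of(loser) - citations_of(survivor)):
                survivor.add_value("CITATIONS", key)
            survivor.add_value("MERGED-FROM", loser_id)
            del new.objects[loser_id]
        elif edit.kind == "DELETE-OBJECT":
            del new.objects[edit.targets[0]]
        elif edit.kind == "ADD-GO-ANNOTATION":
            gene_id, term_id = edit.targets[0], edit.payload[0]
            new.objects[gene_id].add_value("GO-TERMS", term_id)
        elif edit.kind == "REMOVE-GO-ANNOTATION":
            gene_id, term_id = edit.targets[0], edit.payload[0]
            values = new.objects[gene_id].slots.get("GO-TERMS", [])
            kept = [sv for sv in values if sv.value != term_id]
            if len(kept) == len(values):
                raise ScriptError(f"{gene_id} carries no annotation to {term_id}")
            if kept:
                new.objects[gene_id].slots["GO-TERMS"] = kept
            else:
                del new.objects[gene_id].slots["GO-TERMS"]
        elif edit.kind in ("NEW-OBJECT-WITH-CITATION", "NEW-OBJECT-NO-CITATION"):
            new_id, entity_id = edit.targets
            reg = new.add(DbObject(new_id))
            reg.add_value("TYPES", "REGULATION")
            reg.add_value("COMMON-NAME", f"new regulation of {entity_id}")
            reg.add_value("REGULATED-ENTITY", entity_id)
            if edit.kind == "NEW-OBJECT-WITH-CITATION":
                reg.add_value("CITATIONS", edit.payload[0])
        else:
            raise ScriptError(f"unknown edit kind {edit.kind}")
        truth.changed_ids |= _touched(edit)

    new.validate()
    if registry is not None:
        truth.fired = oracle.expected_firings(registry, old, new)
    return new, truth


def random_script(
    base: Snapshot,
    seed: int,
    n_edits: int = 6,
    kinds: tuple[str, ...] = EDIT_KINDS,
) -> EditScript:
    """Sample a conflict-free edit script over a base snapshot.

    Targets are drawn without replacement so no object is edited twice;
    typos are confined to COMMON-NAME values (a typo inside a citation token
    would itself mint a new publication key, which is not a typo edit).
    """
    rng = random.Random(seed)
    used: set[str] = set()
    fresh_pmid = 900000 + (seed % 1000) * 100

    def classed(class_id: str) -> list[str]:
        return sorted(
            o.id for o in base.objects.values()
            if class_id in o.classes and o.id not in used
        )

    edits: list[Edit] = []
    attempts = 0
    while len(edits) < n_edits and attempts < n_edits * 30:
        attempts += 1
        kind = rng.choice(kinds)
        if kind == "ADD-CITATION":
            pool = sorted(
                o.id for o in base.objects.values()
                if o.id not in used and not ({"PUBLICATION", "GO-TERM", "PATHWAY-CLASS", "COMPOUND"} & set(o.classes))
            )
            if not pool:
                continue
            target = rng.choice(pool)
            fresh_pmid += 1
            level = rng.choice(["object", "attribute"])
            edits.append(Edit(kind, (target,), (f"PMID:{fresh_pmid}", level)))
        elif kind == "TYPO":
            pool = sorted(o.id for o in base.objects.values() if o.id not in used and "COMMON-NAME" in o.slots)
            if not pool:
                continue
            edits.append(Edit(kind, (rng.choice(pool),)))
        elif kind == "REWORD-SUMMARY":
            pool = sorted(o.id for o in base.objects.values() if o.id not in used and "COMMENT" in o.slots)
            if not pool:
                continue
            edits.append(Edit(kind, (rng.choice(pool),)))
        elif kind == "MERGE":
            orphans = [i for i in classed("PROTEIN") if i.startswith("ORPHAN-")]
            if len(orphans) < 2:
                continue
            loser, survivor = rng.sample(orphans, 2)
            edits.append(Edit(kind, (loser, survivor)))
        elif kind == "DELETE-OBJECT":
            orphans = [i for i in classed("PROTEIN") if i.startswith("ORPHAN-")]
            if not orphans:
                continue
            edits.append(Edit(kind, (rng.choice(orphans),)))
        elif kind == "ADD-GO-ANNOTATION":
            genes = classed("GENE")
            terms = sorted(o.id for o in base.objects.values() if "GO-TERM" in o.classes)
            if not genes or not terms:
                continue
            gene = rng.choice(genes)
            candidates = [t for t in terms if t not in base.objects[gene].slot_values("GO-TERMS")]
            if not candidates:
                continue
            edits.append(Edit(kind, (gene,), (rng.choice(candidates),)))
        elif kind == "REMOVE-GO-ANNOTATION":
            genes = [g for g in classed("GENE") if base.objects[g].slot_values("GO-TERMS")]
            if not genes:
                continue
            gene = rng.choice(genes)
            term = rng.choice(sorted(base.objects[gene].slot_values("GO-TERMS")))
            edits.append(Edit(kind, (gene,), (term,)))
        else:  # NEW-OBJECT-*
            entities = classed("PROTEIN")
            if not entities:
                continue
            new_id = f"REG-NEW-{seed % 10000}-{len(edits)}"
            if new_id in base.objects or new_id in used:
                continue
            entity = rng.choice(entities)
            if kind == "NEW-OBJECT-WITH-CITATION":
                fresh_pmid += 1
                edits.append(Edit(kind, (new_id, entity), (f"PMID:{fresh_pmid}",)))
            else:
                edits.append(Edit(kind, (new_id, entity)))
        used |= _touched(edits[-1])
    return EditScript(seed, edits)


def sample_registry(base: Snapshot, seed: int, n_users: int = 3) -> Registry:
    """A plausible registry over a generated snapshot: every kind and mode."""
    rng = random.Random(seed)
    genes = sorted(o.id for o in base.objects.values() if "GENE" in o.classes)
    pathways = sorted(o.id for o in base.objects.values() if "PATHWAY" in o.classes)
    terms = sorted(o.id for o in base.objects.values() if "GO-TERM" in o.classes)
    classes = sorted(o.id for o in base.objects.values() if "PATHWAY-CLASS" in o.classes)
    registry = Registry()
    for u in range(1, n_users + 1):
        user = f"user{u}@example.org"
        for g in rng.sample(genes, min(2, len(genes))):
            registry.entries.add(Subscription(user, base.database_id, "GENE", g, "NONE"))
        if pathways:
            registry.entries.add(Subscription(user, base.database_id, "PATHWAY", rng.choice(pathways), "NONE"))
        if terms:
            registry.entries.add(Subscription(user, base.database_id, "GO-TERM", rng.choice(terms), "NEW-MEMBERS"))
            registry.entries.add(Subscription(user, base.database_id, "GO-TERM", rng.choice(terms), "MEMBER-CHANGES"))
        if classes:
            mode = rng.choice(["NEW-MEMBERS", "MEMBER-CHANGES"])
            registry.entries.add(Subscription(user, base.database_id, "PATHWAY-CLASS", rng.choice(classes), mode))
    return registry
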