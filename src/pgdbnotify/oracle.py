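"""Brute-force ground truth for notification triggering.

This module exists to *check* the engine, not to power it: closures, term
membership and the firing criterion are re-derived here by naive
rescan-until-stable loops with the relation semantics written out inline.
It deliberately shares no code with the closure, diff or notify modules, so
agreement between the two routes is evidence, not tautology.
"""

from __future__ import annotations

from .model import Snapshot, citations_of
from .subscriptions import Registry, Subscription


def naive_new_citation_ids(old: Snapshot, new: Snapshot) -> set[str]:
    """Ids in the new release carrying at least one genuinely new citation."""
    merges = new.merges
    out: set[str] = set()
    for oid, obj in new.objects.items():
        previous: set[str] = set()
        if oid in old.objects:
            previous |= citations_of(old.objects[oid])
        for src, tgt in merges.items():
            if tgt == oid and src in old.objects:
                previous |= citations_of(old.objects[src])
        if citations_of(obj) - previous:
            out.add(oid)
    return out


def naive_gene_closure(s: Snapshot, gene_id: str) -> set[str]:
    members = {gene_id} if gene_id in s.objects else set()
    grew = True
    while grew:
        grew = False
        additions: set[str] = set()
        for oid, obj in s.objects.items():
            cl = obj.classes
            if oid in members:
                if "GENE" in cl:
                    additions.update(obj.slot_values("PRODUCT"))
                if "PROTEIN" in cl or "COMPLEX" in cl:
                    additions.update(obj.slot_values("COMPONENT-OF"))
                    additions.update(obj.slot_values("CATALYZES"))
                if "ENZYMATIC-REACTION" in cl:
                    additions.update(obj.slot_values("REACTION"))
                if "REACTION" in cl:
                    additions.update(obj.slot_values("IN-PATHWAY"))
            if "REGULATION" in cl and set(obj.slot_values("REGULATED-ENTITY")) & members:
                additions.add(oid)
            if "TRANSCRIPTION-UNIT" in cl and gene_id in obj.slot_values("GENES"):
                additions.add(oid)
        additions = {a for a in additions if a in s.objects} - members
        if additions:
            members |= additions
            grew = True
    return members


def naive_pathway_closure(s: Snapshot, pathway_id: str) -> set[str]:
    members = {pathway_id} if pathway_id in s.objects else set()
    grew = True
    while grew:
        grew = False
        additions: set[str] = set()
        for oid, obj in s.objects.items():
            cl = obj.classes
            if oid in members:
                if "PATHWAY" in cl:
                    additions.update(obj.slot_values("REACTION-LIST"))
                if "REACTION" in cl:
                    additions.update(obj.slot_values("LEFT"))
                    additions.update(obj.slot_values("RIGHT"))
                if "PROTEIN" in cl or "COMPLEX" in cl:
                    additions.update(obj.slot_values("COMPONENTS"))
                if "PROTEIN" in cl:
                    additions.update(obj.slot_values("GENE"))
            if "ENZYMATIC-REACTION" in cl and set(obj.slot_values("REACTION")) & members:
                additions.add(oid)
            if ("PROTEIN" in cl or "COMPLEX" in cl) and set(obj.slot_values("CATALYZES")) & members:
                additions.add(oid)
            if "REGULATION" in cl and set(obj.slot_values("REGULATED-ENTITY")) & members:
                additions.add(oid)
        additions = {a for a in additions if a in s.objects} - members
        if additions:
            members |= additions
            grew = True
    return members


def _naive_descendant_terms(s: Snapshot, term_id: str, term_class: str) -> set[str]:
    terms = {term_id}
    grew = True
    while grew:
        grew = False
        for obj in s.objects.values():
            if term_class in obj.classes and obj.id not in terms:
                if set(obj.slot_values("PARENTS")) & terms:
                    terms.add(obj.id)
                    grew = True
    return terms


def naive_term_members(s: Snapshot, term_id: str, kind: str) -> set[str]:
    if term_id not in s.objects:
        return set()
    if kind == "GO-TERM":
        terms = _naive_descendant_terms(s, term_id, "GO-TERM")
        return {
            o.id for o in s.objects.values()
            if "GENE" in o.classes and set(o.slot_values("GO-TERMS")) & terms
        }
    classes = _naive_descendant_terms(s, term_id, "PATHWAY-CLASS")
    return {
        o.id for o in s.objects.values()
        if "PATHWAY" in o.classes and set(o.classes) & classes
    }


def expected_firings(registry: Registry, old: Snapshot, new: Snapshot) -> set[Subscription]:
    """The exact set of subscriptions that must fire for this release pair."""
    triggered = naive_new_citation_ids(old, new)
    fired: set[Subscription] = set()
    for sub in registry.entries:
        if sub.database_id != new.database_id:
            continue
        if sub.kind == "GENE":
            if sub.target_id in new.objects and naive_gene_closure(new, sub.target_id) & triggered:
                fired.add(sub)
        elif sub.kind == "PATHWAY":
            if sub.target_id in new.objects and naive_pathway_closure(new, sub.target_id) & triggered:
                fired.add(sub)
        elif sub.mode == "NEW-MEMBERS":
            gained = naive_term_members(new, sub.target_id, sub.kind) - naive_term_members(old, sub.target_id, sub.kind)
            if gained:
                fired.add(sub)
        else:  # MEMBER-CHANGES
            members = naive_term_members(new, sub.target_id, sub.kind)
            walk = naive_gene_closure if sub.kind == "GO-TERM" else naive_pathway_closure
            if any(walk(new, m) & triggered for m in members):
                fired.add(sub)
    return fired
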