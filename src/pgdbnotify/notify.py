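"""The significance filter: decide which subscriptions warrant notification.

Curators never make a significant change without adding a citation, either
to the changed attribute or to the object as a whole.  So regardless of how
many fields changed, a gene or pathway subscription fires only if at least
one *new* citation (absent from the previous release) appears on the anchor
or any object in its interest closure.  Typo fixes, rewordings, object
merges, deletions and obsolete-annotation removals all fail this test and
stay silent.  Once an anchor passes the filter, every difference on every
closure member is collected for the report — the specific field behind each
new citation is generally unknowable.

Term subscriptions come in two modes.  NEW-MEMBERS fires when the term's
member set gains objects (annotation removals never fire); MEMBER-CHANGES
applies the gene/pathway criterion to every current member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .closure import ClosureEngine, Rule, term_members
from .diff import ObjectDiff, SnapshotDiff, diff_snapshot
from .errors import PgdbError, ResolutionError
from .model import Snapshot
from .subscriptions import Registry, Subscription

logger = logging.getLogger(__name__)


@dataclass
class NotificationItem:
    """Evidence bundle for one fired subscription."""

    subscription: Subscription
    anchor_id: str
    trigger_ids: set[str] = field(default_factory=set)
    member_diffs: list[ObjectDiff] = field(default_factory=list)
    new_publications: set[str] = field(default_factory=set)
    new_members: set[str] = field(default_factory=set)
    #: closure members of the anchor(s), for link resolution in reports
    members: set[str] = field(default_factory=set)


def _evaluate_anchor(
    kind: str,
    anchor_id: str,
    engine: ClosureEngine,
    d: SnapshotDiff,
) -> tuple[set[str], list[ObjectDiff], set[str], set[str]] | None:
    """Core gene/pathway criterion on one anchor; None when it does not fire."""
    closure = engine.closure(kind, anchor_id)
    triggers = {m for m in closure.members if m in d.diffs and d.diffs[m].new_citations}
    if not triggers:
        return None
    member_diffs = [d.diffs[m] for m in sorted(closure.members) if m in d.diffs]
    new_pubs = set().union(*(d.diffs[m].new_citations for m in triggers))
    return triggers, member_diffs, new_pubs, closure.members


def evaluate_gene_or_pathway(
    sub: Subscription,
    old: Snapshot,
    new: Snapshot,
    d: SnapshotDiff,
    engine: ClosureEngine | None = None,
) -> NotificationItem | None:
    """Evaluate a GENE or PATHWAY subscription; closure is taken on the new release."""
    if sub.kind not in ("GENE", "PATHWAY"):
        raise PgdbError(f"evaluate_gene_or_pathway got kind {sub.kind}")
    engine = engine or ClosureEngine(new)
    if sub.target_id not in new.objects:
        merged_to = new.merges.get(sub.target_id)
        logger.warning(
            "subscription target %s absent from %s %s%s",
            sub.target_id, new.database_id, new.version,
            f" (merged into {merged_to})" if merged_to else "",
        )
        return None
    fired = _evaluate_anchor(sub.kind, sub.target_id, engine, d)
    if fired is None:
        return None
    triggers, member_diffs, new_pubs, members = fired
    return NotificationItem(sub, sub.target_id, triggers, member_diffs, new_pubs, set(), members)


def evaluate_term(
    sub: Subscription,
    old: Snapshot,
    new: Snapshot,
    d: SnapshotDiff,
    engine: ClosureEngine | None = None,
) -> NotificationItem | None:
    """Evaluate a GO-TERM or PATHWAY-CLASS subscription in its chosen mode."""
    if sub.kind not in ("GO-TERM", "PATHWAY-CLASS"):
        raise PgdbError(f"evaluate_term got kind {sub.kind}")
    engine = engine or ClosureEngine(new)
    member_kind = "GENE" if sub.kind == "GO-TERM" else "PATHWAY"

    def members_in(snap: Snapshot) -> set[str] | None:
        try:
            return term_members(snap, sub.target_id, sub.kind)
        except ResolutionError:
            return None

    new_members_set = members_in(new)
    old_members_set = members_in(old)
    if new_members_set is None and old_members_set is None:
        logger.warning("term %s unknown in both releases of %s", sub.target_id, new.database_id)
        return None
    new_members_set = new_members_set or set()
    old_members_set = old_members_set or set()

    if sub.mode == "NEW-MEMBERS":
        gained = new_members_set - old_members_set
        if not gained:
            return None
        member_diffs = [d.diffs[m] for m in sorted(gained) if m in d.diffs]
        return NotificationItem(sub, sub.target_id, set(), member_diffs, set(), gained, set(gained))

    # MEMBER-CHANGES: the gene/pathway criterion over every current member
    triggers: set[str] = set()
    diffs_by_id: dict[str, ObjectDiff] = {}
    new_pubs: set[str] = set()
    all_members: set[str] = set()
    for member in sorted(new_members_set):
        fired = _evaluate_anchor(member_kind, member, engine, d)
        if fired is None:
            continue
        t, member_diffs, pubs, members = fired
        triggers |= t
        new_pubs |= pubs
        all_members |= members
        for od in member_diffs:
            diffs_by_id.setdefault(od.id, od)
    if not triggers:
        return None
    return NotificationItem(
        sub, sub.target_id, triggers,
        [diffs_by_id[i] for i in sorted(diffs_by_id)], new_pubs, set(), all_members,
    )


def run_notifications(
    registry: Registry,
    old: Snapshot,
    new: Snapshot,
    rules: dict[str, list[Rule]] | None = None,
    category_map: dict[str, str] | None = None,
    d: SnapshotDiff | None = None,
) -> list[NotificationItem]:
    """Evaluate every matching subscription once; deterministic order.

    Entries scoped to other databases are skipped.  Output is sorted by
    (user, kind, anchor id, mode), which groups items per user ready for
    per-database digest assembly.
    """
    if old.database_id != new.database_id:
        raise PgdbError("snapshots must belong to the same database")
    if d is None:
        d = diff_snapshot(old, new, category_map)
    engine = ClosureEngine(new, rules)
    items: list[NotificationItem] = []
    matching = sorted(
        (s for s in registry.entries if s.database_id == new.database_id),
        key=lambda s: (s.user, s.kind, s.target_id, s.mode),
    )
    logger.info("evaluating %d subscriptions against %d diffs", len(matching), len(d.diffs))
    for sub in matching:
        if sub.kind in ("GENE", "PATHWAY"):
            item = evaluate_gene_or_pathway(sub, old, new, d, engine)
        else:
            item = evaluate_term(sub, old, new, d, engine)
        if item is not None:
            items.append(item)
    logger.info("%d subscriptions fired", len(items))
    return items
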