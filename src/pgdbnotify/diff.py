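"""Release-to-release comparison of database snapshots.

Two releases are compared object-by-object and slot-by-slot.  Slot values
are compared as multisets of (text, annotations) pairs — exact text, so a
typo fix is a visible diff — and serialization-order changes alone are not
differences.  Each object diff also carries its set of *new citations*:
publication keys present on the new object (at any level) that were absent
from the old object and from every old object merged into it.  New citations
are the sole significance signal downstream; merges therefore stay silent by
construction, because the survivor inherits its sources' citations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

from .errors import PgdbError
from .model import DbObject, SlotValue, Snapshot, citations_of

ADDED = "ADDED"
REMOVED = "REMOVED"
MODIFIED = "MODIFIED"
MERGED_AWAY = "MERGED-AWAY"


def _load_category_map(path: str | None = None) -> dict[str, str]:
    if path is None:
        text = resources.files("pgdbnotify.data").joinpath("categories.yaml").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return dict(yaml.safe_load(text))


DEFAULT_CATEGORY_MAP = _load_category_map()

load_category_map = _load_category_map


def categorize(slot: str, object_classes: Iterable[str] = (), category_map: dict[str, str] | None = None) -> str:
    """Reader-facing change category for a slot (e.g. COMMENT → 'textual summary')."""
    cmap = category_map if category_map is not None else DEFAULT_CATEGORY_MAP
    return cmap.get(slot, slot.lower())


@dataclass
class SlotDiff:
    slot: str
    added: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    category: str = ""


@dataclass
class ObjectDiff:
    id: str
    status: str  # ADDED | REMOVED | MODIFIED | MERGED-AWAY
    slot_diffs: list[SlotDiff] = field(default_factory=list)
    new_citations: set[str] = field(default_factory=set)

    @property
    def categories(self) -> list[str]:
        seen = dict.fromkeys(sd.category for sd in self.slot_diffs)
        return list(seen)


@dataclass
class SnapshotDiff:
    old_version: str
    new_version: str
    diffs: dict[str, ObjectDiff] = field(default_factory=dict)


def _value_key(sv: SlotValue) -> tuple:
    return (sv.value, tuple(sorted((k, tuple(vs)) for k, vs in sv.annotations.items())))


def _slot_diffs(old: DbObject | None, new: DbObject | None, classes: list[str],
                category_map: dict[str, str] | None) -> list[SlotDiff]:
    old_slots = old.slots if old else {}
    new_slots = new.slots if new else {}
    out: list[SlotDiff] = []
    for slot in dict.fromkeys(list(old_slots) + list(new_slots)):
        old_counts = Counter(_value_key(sv) for sv in old_slots.get(slot, []))
        new_counts = Counter(_value_key(sv) for sv in new_slots.get(slot, []))
        added = [k[0] for k in sorted((new_counts - old_counts).elements())]
        removed = [k[0] for k in sorted((old_counts - new_counts).elements())]
        if added or removed:
            out.append(SlotDiff(slot, added, removed, categorize(slot, classes, category_map)))
    return out


def diff_object(
    old: DbObject | None,
    new: DbObject | None,
    merges: dict[str, str] | None = None,
    old_snapshot: Snapshot | None = None,
    category_map: dict[str, str] | None = None,
) -> ObjectDiff | None:
    """Compare one object across releases; None when nothing changed.

    ``merges`` is the new release's merge provenance and ``old_snapshot`` the
    previous release; together they let citations inherited from merged-away
    objects be subtracted, so a pure merge never looks like new evidence.
    """
    if old is None and new is None:
        raise PgdbError("diff_object requires at least one of old/new")
    merges = merges or {}

    if new is None:
        assert old is not None
        status = MERGED_AWAY if old.id in merges else REMOVED
        return ObjectDiff(old.id, status, _slot_diffs(old, None, old.classes, category_map), set())

    new_cits = citations_of(new)
    if old is not None:
        new_cits -= citations_of(old)
    # merge silence: evidence carried over from merged-away source objects is
    # not new, whether the survivor pre-existed or is a fresh frame
    if old_snapshot is not None:
        for src_id, surviving_id in merges.items():
            if surviving_id == new.id and src_id in old_snapshot.objects:
                new_cits -= citations_of(old_snapshot.objects[src_id])

    if old is None:
        return ObjectDiff(new.id, ADDED, _slot_diffs(None, new, new.classes, category_map), new_cits)

    slot_diffs = _slot_diffs(old, new, new.classes, category_map)
    if not slot_diffs:
        return None
    return ObjectDiff(new.id, MODIFIED, slot_diffs, new_cits)


def diff_snapshot(old: Snapshot, new: Snapshot, category_map: dict[str, str] | None = None) -> SnapshotDiff:
    """All per-object differences between two releases of one database."""
    if old.database_id != new.database_id:
        raise PgdbError(f"cannot diff releases of different databases ({old.database_id} vs {new.database_id})")
    merges = new.merges
    result = SnapshotDiff(old.version, new.version)
    for obj_id in sorted(set(old.objects) | set(new.objects)):
        d = diff_object(old.objects.get(obj_id), new.objects.get(obj_id), merges, old, category_map)
        if d is not None:
            result.diffs[obj_id] = d
    return result


def snapshot_diff_to_dict(d: SnapshotDiff) -> dict:
    """JSON-ready form of a SnapshotDiff (schema: data/diff_schema.json)."""
    return {
        "old_version": d.old_version,
        "new_version": d.new_version,
        "objects": {
            obj_id: {
                "status": od.status,
                "new_citations": sorted(od.new_citations),
                "slots": [
                    {"slot": sd.slot, "category": sd.category, "added": sd.added, "removed": sd.removed}
                    for sd in od.slot_diffs
                ],
            }
            for obj_id, od in sorted(d.diffs.items())
        },
    }
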