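"""Core data model for pathway/genome database (PGDB) snapshots.

A snapshot is one release of an object database in the attribute-value
flatfile style used by Pathway Tools ``.dat`` exports: each record is a frame
with a unique id, an ordered set of slots, and per-value annotations (for
example a ``^CITATIONS`` annotation attaching evidence to a single slot
value).  The reader and writer here round-trip the model exactly — object
set, class lists, slot order, value order, annotations and merge provenance
all survive ``read(write(S))``.

Flatfile dialect
----------------
* lines beginning ``#`` are comments; blank lines are ignored
* a record starts with ``UNIQUE-ID - <id>`` and ends with a line ``//``
* slot line: ``<SLOT-NAME> - <value>`` (separator is space-hyphen-space);
  repeated slot lines append values in order
* annotation line: ``^<LABEL> - <value>`` attaches to the most recent value
* continuation line: ``/<text>`` appends ``" <text>"`` to the most recent
  value (slot or annotation)

Merge provenance is recorded by the release itself: the surviving object of
a merge carries a ``MERGED-FROM`` slot naming each merged-away id.  This is
what lets downstream change detection distinguish a merge (non-notifiable)
from genuinely new content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import IntegrityError, ParseError, ValidationError

ID_PATTERN = re.compile(r"[A-Za-z0-9._:+-]+\Z")
_LABEL_PATTERN = re.compile(r"[A-Z][A-Z0-9_.-]*\Z")

#: slot names with model-level meaning
TYPES_SLOT = "TYPES"
CITATIONS_SLOT = "CITATIONS"
MERGED_FROM_SLOT = "MERGED-FROM"


@dataclass
class SlotValue:
    """One value of a slot, with its per-value annotations.

    ``annotations`` maps an uppercase label (e.g. ``CITATIONS``) to the list
    of annotation values attached to this particular slot value.
    """

    value: str
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.value.strip():
            raise ValidationError("slot value is empty after whitespace trimming")
        for label in self.annotations:
            if not label or label != label.upper():
                raise ValidationError(f"annotation label {label!r} must be uppercase and non-empty")


@dataclass
class DbObject:
    """One curated record: a frame id plus ordered slots.

    ``classes`` is a view of the ``TYPES`` slot — the record's direct class
    memberships (GENE, PROTEIN, PATHWAY, ...).
    """

    id: str
    slots: dict[str, list[SlotValue]] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return [sv.value for sv in self.slots.get(TYPES_SLOT, [])]

    def slot_values(self, slot: str) -> list[str]:
        """Plain text values of a slot ([] when absent)."""
        return [sv.value for sv in self.slots.get(slot, [])]

    def first_value(self, slot: str) -> str | None:
        vals = self.slot_values(slot)
        return vals[0] if vals else None

    def add_value(self, slot: str, value: str, annotations: dict[str, list[str]] | None = None) -> SlotValue:
        sv = SlotValue(value, dict(annotations or {}))
        self.slots.setdefault(slot, []).append(sv)
        return sv

    def validate(self) -> None:
        if not ID_PATTERN.match(self.id):
            raise ValidationError(f"object id {self.id!r} contains characters outside [A-Za-z0-9._:+-]")
        if not self.classes:
            raise ValidationError(f"object {self.id} has no TYPES (classes must be non-empty)")
        for slot, values in self.slots.items():
            if not slot:
                raise ValidationError(f"object {self.id} has an empty slot name")
            for sv in values:
                sv.validate()


@dataclass
class Snapshot:
    """A full database release: identifier, version label and object map.

    Merge provenance (``merges``: merged-away id → surviving id) is derived
    from ``MERGED-FROM`` slots so it can never disagree with the records.
    """

    database_id: str
    version: str
    objects: dict[str, DbObject] = field(default_factory=dict)

    @property
    def merges(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for obj in self.objects.values():
            for old_id in obj.slot_values(MERGED_FROM_SLOT):
                out[old_id] = obj.id
        return out

    def add(self, obj: DbObject) -> DbObject:
        if obj.id in self.objects:
            raise IntegrityError(f"duplicate object id {obj.id}")
        self.objects[obj.id] = obj
        return obj

    def validate(self) -> None:
        for obj in self.objects.values():
            obj.validate()
        for old_id, new_id in self.merges.items():
            if new_id not in self.objects:
                raise IntegrityError(f"MERGED-FROM on missing survivor {new_id}")
            if old_id in self.objects:
                raise IntegrityError(f"merged-away id {old_id} still present in snapshot")


def normalize_citation(token: str) -> str:
    """Normalize a citation token to its publication identity.

    Curators attach qualifiers (evidence codes, curator ids, timestamps)
    after ``:`` separators; the publication reference is the part before the
    first ``:``, except for ``PMID:<digits>`` tokens where the accession
    keeps its prefix.  Surrounding whitespace and brackets are stripped and
    the result is uppercased.  The function is idempotent.
    """
    t = token.strip().strip("[]()").strip().upper()
    if t.startswith("PMID:"):
        m = re.match(r"PMID:(\d+)", t)
        if m:
            return f"PMID:{m.group(1)}"
    return t.split(":", 1)[0]


def citations_of(obj: DbObject) -> set[str]:
    """All normalized citation keys on an object.

    Unions the object-level ``CITATIONS`` slot with every value-level
    ``CITATIONS`` annotation on every slot, so a citation counts no matter
    whether the curator attached it to the object or to one attribute.
    """
    keys: set[str] = set()
    for sv in obj.slots.get(CITATIONS_SLOT, []):
        keys.add(normalize_citation(sv.value))
    for values in obj.slots.values():
        for sv in values:
            for tok in sv.annotations.get(CITATIONS_SLOT, []):
                keys.add(normalize_citation(tok))
    return keys


def objects_of_class(snapshot: Snapshot, class_id: str) -> set[str]:
    """Ids whose TYPES contain ``class_id`` (direct membership only)."""
    return {o.id for o in snapshot.objects.values() if class_id in o.classes}


# ---------------------------------------------------------------------------
# flatfile reader / writer
# ---------------------------------------------------------------------------

_HEADER_DB = re.compile(r"#\s*Database:\s*(\S+)")
_HEADER_VERSION = re.compile(r"#\s*Version:\s*(\S+)")


def _iter_lines(path: str) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            yield lineno, raw.rstrip("\n")


def read_snapshot(path: str, database_id: str | None = None, version: str | None = None) -> Snapshot:
    """Parse a flatfile release into a Snapshot.

    ``database_id``/``version`` default to ``# Database:`` / ``# Version:``
    header comments when present (the writer emits them), else placeholders.
    Raises :class:`ParseError` on malformed records (naming the line) and
    :class:`IntegrityError` on duplicate ids.
    """
    objects: dict[str, DbObject] = {}
    header_db: str | None = None
    header_version: str | None = None

    cur: DbObject | None = None
    cur_start = 0
    # continuation target: the mutable location of the most recent value
    last_slot_value: SlotValue | None = None
    last_ann_values: list[str] | None = None

    def finish(lineno: int) -> None:
        nonlocal cur, last_slot_value, last_ann_values
        assert cur is not None
        if cur.id in objects:
            raise IntegrityError(f"{path}:{lineno}: duplicate UNIQUE-ID {cur.id}")
        objects[cur.id] = cur
        cur = None
        last_slot_value = None
        last_ann_values = None

    for lineno, line in _iter_lines(path):
        if not line.strip():
            continue
        if line.startswith("#"):
            if cur is None:
                m = _HEADER_DB.match(line)
                if m:
                    header_db = m.group(1)
                m = _HEADER_VERSION.match(line)
                if m:
                    header_version = m.group(1)
            continue
        if line == "//":
            if cur is None:
                raise ParseError("record terminator '//' outside any record", path, lineno)
            finish(lineno)
            continue
        if line.startswith("^"):
            if cur is None:
                raise ParseError("annotation line outside any record", path, lineno)
            if last_slot_value is None:
                raise ParseError("annotation line before any slot line", path, lineno)
            if " - " not in line:
                raise ParseError("annotation line lacks ' - ' separator", path, lineno)
            label, value = line[1:].split(" - ", 1)
            if not _LABEL_PATTERN.match(label):
                raise ParseError(f"annotation label {label!r} is not an uppercase token", path, lineno)
            anns = last_slot_value.annotations.setdefault(label, [])
            anns.append(value)
            last_ann_values = anns
            continue
        if line.startswith("/"):
            text = line[1:]
            if cur is None or last_slot_value is None:
                raise ParseError("continuation line with no preceding value", path, lineno)
            if last_ann_values is not None:
                last_ann_values[-1] += " " + text
            else:
                last_slot_value.value += " " + text
            continue
        if " - " not in line:
            raise ParseError(f"line is not a slot line (missing ' - '): {line!r}", path, lineno)
        slot, value = line.split(" - ", 1)
        if slot == "UNIQUE-ID":
            if cur is not None:
                raise ParseError(f"record {cur.id} (line {cur_start}) not terminated by '//'", path, lineno)
            if not ID_PATTERN.match(value):
                raise ParseError(f"invalid object id {value!r}", path, lineno)
            cur = DbObject(value)
            cur_start = lineno
            continue
        if cur is None:
            raise ParseError("slot line before any UNIQUE-ID record header", path, lineno)
        last_slot_value = cur.add_value(slot, value)
        last_ann_values = None

    if cur is not None:
        raise ParseError(f"record {cur.id} (line {cur_start}) not terminated by '//' at end of file", path, cur_start)

    snap = Snapshot(
        database_id=database_id or header_db or "DB",
        version=version or header_version or "0",
        objects=objects,
    )
    snap.validate()
    return snap


def write_snapshot(snapshot: Snapshot, path: str) -> None:
    """Serialize a Snapshot; ``read_snapshot`` of the output equals the model."""
    snapshot.validate()
    lines: list[str] = [
        f"# Database: {snapshot.database_id}",
        f"# Version: {snapshot.version}",
        "#",
    ]
    for obj in snapshot.objects.values():
        lines.append(f"UNIQUE-ID - {obj.id}")
        for slot, values in obj.slots.items():
            for sv in values:
                if "\n" in sv.value:
                    raise ValidationError(f"{obj.id}.{slot}: embedded newline in slot value")
                lines.append(f"{slot} - {sv.value}")
                for label, ann_values in sv.annotations.items():
                    for v in ann_values:
                        lines.append(f"^{label} - {v}")
        lines.append("//")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def resolve_publication(snapshot: Snapshot, citation_key: str) -> DbObject | None:
    """Find the PUBLICATION record for a normalized citation key, if any.

    Matches either the publication's own frame id or its PMID slot
    (``PMID:123`` keys match a record with ``PMID - 123``).
    """
    if citation_key in snapshot.objects and "PUBLICATION" in snapshot.objects[citation_key].classes:
        return snapshot.objects[citation_key]
    if citation_key.startswith("PMID:"):
        digits = citation_key[5:]
        for obj in snapshot.objects.values():
            if "PUBLICATION" in obj.classes and digits in obj.slot_values("PMID"):
                return obj
    return None
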