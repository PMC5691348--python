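"""Subscription registry: who wants to hear about what, in which database.

Four subscription kinds are supported.  GENE and PATHWAY subscriptions name
one object and implicitly cover its interest closure.  GO-TERM and
PATHWAY-CLASS subscriptions name an ontology term and carry a mode:
``NEW-MEMBERS`` (notify when new genes/pathways are annotated under the
term) or ``MEMBER-CHANGES`` (apply the gene/pathway change criteria to every
current member).  Every subscription is scoped to a single database.

The registry persists as a TSV so curators can diff and spreadsheet-edit it:
``user<TAB>database<TAB>kind<TAB>target<TAB>mode`` with ``-`` in the mode
column for GENE/PATHWAY rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ValidationError

KINDS = ("GENE", "PATHWAY", "GO-TERM", "PATHWAY-CLASS")
OBJECT_KINDS = ("GENE", "PATHWAY")
TERM_KINDS = ("GO-TERM", "PATHWAY-CLASS")
MODES = ("NEW-MEMBERS", "MEMBER-CHANGES", "NONE")

_TSV_HEADER = ["user", "database", "kind", "target", "mode"]


@dataclass(frozen=True, order=True)
class Subscription:
    """One registered interest; hashable, so a registry is a plain set."""

    user: str
    database_id: str
    kind: str
    target_id: str
    mode: str = "NONE"

    def validate(self) -> None:
        if not self.user or not self.database_id or not self.target_id:
            raise ValidationError("subscription user/database/target must be non-empty")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown subscription kind {self.kind!r} (expected one of {KINDS})")
        if self.mode not in MODES:
            raise ValidationError(f"unknown subscription mode {self.mode!r} (expected one of {MODES})")
        if self.kind in OBJECT_KINDS and self.mode != "NONE":
            raise ValidationError(f"{self.kind} subscriptions take no mode (got {self.mode})")
        if self.kind in TERM_KINDS and self.mode == "NONE":
            raise ValidationError(
                f"{self.kind} subscription to {self.target_id} requires mode NEW-MEMBERS or MEMBER-CHANGES"
            )


@dataclass
class Registry:
    entries: set[Subscription] = field(default_factory=set)

    def for_database(self, database_id: str) -> list[Subscription]:
        return sorted(e for e in self.entries if e.database_id == database_id)


def subscribe(registry: Registry, sub: Subscription) -> Registry:
    """Add one subscription; idempotent."""
    sub.validate()
    registry.entries.add(sub)
    return registry


def unsubscribe(registry: Registry, sub: Subscription) -> Registry:
    """Remove one subscription; removing a non-member is a no-op."""
    registry.entries.discard(sub)
    return registry


def bulk_subscribe(registry: Registry, user: str, database_id: str, kind: str, ids: Iterable[str]) -> Registry:
    """Subscribe one user to a whole id list (a SmartTable-style export).

    Only object kinds (GENE, PATHWAY) are valid in bulk: term kinds need a
    mode choice per term.  Duplicate ids collapse to one entry.
    """
    if kind not in OBJECT_KINDS:
        raise ValidationError(f"bulk subscription supports kinds {OBJECT_KINDS}, not {kind!r}")
    for target in dict.fromkeys(ids):
        subscribe(registry, Subscription(user, database_id, kind, target, "NONE"))
    return registry


def load_registry(path: str) -> Registry:
    registry = Registry()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if rownum == 1 and [c.strip() for c in row] == _TSV_HEADER:
                continue
            if len(row) != 5:
                raise ValidationError(f"{path}: row {rownum}: expected 5 tab-separated columns, got {len(row)}")
            user, db, kind, target, mode = (c.strip() for c in row)
            sub = Subscription(user, db, kind, target, "NONE" if mode == "-" else mode)
            try:
                sub.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {rownum}: {exc}") from exc
            registry.entries.add(sub)
    return registry


def save_registry(registry: Registry, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for sub in sorted(registry.entries):
            mode = "-" if sub.mode == "NONE" else sub.mode
            writer.writerow([sub.user, sub.database_id, sub.kind, sub.target_id, mode])


def load_id_list(path: str) -> list[str]:
    """Read a bulk-subscribe id file: one id per line, '#' comments allowed."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids
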