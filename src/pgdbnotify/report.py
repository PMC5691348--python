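"""Digest assembly and rendering.

All fired subscriptions of one user in one database become a single report
(one email's worth of text).  The report is deliberately compact: per
subscription, a linked anchor heading, one linked line per changed related
object naming its change categories, and a shared list of new publications;
the footer links to subscription management.  Markdown is the canonical
rendering; HTML is derived from the same block structure, so link targets
and visible strings agree between formats.  Output bytes are deterministic:
no timestamps, all orderings fixed.
"""

from __future__ import annotations

import html as _html
import json
import os
import re
from dataclasses import dataclass, field

from .errors import ConfigurationError, PgdbError
from .model import Snapshot, resolve_publication
from .notify import NotificationItem

_KIND_LABEL = {"GENE": "Gene", "PATHWAY": "Pathway", "GO-TERM": "GO term", "PATHWAY-CLASS": "Pathway class"}
_STATUS_LABEL = {"ADDED": "New", "MODIFIED": "Changed", "REMOVED": "Removed", "MERGED-AWAY": "Merged away"}


@dataclass(frozen=True)
class Link:
    text: str
    url: str


Inline = str | Link


@dataclass
class Report:
    user: str
    database_id: str
    old_version: str
    new_version: str
    items: list[NotificationItem]
    manage_url: str
    url_template: str
    display_names: dict[str, str] = field(default_factory=dict)
    #: citation key -> (display string, linked object id or None)
    publications: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def link_for(self, obj_id: str) -> str:
        return self.url_template.format(db=self.database_id, id=obj_id)

    def name_of(self, obj_id: str) -> str:
        return self.display_names.get(obj_id, obj_id)


def _publication_display(snapshot: Snapshot, key: str) -> tuple[str, str | None]:
    pub = resolve_publication(snapshot, key)
    if pub is None:
        return key, None
    authors = ", ".join(pub.slot_values("AUTHORS"))
    year = pub.first_value("YEAR")
    title = pub.first_value("TITLE")
    pmid = pub.first_value("PMID")
    if title:
        head = " ".join(x for x in (authors, year) if x)
        tail = f" (PMID:{pmid})" if pmid else ""
        return (f"{head}: {title}{tail}" if head else f"{title}{tail}"), pub.id
    return key, pub.id


def build_reports(
    items: list[NotificationItem],
    url_template: str,
    manage_url: str,
    snapshot: Snapshot,
    old_version: str = "",
) -> list[Report]:
    """One Report per (user, database) group with at least one fired item.

    ``url_template`` must contain ``{db}`` and ``{id}`` placeholders; links
    in the rendered digest are formed from it.
    """
    if "{db}" not in url_template or "{id}" not in url_template:
        raise ConfigurationError("url template must contain {db} and {id} placeholders")
    groups: dict[tuple[str, str], list[NotificationItem]] = {}
    for item in items:
        groups.setdefault((item.subscription.user, item.subscription.database_id), []).append(item)

    reports: list[Report] = []
    for (user, db), group in sorted(groups.items()):
        names: dict[str, str] = {}
        pubs: dict[str, tuple[str, str | None]] = {}
        for item in group:
            for obj_id in {item.anchor_id} | item.members | item.new_members | {d.id for d in item.member_diffs}:
                obj = snapshot.objects.get(obj_id)
                names[obj_id] = (obj.first_value("COMMON-NAME") or obj_id) if obj else obj_id
            for key in item.new_publications:
                if key not in pubs:
                    pubs[key] = _publication_display(snapshot, key)
        ordered = sorted(
            group,
            key=lambda it: (it.subscription.kind, names.get(it.anchor_id, it.anchor_id), it.anchor_id),
        )
        reports.append(Report(user, db, old_version, snapshot.version, ordered, manage_url, url_template, names, pubs))
    return reports


# ---------------------------------------------------------------------------
# rendering: one block model, two emitters
# ---------------------------------------------------------------------------


def _blocks(r: Report) -> list[tuple[str, list[Inline]]]:
    blocks: list[tuple[str, list[Inline]]] = []
    title = f"Update notifications: {r.database_id}"
    if r.old_version or r.new_version:
        title += f" (release {r.old_version} → {r.new_version})"
    blocks.append(("h1", [title]))

    rendered_members: set[str] = set()
    for item in r.items:
        kind = item.subscription.kind
        anchor_label = f"{_KIND_LABEL[kind]}: "
        blocks.append(("h2", [anchor_label, Link(r.name_of(item.anchor_id), r.link_for(item.anchor_id))]))

        for member_id in sorted(item.new_members):
            blocks.append(("li", ["New member: ", Link(r.name_of(member_id), r.link_for(member_id))]))

        fresh: list[tuple[str, list[Inline]]] = []
        seen_again: list[str] = []
        for od in item.member_diffs:
            if od.id in item.new_members:
                continue  # already listed as a new member
            if od.id in rendered_members:
                seen_again.append(od.id)
                continue
            rendered_members.add(od.id)
            label = _STATUS_LABEL[od.status]
            cats = ", ".join(od.categories)
            if od.status in ("REMOVED", "MERGED-AWAY"):
                # object absent from the new release: no page to link to
                fresh.append(("li", [f"{label}: {r.name_of(od.id)}"]))
            else:
                fresh.append(("li", [f"{label}: ", Link(r.name_of(od.id), r.link_for(od.id)), f" — {cats}"]))
        blocks.extend(fresh)
        if seen_again:
            inlines: list[Inline] = ["Also changed (listed above): "]
            for i, obj_id in enumerate(sorted(seen_again, key=lambda x: (r.name_of(x), x))):
                if i:
                    inlines.append(", ")
                inlines.append(Link(r.name_of(obj_id), r.link_for(obj_id)))
            blocks.append(("li", inlines))

    all_pub_keys = sorted(r.publications)
    if all_pub_keys:
        blocks.append(("p", ["New publications:"]))
        for key in all_pub_keys:
            display, pub_id = r.publications[key]
            if pub_id is not None:
                blocks.append(("li", [Link(display, r.link_for(pub_id))]))
            else:
                blocks.append(("li", [display]))

    blocks.append(("p", [Link("Manage your notification subscriptions", r.manage_url)]))
    return blocks


def _md_inline(inlines: list[Inline]) -> str:
    out = []
    for part in inlines:
        if isinstance(part, Link):
            out.append(f"[{part.text}]({part.url})")
        else:
            out.append(part)
    return "".join(out)


def _html_inline(inlines: list[Inline]) -> str:
    out = []
    for part in inlines:
        if isinstance(part, Link):
            out.append(f'<a href="{_html.escape(part.url, quote=True)}">{_html.escape(part.text)}</a>')
        else:
            out.append(_html.escape(part))
    return "".join(out)


def render(r: Report, format: str = "markdown") -> str:
    """Render one report; byte-deterministic for a given Report."""
    if not r.items:
        raise PgdbError("refusing to render an empty report")
    blocks = _blocks(r)
    if format == "markdown":
        lines: list[str] = []
        for kind, inlines in blocks:
            text = _md_inline(inlines)
            if kind == "h1":
                lines += [f"# {text}", ""]
            elif kind == "h2":
                if lines and lines[-1] != "":
                    lines.append("")
                lines += [f"## {text}", ""]
            elif kind == "li":
                lines.append(f"- {text}")
            else:
                if lines and lines[-1] != "":
                    lines.append("")
                lines += [text, ""]
        while lines and lines[-1] == "":
            lines.pop()
        return "\n".join(lines) + "\n"
    if format == "html":
        out: list[str] = ["<!DOCTYPE html>", "<html><body>"]
        in_list = False
        for kind, inlines in blocks:
            text = _html_inline(inlines)
            if kind == "li":
                if not in_list:
                    out.append("<ul>")
                    in_list = True
                out.append(f"<li>{text}</li>")
                continue
            if in_list:
                out.append("</ul>")
                in_list = False
            tag = {"h1": "h1", "h2": "h2", "p": "p"}[kind]
            out.append(f"<{tag}>{text}</{tag}>")
        if in_list:
            out.append("</ul>")
        out.append("</body></html>")
        return "\n".join(out) + "\n"
    raise PgdbError(f"unknown render format {format!r} (expected markdown or html)")


def extract_links(text: str, format: str = "markdown") -> list[tuple[str, str]]:
    """(text, url) pairs of every hyperlink in a rendered report."""
    if format == "markdown":
        return re.findall(r"\[([^\]]*)\]\(([^)]*)\)", text)
    pairs = re.findall(r'<a href="([^"]*)">(.*?)</a>', text)
    return [(_html.unescape(t), _html.unescape(u)) for u, t in pairs]


def report_to_json(r: Report) -> dict:
    return {
        "user": r.user,
        "database": r.database_id,
        "old_version": r.old_version,
        "new_version": r.new_version,
        "manage_url": r.manage_url,
        "items": [
            {
                "kind": it.subscription.kind,
                "mode": it.subscription.mode,
                "anchor": it.anchor_id,
                "triggers": sorted(it.trigger_ids),
                "new_members": sorted(it.new_members),
                "changed": sorted(d.id for d in it.member_diffs),
                "new_publications": sorted(it.new_publications),
            }
            for it in r.items
        ],
    }


def _sanitize(user: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", user)


def write_reports(reports: list[Report], outdir: str, format: str = "markdown") -> list[str]:
    """Write one digest file (plus a JSON sidecar) per report; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    ext = "md" if format == "markdown" else "html"
    paths = []
    for r in reports:
        base = f"{_sanitize(r.user)}__{r.database_id}"
        path = os.path.join(outdir, f"{base}.{ext}")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(render(r, format))
        with open(os.path.join(outdir, f"{base}.json"), "w", encoding="utf-8", newline="\n") as fh:
            json.dump(report_to_json(r), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths.append(path)
    return paths
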