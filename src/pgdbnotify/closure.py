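"""Interest closures and ontology-term membership.

A gene or pathway subscription implicitly covers a whole neighborhood of
functionally related objects.  For a gene: its product, the complexes the
product belongs to (transitively), the enzymatic activities of product or
complexes, those activities' reactions, the pathways containing the
reactions, regulation of any member, and transcription units containing the
gene (plus regulation of those units).  For a pathway: its reactions (with
sub-pathways expanded recursively), their substrate/product metabolites,
catalyzing activities, the enzymes behind them (complexes broken down to
monomers), those monomers' genes, and regulation of any member.

The traversal is a fixed point over a configurable relation set (see
``data/relations.yaml``), cycle-safe and deterministic.  Term membership
implements the GO true-path rule: a gene annotated to a descendant term is a
member of every ancestor term; pathway-class membership follows the TYPES →
PARENTS chain of the pathway ontology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .errors import ConfigurationError, OntologyError, ResolutionError
from .model import DbObject, Snapshot


@dataclass(frozen=True)
class Rule:
    """One traversal rule; see data/relations.yaml for field semantics."""

    name: str
    on: frozenset[str]
    slot: str
    direction: str  # "forward" | "reverse"
    anchor_only: bool = False


@dataclass
class ClosureResult:
    anchor_id: str
    members: set[str] = field(default_factory=set)
    #: member id -> path of (relation, id) steps from the anchor
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def _parse_rules(raw: object) -> dict[str, list[Rule]]:
    if not isinstance(raw, Mapping):
        raise ConfigurationError("relation config must map closure type to a rule list")
    out: dict[str, list[Rule]] = {}
    for closure_type, rules in raw.items():
        parsed = []
        for r in rules:
            try:
                parsed.append(
                    Rule(
                        name=r["name"],
                        on=frozenset(r["classes"]),
                        slot=r["slot"],
                        direction=r["direction"],
                        anchor_only=bool(r.get("anchor_only", False)),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(f"bad relation rule in {closure_type!r}: {r!r}") from exc
            if parsed[-1].direction not in ("forward", "reverse"):
                raise ConfigurationError(f"rule {parsed[-1].name}: direction must be forward or reverse")
        out[str(closure_type)] = parsed
    return out


def load_relation_config(path: str | None = None) -> dict[str, list[Rule]]:
    """Load closure rules from YAML; default config ships with the package."""
    if path is None:
        text = resources.files("pgdbnotify.data").joinpath("relations.yaml").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return _parse_rules(yaml.safe_load(text))


DEFAULT_RULES = load_relation_config()


class ClosureEngine:
    """Reusable closure computer over one snapshot.

    Builds a reverse index (slot → value → holder ids) once, so evaluating
    hundreds of subscriptions against a large release stays linear.
    """

    def __init__(self, snapshot: Snapshot, rules: dict[str, list[Rule]] | None = None):
        self.snapshot = snapshot
        self.rules = rules if rules is not None else DEFAULT_RULES
        reverse_slots = {r.slot for rs in self.rules.values() for r in rs if r.direction == "reverse"}
        self._reverse: dict[str, dict[str, list[str]]] = {s: {} for s in reverse_slots}
        for obj in snapshot.objects.values():
            for slot in reverse_slots:
                for value in obj.slot_values(slot):
                    self._reverse[slot].setdefault(value, []).append(obj.id)

    def _expand(self, anchor_id: str, rules: list[Rule]) -> ClosureResult:
        objects = self.snapshot.objects
        if anchor_id not in objects:
            raise ResolutionError(f"anchor {anchor_id} not found in {self.snapshot.database_id} {self.snapshot.version}")
        result = ClosureResult(anchor_id, {anchor_id}, {anchor_id: []})

        frontier = [anchor_id]
        while frontier:
            next_frontier: list[str] = []

            def reach(target: str, relation: str, via: str) -> None:
                if target in result.members or target not in objects:
                    return
                result.members.add(target)
                result.provenance[target] = result.provenance[via] + [(relation, target)]
                next_frontier.append(target)

            for member in sorted(frontier):
                obj = objects[member]
                member_classes = set(obj.classes)
                for rule in rules:
                    if rule.direction == "forward":
                        if member_classes & rule.on:
                            for target in obj.slot_values(rule.slot):
                                reach(target, rule.name, member)
                    else:
                        if rule.anchor_only and member != anchor_id:
                            continue
                        for holder_id in self._reverse.get(rule.slot, {}).get(member, []):
                            if set(objects[holder_id].classes) & rule.on:
                                reach(holder_id, rule.name, member)
            frontier = next_frontier
        return result

    def gene_closure(self, gene_id: str) -> ClosureResult:
        return self._expand(gene_id, self.rules["gene"])

    def pathway_closure(self, pathway_id: str) -> ClosureResult:
        return self._expand(pathway_id, self.rules["pathway"])

    def closure(self, kind: str, anchor_id: str) -> ClosureResult:
        if kind == "GENE":
            return self.gene_closure(anchor_id)
        if kind == "PATHWAY":
            return self.pathway_closure(anchor_id)
        raise ResolutionError(f"no closure defined for subscription kind {kind}")


def gene_closure(snapshot: Snapshot, gene_id: str, rules: dict[str, list[Rule]] | None = None) -> ClosureResult:
    """Interest closure of one gene (convenience wrapper over ClosureEngine)."""
    return ClosureEngine(snapshot, rules).gene_closure(gene_id)


def pathway_closure(snapshot: Snapshot, pathway_id: str, rules: dict[str, list[Rule]] | None = None) -> ClosureResult:
    """Interest closure of one pathway."""
    return ClosureEngine(snapshot, rules).pathway_closure(pathway_id)


# ---------------------------------------------------------------------------
# ontology-term membership
# ---------------------------------------------------------------------------


def _descendants(snapshot: Snapshot, term_id: str, term_class: str) -> set[str]:
    """term_id plus every term reachable against PARENTS links.

    Raises :class:`OntologyError` if the reachable subgraph is not a DAG
    (iterative DFS with on-stack coloring).
    """
    children: dict[str, list[str]] = {}
    for obj in snapshot.objects.values():
        if term_class in obj.classes:
            for parent in obj.slot_values("PARENTS"):
                children.setdefault(parent, []).append(obj.id)

    done: set[str] = set()
    on_path: set[str] = set()
    out: set[str] = set()
    stack: list[tuple[str, bool]] = [(term_id, False)]
    while stack:
        node, leaving = stack.pop()
        if leaving:
            on_path.discard(node)
            done.add(node)
            continue
        if node in done:
            continue
        if node in on_path:
            raise OntologyError(f"PARENTS cycle through {node} below {term_id}")
        on_path.add(node)
        out.add(node)
        stack.append((node, True))
        for child in children.get(node, []):
            if child in on_path:
                raise OntologyError(f"PARENTS cycle through {child} below {term_id}")
            if child not in done:
                stack.append((child, False))
    return out


def term_members(snapshot: Snapshot, term_id: str, kind: str) -> set[str]:
    """Genes (GO-TERM) or pathways (PATHWAY-CLASS) under a term.

    GO membership applies the true-path rule: annotation to any descendant
    term counts.  Pathway-class membership follows each pathway's TYPES into
    the class hierarchy's PARENTS chain.
    """
    if kind == "GO-TERM":
        if term_id not in snapshot.objects:
            raise ResolutionError(f"GO term {term_id} not found")
        terms = _descendants(snapshot, term_id, "GO-TERM")
        return {
            o.id
            for o in snapshot.objects.values()
            if "GENE" in o.classes and set(o.slot_values("GO-TERMS")) & terms
        }
    if kind == "PATHWAY-CLASS":
        if term_id not in snapshot.objects:
            raise ResolutionError(f"pathway class {term_id} not found")
        classes = _descendants(snapshot, term_id, "PATHWAY-CLASS")
        return {
            o.id
            for o in snapshot.objects.values()
            if "PATHWAY" in o.classes and set(o.classes) & classes
        }
    raise ResolutionError(f"term membership undefined for kind {kind}")
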