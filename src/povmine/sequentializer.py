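"""Variant sequentialization: domain-knowledge rewriting of parallel groups.

Coarse (day-granularity) timestamps make genuinely ordered activities look
parallel. Domain experts, however, often know the true order — a CT scan of
the chest is taken before a liver biopsy, a therapeutic appliance is removed
after the surgery that installed it. A sequentialization rule captures such
knowledge as a source/target pattern pair over a parallel group: the source
names the activities that must co-occur in one parallel group (with an
optional wildcard ``...`` binding the unnamed remainder), and the target
rearranges exactly those activities into a series-parallel shape, keeping
the remainder parallel to it. Rewriting only ever adds order relations; the
result's linearizations are a subset of the input's.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from . import grammar
from .variants import (
    LEAF,
    PAR,
    SEQ,
    Variant,
    VariantNode,
    VariantTable,
    canonicalize,
    leaf,
    par,
    seq,
)

#: Leaf label standing for "whatever else runs in parallel here".
WILDCARD = grammar.WILDCARD_TOKEN


class RuleError(ValueError):
    pass


def _pattern_node_from_sexpr(sexpr: tuple) -> VariantNode:
    head = sexpr[0]
    if head == "leaf":
        return leaf(sexpr[1])
    if head == "wildcard":
        return leaf(WILDCARD)
    if head == grammar.SEQ_TOKEN:
        return VariantNode(
            kind=SEQ, children=tuple(_pattern_node_from_sexpr(c) for c in sexpr[1])
        )
    if head == grammar.PAR_TOKEN:
        return VariantNode(
            kind=PAR, children=tuple(_pattern_node_from_sexpr(c) for c in sexpr[1])
        )
    raise RuleError(f"token {head!r} is not part of the pattern grammar")


def _serialize_pattern(node: VariantNode) -> str:
    if node.kind == LEAF:
        return WILDCARD if node.label == WILDCARD else grammar.quote_label(node.label)
    op = grammar.SEQ_TOKEN if node.kind == SEQ else grammar.PAR_TOKEN
    return f"{op}( " + ", ".join(_serialize_pattern(c) for c in node.children) + " )"


@dataclass(frozen=True)
class Pattern:
    """A variant fragment whose leaves are activity labels or the wildcard."""

    root: VariantNode

    def __post_init__(self) -> None:
        wildcards = [l for l in self.root.leaves() if l == WILDCARD]
        if len(wildcards) > 1:
            raise RuleError("a pattern may contain at most one wildcard")
        if wildcards:
            ok = self.root.kind == PAR and any(
                c.kind == LEAF and c.label == WILDCARD for c in self.root.children
            )
            if not ok:
                raise RuleError(
                    "the wildcard must be a direct child of the top-level "
                    "parallel group"
                )

    @property
    def has_wildcard(self) -> bool:
        return WILDCARD in self.root.leaves()

    @property
    def explicit_labels(self) -> Counter:
        return Counter(l for l in self.root.leaves() if l != WILDCARD)

    def serialize(self) -> str:
        return _serialize_pattern(self.root)

    @classmethod
    def parse(cls, text: str) -> "Pattern":
        return cls(root=_pattern_node_from_sexpr(grammar.parse(text)))


@dataclass(frozen=True)
class Rule:
    """Source/target pattern pair imposing domain-knowledge order."""

    name: str
    source: Pattern
    target: Pattern

    def __post_init__(self) -> None:
        src = self.source
        if src.root.kind != PAR:
            raise RuleError(
                f"rule {self.name!r}: source must be a parallel group"
            )
        explicit = [
            c for c in src.root.children if not (c.kind == LEAF and c.label == WILDCARD)
        ]
        if any(c.kind != LEAF for c in explicit):
            raise RuleError(
                f"rule {self.name!r}: source group may contain only activity "
                "leaves and the wildcard"
            )
        needed = 1 if src.has_wildcard else 2
        if len(explicit) < needed:
            raise RuleError(
                f"rule {self.name!r}: source needs at least "
                f"{needed} explicit activities"
            )
        if src.explicit_labels != self.target.explicit_labels:
            raise RuleError(
                f"rule {self.name!r}: source and target must name the same "
                f"activity multiset (source {sorted(src.explicit_labels.elements())}, "
                f"target {sorted(self.target.explicit_labels.elements())})"
            )
        if src.has_wildcard != self.target.has_wildcard:
            raise RuleError(
                f"rule {self.name!r}: target must contain the wildcard iff the "
                "source does"
            )


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]
    iteration_cap: int = 100

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise RuleError("rule names must be unique")
        if self.iteration_cap < 1:
            raise RuleError("iteration cap must be at least 1")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def parse_ruleset(config: Mapping) -> RuleSet:
    """Build a rule set from parsed YAML/JSON configuration.

    Expected shape::

        rules:
          - name: ct-before-liver-biopsy
            source: "+( 'CTC', 'LiB', ... )"
            target: "+( ->( 'CTC', 'LiB' ), ... )"
        iteration_cap: 100
    """
    rules = []
    for entry in config.get("rules", []):
        try:
            rules.append(
                Rule(
                    name=entry["name"],
                    source=Pattern.parse(entry["source"]),
                    target=Pattern.parse(entry["target"]),
                )
            )
        except KeyError as exc:
            raise RuleError(f"rule entry {entry!r} lacks field {exc}") from exc
    return RuleSet(
        rules=tuple(rules), iteration_cap=int(config.get("iteration_cap", 100))
    )


def load_ruleset(path: str | Path) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        return parse_ruleset(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class MatchSite:
    """A parallel group matched by a source pattern.

    ``bound`` and ``remainder`` index the group's leaves in depth-first
    order; the label tuples carry the same information by name.
    """

    path: tuple[int, ...]
    bound: tuple[int, ...]
    remainder: tuple[int, ...]
    bound_labels: tuple[str, ...]
    remainder_labels: tuple[str, ...]


def _group_order(node: VariantNode) -> tuple[tuple[str, ...], set[tuple[int, int]]]:
    """Leaf labels (depth-first) of a group and its strict order pairs."""
    v = Variant(root=node)
    labels = v.leaves
    lt = {
        (x, y)
        for y, before in enumerate(v.predecessors)
        for x in before
    }
    return labels, lt


def _bind(source: Pattern, labels: Sequence[str]) -> tuple[int, ...] | None:
    """Bind explicit source labels to the canonically-first leaf occurrences."""
    wanted = dict(source.explicit_labels)
    bound: list[int] = []
    for idx, label in enumerate(labels):
        if wanted.get(label, 0) > 0:
            wanted[label] -= 1
            bound.append(idx)
    if any(v > 0 for v in wanted.values()):
        return None
    if not source.has_wildcard and len(bound) != len(labels):
        return None
    return tuple(bound)


def match_source(source: Pattern, variant: Variant) -> list[MatchSite]:
    """All parallel groups of the variant (any depth) matching ``source``.

    A group matches iff the multiset of its leaves contains the source's
    explicit labels (and nothing else, when the source has no wildcard).
    """
    sites: list[MatchSite] = []

    def walk(node: VariantNode, path: tuple[int, ...]) -> None:
        if node.kind == PAR:
            labels = node.leaves()
            bound = _bind(source, labels)
            if bound is not None:
                remainder = tuple(
                    i for i in range(len(labels)) if i not in bound
                )
                sites.append(
                    MatchSite(
                        path=path,
                        bound=bound,
                        remainder=remainder,
                        bound_labels=tuple(labels[i] for i in bound),
                        remainder_labels=tuple(labels[i] for i in remainder),
                    )
                )
        for i, child in enumerate(node.children):
            walk(child, path + (i,))

    walk(variant.root, ())
    return sites


def _target_order_pairs(target: Pattern) -> tuple[tuple[str, ...], set[tuple[int, int]]]:
    """Order pairs the target imposes over its explicit leaves.

    Leaves are indexed per label occurrence in depth-first order, so the
    k-th occurrence of a label in the target maps onto the k-th bound leaf.
    """

    def strip(node: VariantNode) -> VariantNode | None:
        if node.kind == LEAF:
            return None if node.label == WILDCARD else node
        children = [c2 for c in node.children if (c2 := strip(c)) is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return VariantNode(kind=node.kind, children=tuple(children))

    core = strip(target.root)
    if core is None:  # pragma: no cover - excluded by Rule validation
        raise RuleError("target has no explicit activities")
    return _group_order(core)


def _series_parallel_build(
    elements: Sequence[int], labels: Sequence[str], lt: set[tuple[int, int]]
) -> VariantNode | None:
    """Rebuild a series-parallel tree from a strict partial order.

    Returns None when the order is not series-parallel (contains an
    N-shaped suborder).
    """
    if len(elements) == 1:
        return leaf(labels[elements[0]])
    # parallel split: components of the comparability graph
    component: dict[int, int] = {}
    for e in elements:
        component[e] = e
    def find(e: int) -> int:
        while component[e] != e:
            component[e] = component[component[e]]
            e = component[e]
        return e
    for x, y in lt:
        if x in component and y in component:
            component[find(x)] = find(y)
    groups: dict[int, list[int]] = {}
    for e in elements:
        groups.setdefault(find(e), []).append(e)
    if len(groups) > 1:
        children = [
            _series_parallel_build(g, labels, lt) for g in groups.values()
        ]
        if any(c is None for c in children):
            return None
        return par(*children)
    # series split: scan a linear extension for complete cuts
    order = sorted(
        elements, key=lambda e: (sum((x, e) in lt for x in elements), e)
    )
    blocks: list[list[int]] = []
    current: list[int] = []
    for k, e in enumerate(order):
        current.append(e)
        rest = order[k + 1 :]
        if rest and all((p, q) in lt for p in current for q in rest):
            blocks.append(current)
            current = []
    blocks.append(current)
    if len(blocks) == 1:
        return None  # connected but not series-decomposable: not SP
    children = [_series_parallel_build(b, labels, lt) for b in blocks]
    if any(c is None for c in children):
        return None
    return seq(*children)


def _rewrite_group(rule: Rule, node: VariantNode) -> VariantNode | None:
    """Apply the rule's added order constraints to one parallel group.

    Returns the rebuilt group, or None when the rule does not match, the
    added constraints contradict existing order, or the extended order is
    not series-parallel.
    """
    labels, lt = _group_order(node)
    bound = _bind(rule.source, labels)
    if bound is None:
        return None
    t_labels, t_lt = _target_order_pairs(rule.target)
    # map target occurrences to bound leaves, per label, in DFS order
    by_label_bound: dict[str, list[int]] = {}
    for idx in bound:
        by_label_bound.setdefault(labels[idx], []).append(idx)
    mapping: dict[int, int] = {}
    counters: dict[str, int] = {}
    for t_idx, label in enumerate(t_labels):
        k = counters.get(label, 0)
        counters[label] = k + 1
        mapping[t_idx] = by_label_bound[label][k]
    added = {(mapping[x], mapping[y]) for x, y in t_lt}
    relation = set(lt) | added
    # transitive closure
    n = len(labels)
    changed = True
    while changed:
        changed = False
        for x, y in list(relation):
            for z in range(n):
                if (y, z) in relation and (x, z) not in relation:
                    relation.add((x, z))
                    changed = True
    if any((x, x) in relation for x in range(n)):
        return None  # the rule contradicts order already present
    rebuilt = _series_parallel_build(list(range(n)), labels, relation)
    return rebuilt


def apply_rule(rule: Rule, variant: Variant) -> Variant:
    """Rewrite every matching parallel group once; canonicalize the result.

    Identity when nothing matches. Each match adds the target's order
    constraints to the group's partial order; the leaf multiset is conserved
    and order relations are only added, never removed. A site whose extended
    order would be contradictory or not series-parallel is left unchanged.
    """

    def rewrite(node: VariantNode) -> VariantNode:
        if node.kind == LEAF:
            return node
        children = tuple(rewrite(c) for c in node.children)
        node = VariantNode(kind=node.kind, children=children)
        if node.kind == PAR:
            rebuilt = _rewrite_group(rule, node)
            if rebuilt is not None:
                return rebuilt
        return node

    return Variant(root=rewrite(variant.root))


def apply_rule_to_fixpoint(
    rule: Rule, variant: Variant, cap: int = 100
) -> tuple[Variant, int, bool]:
    """Apply ``rule`` repeatedly until it no longer changes the variant.

    Returns (result, number of rewriting passes, cap-exhausted flag). The
    flag signals a likely rule cycle: the cap was reached and the rule would
    still change the variant.
    """
    passes = 0
    current = variant
    while passes < cap:
        nxt = apply_rule(rule, current)
        if nxt == current:
            return current, passes, False
        current = nxt
        passes += 1
    return current, passes, apply_rule(rule, current) != current


@dataclass(frozen=True)
class RewriteReport:
    """What a rule-set application did to a variant table."""

    per_rule: tuple[dict, ...]
    rewritten: tuple[dict, ...]  # before/after serializations per changed variant
    cap_exhausted: tuple[str, ...]  # rule names that hit the iteration cap

    def to_dict(self) -> dict:
        return {
            "per_rule": list(self.per_rule),
            "rewritten_variants": list(self.rewritten),
            "cap_exhausted": list(self.cap_exhausted),
        }


def apply_ruleset(
    rules: RuleSet, table: VariantTable
) -> tuple[VariantTable, RewriteReport]:
    """Apply rules in order, each to per-variant fixpoint; re-merge the table.

    The total case count is conserved; variants made equal by rewriting are
    merged and their frequencies summed.
    """
    rule_stats = {r.name: {"rule": r.name, "matched_variants": 0, "rewritten_cases": 0} for r in rules}
    rewritten: list[dict] = []
    cap_exhausted: set[str] = set()
    pairs: list[tuple[Variant, Sequence[str]]] = []
    for variant, cases in table:
        current = variant
        for rule in rules:
            result, passes, exhausted = apply_rule_to_fixpoint(
                rule, current, cap=rules.iteration_cap
            )
            if passes > 0:
                rule_stats[rule.name]["matched_variants"] += 1
                rule_stats[rule.name]["rewritten_cases"] += len(cases)
            if exhausted:
                cap_exhausted.add(rule.name)
            current = result
        if current != variant:
            rewritten.append(
                {
                    "before": variant.serialization,
                    "after": current.serialization,
                    "cases": len(cases),
                }
            )
        pairs.append((current, cases))
    report = RewriteReport(
        per_rule=tuple(rule_stats[r.name] for r in rules),
        rewritten=tuple(rewritten),
        cap_exhausted=tuple(sorted(cap_exhausted)),
    )
    return VariantTable.from_pairs(pairs), report
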