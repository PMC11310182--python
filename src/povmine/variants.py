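"""Concurrency-aware trace variants.

A variant is the equivalence class of traces with identical order
relationships among their activity executions. With day-granularity
timestamps, events of one case that share a day are unordered, so a trace
maps to a series-parallel tree: a sequence of day groups in which a
multi-event group is a parallel block. Variants built from raw traces are
therefore two-level (SEQ of LEAF/PAR); deeper nesting arises only from
sequentialization rewriting.

Canonical form makes variant equality decidable by string comparison:
operators are flattened (no SEQ under SEQ, no PAR under PAR), single-child
operators collapse, and PAR children are sorted by their serialization.
The textual form is bit-exact: ``->( 'a', +( 'b', 'c' ) )``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Iterable, Mapping, Sequence

from . import grammar
from .event_log import EventLog, Trace

LEAF = "leaf"
SEQ = "seq"
PAR = "par"


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantNode:
    kind: str
    label: str | None = None
    children: tuple["VariantNode", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == LEAF:
            if not self.label:
                raise VariantError("leaf requires a non-empty label")
            if self.children:
                raise VariantError("leaf may not have children")
        elif self.kind in (SEQ, PAR):
            if self.label is not None:
                raise VariantError("operator node may not carry a label")
        else:
            raise VariantError(f"unknown node kind {self.kind!r}")

    def serialize(self) -> str:
        if self.kind == LEAF:
            return grammar.quote_label(self.label)
        op = grammar.SEQ_TOKEN if self.kind == SEQ else grammar.PAR_TOKEN
        inner = ", ".join(c.serialize() for c in self.children)
        return f"{op}( {inner} )"

    def leaves(self) -> tuple[str, ...]:
        if self.kind == LEAF:
            return (self.label,)
        return tuple(l for c in self.children for l in c.leaves())


def leaf(label: str) -> VariantNode:
    return VariantNode(kind=LEAF, label=label)


def seq(*children: VariantNode) -> VariantNode:
    return VariantNode(kind=SEQ, children=tuple(children))


def par(*children: VariantNode) -> VariantNode:
    return VariantNode(kind=PAR, children=tuple(children))


def canonicalize(node: VariantNode) -> VariantNode:
    """Flatten, collapse single-child operators, sort PAR children.

    Idempotent; two structurally equivalent builds yield identical trees.
    """
    if node.kind == LEAF:
        return node
    children: list[VariantNode] = []
    for child in node.children:
        child = canonicalize(child)
        if child.kind == node.kind:
            children.extend(child.children)
        else:
            children.append(child)
    if len(children) == 1:
        return children[0]
    if not children:
        raise VariantError("operator node must have at least one child")
    if node.kind == PAR:
        children.sort(key=lambda c: (c.serialize().casefold(), c.serialize()))
    return VariantNode(kind=node.kind, children=tuple(children))


@dataclass(frozen=True)
class Variant:
    """A canonicalized series-parallel variant with its induced partial order."""

    root: VariantNode

    def __post_init__(self) -> None:
        object.__setattr__(self, "root", canonicalize(self.root))

    @cached_property
    def serialization(self) -> str:
        return self.root.serialize()

    @cached_property
    def leaves(self) -> tuple[str, ...]:
        """Leaf labels in depth-first order (a linear extension of the order)."""
        return self.root.leaves()

    @property
    def n_events(self) -> int:
        return len(self.leaves)

    @cached_property
    def n_distinct(self) -> int:
        return len(set(self.leaves))

    @cached_property
    def predecessors(self) -> tuple[frozenset[int], ...]:
        """For each leaf index, the set of leaf indices strictly before it."""
        n = self.n_events
        before: list[set[int]] = [set() for _ in range(n)]

        def walk(node: VariantNode, offset: int) -> int:
            if node.kind == LEAF:
                return offset + 1
            starts = []
            end = offset
            for child in node.children:
                starts.append(end)
                end = walk(child, end)
            starts.append(end)
            if node.kind == SEQ:
                for i in range(1, len(node.children)):
                    earlier = range(offset, starts[i])
                    for y in range(starts[i], starts[i + 1]):
                        before[y].update(earlier)
            return end

        walk(self.root, 0)
        return tuple(frozenset(s) for s in before)

    def strictly_before(self, x: int, y: int) -> bool:
        return x in self.predecessors[y]

    def incomparable(self, x: int, y: int) -> bool:
        return (
            x != y
            and x not in self.predecessors[y]
            and y not in self.predecessors[x]
        )

    def first_occurrence(self, label: str) -> int | None:
        for i, l in enumerate(self.leaves):
            if l == label:
                return i
        return None

    def occurrences(self, label: str) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.leaves) if l == label)

    def __eq__(self, other) -> bool:
        return isinstance(other, Variant) and self.serialization == other.serialization

    def __hash__(self) -> int:
        return hash(self.serialization)


def parse_variant(text: str) -> Variant:
    """Parse the bit-exact textual form back into a canonical variant."""
    return Variant(root=node_from_sexpr(grammar.parse(text)))


def node_from_sexpr(sexpr: tuple) -> VariantNode:
    head = sexpr[0]
    if head == "leaf":
        return leaf(sexpr[1])
    if head == grammar.SEQ_TOKEN:
        return seq(*(node_from_sexpr(c) for c in sexpr[1]))
    if head == grammar.PAR_TOKEN:
        return par(*(node_from_sexpr(c) for c in sexpr[1]))
    raise VariantError(f"token {head!r} is not part of the variant grammar")


def variant_of_trace(trace: Trace) -> Variant:
    """Build the variant of a trace: one group per day, groups in day order."""
    if len(trace) == 0:
        raise VariantError(f"trace {trace.case_id!r} has no events")
    groups: list[VariantNode] = []
    for _, day_events in itertools.groupby(trace.events, key=lambda e: e.timestamp):
        members = [leaf(e.activity) for e in day_events]
        groups.append(members[0] if len(members) == 1 else par(*members))
    return Variant(root=groups[0] if len(groups) == 1 else seq(*groups))


def linearizations(node: VariantNode | Variant) -> list[tuple[str, ...]]:
    """All total orders consistent with the variant's partial order.

    Exponential in the worst case; intended for small variants (oracle
    checks and worked examples).
    """
    if isinstance(node, Variant):
        node = node.root

    def shuffle(a: tuple[str, ...], b: tuple[str, ...]) -> set[tuple[str, ...]]:
        if not a:
            return {b}
        if not b:
            return {a}
        return {(a[0],) + w for w in shuffle(a[1:], b)} | {
            (b[0],) + w for w in shuffle(a, b[1:])
        }

    def walk(n: VariantNode) -> set[tuple[str, ...]]:
        if n.kind == LEAF:
            return {(n.label,)}
        if n.kind == SEQ:
            words = {()}
            for child in n.children:
                words = {w + c for w in words for c in walk(child)}
            return words
        words = {()}
        for child in n.children:
            words = {m for w in words for c in walk(child) for m in shuffle(w, c)}
        return words

    return sorted(walk(node))


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantTable:
    """Map from canonical variant to the cases exhibiting it."""

    entries: tuple[tuple[Variant, tuple[str, ...]], ...]

    @property
    def total_cases(self) -> int:
        return sum(len(cases) for _, cases in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def frequency(self, variant: Variant) -> int:
        for v, cases in self.entries:
            if v == variant:
                return len(cases)
        return 0

    def variants(self) -> tuple[Variant, ...]:
        return tuple(v for v, _ in self.entries)

    def by_frequency(self) -> tuple[tuple[Variant, tuple[str, ...]], ...]:
        """Entries sorted by descending frequency, serialization as tie-break."""
        return tuple(
            sorted(
                self.entries,
                key=lambda e: (-len(e[1]), e[0].serialization),
            )
        )

    def to_dict(self) -> dict:
        return {
            v.serialization: {"cases": list(cases), "frequency": len(cases)}
            for v, cases in self.entries
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "VariantTable":
        return cls.from_pairs(
            (parse_variant(text), entry["cases"]) for text, entry in data.items()
        )

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[Variant, Sequence[str]]]
    ) -> "VariantTable":
        merged: dict[str, tuple[Variant, list[str]]] = {}
        for variant, cases in pairs:
            key = variant.serialization
            if key in merged:
                merged[key][1].extend(cases)
            else:
                merged[key] = (variant, list(cases))
        return cls(
            entries=tuple((v, tuple(cases)) for v, cases in merged.values())
        )


def variant_table(log: EventLog) -> VariantTable:
    """Tabulate the variants of a log; frequencies sum to the case count."""
    return VariantTable.from_pairs(
        (variant_of_trace(t), [t.case_id]) for t in log
    )


# ---------------------------------------------------------------------------
# Query predicates
# ---------------------------------------------------------------------------

_CMP: dict[str, Callable[[int, int], bool]] = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


class UnknownLabelError(ValueError):
    pass


@dataclass(frozen=True)
class _Context:
    variant: Variant
    frequency: int
    universe: frozenset[str] | None
    strict: bool

    def check_label(self, label: str) -> bool:
        """True if the label is usable; raise in strict mode when unknown."""
        if self.universe is not None and label not in self.universe:
            if self.strict:
                raise UnknownLabelError(
                    f"label {label!r} is not in the declared activity universe"
                )
            return False
        return True


class Predicate:
    """Boolean query over a variant (and its table frequency).

    Combine with ``&``, ``|`` and ``~``.
    """

    def _eval(self, ctx: _Context) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def __and__(self, other: "Predicate") -> "Predicate":
        return And((self, other))

    def __or__(self, other: "Predicate") -> "Predicate":
        return Or((self, other))

    def __invert__(self) -> "Predicate":
        return Not(self)


@dataclass(frozen=True)
class And(Predicate):
    operands: tuple[Predicate, ...]

    def _eval(self, ctx: _Context) -> bool:
        return all(p._eval(ctx) for p in self.operands)


@dataclass(frozen=True)
class Or(Predicate):
    operands: tuple[Predicate, ...]

    def _eval(self, ctx: _Context) -> bool:
        return any(p._eval(ctx) for p in self.operands)


@dataclass(frozen=True)
class Not(Predicate):
    operand: Predicate

    def _eval(self, ctx: _Context) -> bool:
        return not self.operand._eval(ctx)


@dataclass(frozen=True)
class Contains(Predicate):
    label: str

    def _eval(self, ctx: _Context) -> bool:
        if not ctx.check_label(self.label):
            return False
        return self.label in ctx.variant.leaves


@dataclass(frozen=True)
class PrecedesFirst(Predicate):
    """First occurrence of ``a`` strictly precedes first occurrence of ``b``."""

    a: str
    b: str

    def _eval(self, ctx: _Context) -> bool:
        if not (ctx.check_label(self.a) and ctx.check_label(self.b)):
            return False
        x = ctx.variant.first_occurrence(self.a)
        y = ctx.variant.first_occurrence(self.b)
        if x is None or y is None:
            return False
        return ctx.variant.strictly_before(x, y)


@dataclass(frozen=True)
class ConcurrentAny(Predicate):
    """Some occurrence of ``a`` is incomparable with some occurrence of ``b``."""

    a: str
    b: str

    def _eval(self, ctx: _Context) -> bool:
        if not (ctx.check_label(self.a) and ctx.check_label(self.b)):
            return False
        v = ctx.variant
        return any(
            v.incomparable(x, y)
            for x in v.occurrences(self.a)
            for y in v.occurrences(self.b)
        )


@dataclass(frozen=True)
class NEvents(Predicate):
    cmp: str
    value: int

    def _eval(self, ctx: _Context) -> bool:
        return _CMP[self.cmp](ctx.variant.n_events, self.value)


@dataclass(frozen=True)
class NDistinct(Predicate):
    cmp: str
    value: int

    def _eval(self, ctx: _Context) -> bool:
        return _CMP[self.cmp](ctx.variant.n_distinct, self.value)


@dataclass(frozen=True)
class Frequency(Predicate):
    cmp: str
    value: int

    def _eval(self, ctx: _Context) -> bool:
        return _CMP[self.cmp](ctx.frequency, self.value)


def evaluate_predicate(
    pred: Predicate,
    variant: Variant,
    frequency: int = 0,
    universe: Iterable[str] | None = None,
    strict: bool = False,
) -> bool:
    """Evaluate ``pred`` on a variant.

    Precedence and concurrency atoms use the variant's partial order: two
    executions are ordered iff their lowest common ancestor in the
    series-parallel tree is a sequence node. In strict mode an atom naming
    a label outside ``universe`` raises; otherwise the atom is false.
    """
    ctx = _Context(
        variant=variant,
        frequency=frequency,
        universe=frozenset(universe) if universe is not None else None,
        strict=strict,
    )
    return pred._eval(ctx)


_ATOMS: dict[str, Callable[..., Predicate]] = {
    "contains": lambda d: Contains(d["label"]),
    "precedes_first": lambda d: PrecedesFirst(d["a"], d["b"]),
    "concurrent_any": lambda d: ConcurrentAny(d["a"], d["b"]),
    "n_events": lambda d: NEvents(d["cmp"], int(d["value"])),
    "n_distinct": lambda d: NDistinct(d["cmp"], int(d["value"])),
    "frequency": lambda d: Frequency(d["cmp"], int(d["value"])),
}


def predicate_from_dict(config: Mapping) -> Predicate:
    """Build a predicate from nested config (``all`` / ``any`` / ``not`` / ``atom``)."""
    if "all" in config:
        return And(tuple(predicate_from_dict(c) for c in config["all"]))
    if "any" in config:
        return Or(tuple(predicate_from_dict(c) for c in config["any"]))
    if "not" in config:
        return Not(predicate_from_dict(config["not"]))
    if "atom" in config:
        name = config["atom"]
        if name not in _ATOMS:
            raise VariantError(f"unknown predicate atom {name!r}")
        return _ATOMS[name](config)
    raise VariantError(f"cannot interpret predicate config {config!r}")


#: Invasive diagnostic procedures and the non-invasive exams that clinical
#: guidelines require first.
DEFAULT_INVASIVE = ("Biopsy", "Bronchoscopy")
DEFAULT_NONINVASIVE = ("X-ray", "CT scan")


def guideline_violation_predicate(
    invasive: Sequence[str] = DEFAULT_INVASIVE,
    noninvasive: Sequence[str] = DEFAULT_NONINVASIVE,
) -> Predicate:
    """Variants where an invasive procedure precedes a non-invasive exam."""
    return Or(
        tuple(
            PrecedesFirst(a, b)
            for a in invasive
            for b in noninvasive
        )
    )


def noise_predicate(
    max_short_length: int = 2,
    invasive: Sequence[str] = DEFAULT_INVASIVE,
    noninvasive: Sequence[str] = DEFAULT_NONINVASIVE,
) -> Predicate:
    """The shipped data-quality filter.

    Flags truncated variants (at most ``max_short_length`` events),
    single-activity variants (one label, possibly repeated; implausible
    hospitalizations) and guideline-order violations.
    """
    return Or(
        (
            NEvents("<=", max_short_length),
            NDistinct("<=", 1),
            guideline_violation_predicate(invasive, noninvasive),
        )
    )


def filter_variant_table(
    table: VariantTable,
    pred: Predicate,
    mode: str = "remove",
    universe: Iterable[str] | None = None,
    strict: bool = False,
) -> tuple[VariantTable, dict]:
    """Keep or remove the entries matching ``pred``; report what was removed."""
    if mode not in ("keep", "remove"):
        raise VariantError(f"mode must be 'keep' or 'remove', got {mode!r}")
    kept, removed = [], []
    for variant, cases in table:
        matches = evaluate_predicate(
            pred, variant, frequency=len(cases), universe=universe, strict=strict
        )
        target = kept if matches == (mode == "keep") else removed
        target.append((variant, cases))
    total = table.total_cases
    removed_cases = sum(len(c) for _, c in removed)
    report = {
        "mode": mode,
        "removed_variants": [
            {"variant": v.serialization, "frequency": len(c), "cases": list(c)}
            for v, c in removed
        ],
        "n_removed_variants": len(removed),
        "n_removed_cases": removed_cases,
        "fraction_cases_removed": (removed_cases / total) if total else 0.0,
    }
    return VariantTable(entries=tuple(kept)), report
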