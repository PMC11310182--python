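"""Process trees: representation, language semantics, fitness, discovery.

A process tree is a block-structured model with operators sequence, choice,
parallel (interleaving) and loop, activity leaves and the silent step tau.
Its language is a set of sequential words. Conformance of a
concurrency-aware variant is boolean: the variant fits iff SOME
linearization of its partial order is a word of the tree — day-granularity
timestamps carry no intra-day order, so they cannot contradict an order the
model imposes.

Membership and fitting are decided exactly by an operational semantics: a
tree configuration records execution progress per node, and a synchronized
search couples configurations with the variant's partial-order state. No
linearizations are ever materialized.

Incremental discovery maintains the invariant that every incorporated
variant fits the current tree. The baseline strategy augments the root with
a choice branch for a non-fitting variant and then applies
language-preserving reduction; subtrees can be frozen, and frozen subtrees
survive any number of incorporation steps verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from . import grammar
from .variants import (
    LEAF,
    PAR,
    SEQ,
    Variant,
    VariantNode,
    VariantTable,
)

ACTIVITY = "activity"
TAU = "tau"
PT_SEQ = "pt_seq"
PT_XOR = "pt_xor"
PT_PAR = "pt_par"
PT_LOOP = "pt_loop"

_OP_TOKEN = {
    PT_SEQ: grammar.SEQ_TOKEN,
    PT_XOR: grammar.XOR_TOKEN,
    PT_PAR: grammar.PAR_TOKEN,
    PT_LOOP: grammar.LOOP_TOKEN,
}
_TOKEN_OP = {v: k for k, v in _OP_TOKEN.items()}


class ModelError(ValueError):
    pass


class CapacityError(RuntimeError):
    """The input exceeds the configured safety bound; no answer is computed."""


class FrozenSubtreeError(ValueError):
    """Refusal to edit inside a frozen region of the model."""


@dataclass(frozen=True)
class ProcessTree:
    kind: str
    label: str | None = None
    children: tuple["ProcessTree", ...] = ()
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.kind == ACTIVITY:
            if not self.label:
                raise ModelError("activity leaf requires a non-empty label")
            if self.children:
                raise ModelError("activity leaf may not have children")
        elif self.kind == TAU:
            if self.label or self.children:
                raise ModelError("tau has neither label nor children")
        elif self.kind in (PT_SEQ, PT_XOR, PT_PAR):
            if not self.children:
                raise ModelError("operator node requires at least one child")
            if self.label is not None:
                raise ModelError("operator node may not carry a label")
        elif self.kind == PT_LOOP:
            if len(self.children) != 2:
                raise ModelError("loop requires exactly (do, redo) children")
        else:
            raise ModelError(f"unknown node kind {self.kind!r}")

    def serialize(self) -> str:
        if self.kind == ACTIVITY:
            return grammar.quote_label(self.label)
        if self.kind == TAU:
            return grammar.TAU_TOKEN
        inner = ", ".join(c.serialize() for c in self.children)
        return f"{_OP_TOKEN[self.kind]}( {inner} )"

    def subtree(self, path: Sequence[int]) -> "ProcessTree":
        node = self
        for i in path:
            try:
                node = node.children[i]
            except IndexError as exc:
                raise ModelError(f"invalid path {tuple(path)}") from exc
        return node

    def labels(self) -> frozenset[str]:
        if self.kind == ACTIVITY:
            return frozenset((self.label,))
        return frozenset(l for c in self.children for l in c.labels())


def activity(label: str) -> ProcessTree:
    return ProcessTree(kind=ACTIVITY, label=label)


def tau() -> ProcessTree:
    return ProcessTree(kind=TAU)


def pt_seq(*children: ProcessTree) -> ProcessTree:
    return ProcessTree(kind=PT_SEQ, children=tuple(children))


def pt_xor(*children: ProcessTree) -> ProcessTree:
    return ProcessTree(kind=PT_XOR, children=tuple(children))


def pt_par(*children: ProcessTree) -> ProcessTree:
    return ProcessTree(kind=PT_PAR, children=tuple(children))


def pt_loop(do: ProcessTree, redo: ProcessTree | None = None) -> ProcessTree:
    """Loop: do, then any number of (redo, do) rounds. Default redo is tau."""
    return ProcessTree(kind=PT_LOOP, children=(do, redo if redo is not None else tau()))


def serialize_tree(tree: ProcessTree) -> str:
    return tree.serialize()


def parse_tree(text: str) -> ProcessTree:
    """Parse the textual grammar: ``->(…)``, ``X(…)``, ``+(…)``, ``*(do, redo)``."""

    def build(sexpr: tuple) -> ProcessTree:
        head = sexpr[0]
        if head == "leaf":
            return activity(sexpr[1])
        if head == "tau":
            return tau()
        if head == "wildcard":
            raise ModelError("wildcard is not part of the process-tree grammar")
        kind = _TOKEN_OP[head]
        children = tuple(build(c) for c in sexpr[1])
        if kind == PT_LOOP and len(children) == 1:
            children = (children[0], tau())
        return ProcessTree(kind=kind, children=children)

    return build(grammar.parse(text))


# ---------------------------------------------------------------------------
# Operational semantics
# ---------------------------------------------------------------------------
#
# A configuration is a nested hashable value mirroring the tree:
#   ACTIVITY: 0 (pending) | 1 (executed)      TAU: 1
#   SEQ:  (i, child cfg)      XOR: ("?",) undecided | (j, child cfg)
#   PAR:  tuple of child cfgs LOOP: ("do"|"redo", child cfg)


def _nullable(tree: ProcessTree) -> bool:
    if tree.kind == ACTIVITY:
        return False
    if tree.kind == TAU:
        return True
    if tree.kind == PT_SEQ or tree.kind == PT_PAR:
        return all(_nullable(c) for c in tree.children)
    if tree.kind == PT_XOR:
        return any(_nullable(c) for c in tree.children)
    return _nullable(tree.children[0])  # loop: the do part runs at least once


def _init(tree: ProcessTree):
    if tree.kind in (ACTIVITY, TAU):
        return 0 if tree.kind == ACTIVITY else 1
    if tree.kind == PT_SEQ:
        return (0, _init(tree.children[0]))
    if tree.kind == PT_XOR:
        return ("?",)
    if tree.kind == PT_PAR:
        return tuple(_init(c) for c in tree.children)
    return ("do", _init(tree.children[0]))


def _done(tree: ProcessTree, cfg) -> bool:
    if tree.kind == ACTIVITY:
        return cfg == 1
    if tree.kind == TAU:
        return True
    if tree.kind == PT_SEQ:
        i, ci = cfg
        return _done(tree.children[i], ci) and all(
            _nullable(c) for c in tree.children[i + 1 :]
        )
    if tree.kind == PT_XOR:
        if cfg == ("?",):
            return any(_nullable(c) for c in tree.children)
        j, cj = cfg
        return _done(tree.children[j], cj)
    if tree.kind == PT_PAR:
        return all(_done(c, cc) for c, cc in zip(tree.children, cfg))
    phase, cc = cfg
    if phase == "do":
        return _done(tree.children[0], cc)
    return _done(tree.children[1], cc) and _nullable(tree.children[0])


def _steps(tree: ProcessTree, cfg) -> list[tuple[str, object]]:
    """All (label, successor configuration) moves from ``cfg``."""
    if tree.kind == ACTIVITY:
        return [(tree.label, 1)] if cfg == 0 else []
    if tree.kind == TAU:
        return []
    if tree.kind == PT_SEQ:
        out = []
        i, ci = cfg
        while True:
            child = tree.children[i]
            out.extend((l, (i, c2)) for l, c2 in _steps(child, ci))
            if _done(child, ci) and i + 1 < len(tree.children):
                i, ci = i + 1, _init(tree.children[i + 1])
            else:
                return out
    if tree.kind == PT_XOR:
        if cfg == ("?",):
            return [
                (l, (j, c2))
                for j, child in enumerate(tree.children)
                for l, c2 in _steps(child, _init(child))
            ]
        j, cj = cfg
        return [(l, (j, c2)) for l, c2 in _steps(tree.children[j], cj)]
    if tree.kind == PT_PAR:
        out = []
        for idx, (child, cc) in enumerate(zip(tree.children, cfg)):
            for l, c2 in _steps(child, cc):
                out.append((l, cfg[:idx] + (c2,) + cfg[idx + 1 :]))
        return out
    # loop: expand silently through completed do/redo rounds (guarded: the
    # round-switch can revisit configurations when both parts are nullable)
    out = []
    stack, seen = [cfg], {cfg}
    while stack:
        phase, cc = stack.pop()
        child = tree.children[0 if phase == "do" else 1]
        out.extend((l, (phase, c2)) for l, c2 in _steps(child, cc))
        if _done(child, cc):
            nxt = (
                ("redo", _init(tree.children[1]))
                if phase == "do"
                else ("do", _init(tree.children[0]))
            )
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return out


def word_in_language(tree: ProcessTree, word: Sequence[str]) -> bool:
    """Exact membership of a sequential word in the tree's language."""
    states = {_init(tree)}
    for symbol in word:
        states = {c2 for c in states for l, c2 in _steps(tree, c) if l == symbol}
        if not states:
            return False
    return any(_done(tree, c) for c in states)


#: Above this many events, fits_variant refuses rather than risk blow-up.
DEFAULT_EVENT_BOUND = 400


def fits_variant(
    tree: ProcessTree, variant: Variant, event_bound: int = DEFAULT_EVENT_BOUND
) -> bool:
    """True iff some linearization of the variant is in the tree's language.

    Synchronized search over (set of executed variant events × tree
    configuration) with memoization of failed states; exact, and never
    enumerates linearizations.
    """
    n = variant.n_events
    if n > event_bound:
        raise CapacityError(
            f"variant has {n} events, above the safety bound {event_bound}"
        )
    labels = variant.leaves
    preds = variant.predecessors
    failed: set[tuple[frozenset[int], object]] = set()

    def search(executed: frozenset[int], cfg) -> bool:
        if len(executed) == n:
            return _done(tree, cfg)
        key = (executed, cfg)
        if key in failed:
            return False
        by_label: dict[str, list] = {}
        for l, c2 in _steps(tree, cfg):
            by_label.setdefault(l, []).append(c2)
        tried_labels: set[str] = set()
        for y in range(n):
            if y in executed or not preds[y] <= executed:
                continue
            l = labels[y]
            for c2 in by_label.get(l, ()):
                if search(executed | {y}, c2):
                    return True
        failed.add(key)
        return False

    return search(frozenset(), _init(tree))


@dataclass(frozen=True)
class FitnessResult:
    """Case-weighted boolean conformance of a variant table against a model."""

    fitting_cases: int
    total_cases: int
    per_variant: tuple[tuple[str, bool], ...]

    @property
    def fitness(self) -> float:
        return self.fitting_cases / self.total_cases

    @property
    def percent(self) -> float:
        return 100.0 * self.fitness


def fitness(tree: ProcessTree, table: VariantTable) -> FitnessResult:
    """Fraction of cases whose variant admits an accepted linearization."""
    if len(table) == 0:
        raise ModelError("fitness is undefined on an empty variant table")
    fitting = 0
    flags = []
    for variant, cases in table:
        ok = fits_variant(tree, variant)
        flags.append((variant.serialization, ok))
        if ok:
            fitting += len(cases)
    return FitnessResult(
        fitting_cases=fitting,
        total_cases=table.total_cases,
        per_variant=tuple(flags),
    )


def variant_as_tree(variant: Variant | VariantNode) -> ProcessTree:
    """A tree whose language is exactly the variant's linearization set."""
    node = variant.root if isinstance(variant, Variant) else variant
    if node.kind == LEAF:
        return activity(node.label)
    children = tuple(variant_as_tree(c) for c in node.children)
    return ProcessTree(kind=PT_SEQ if node.kind == SEQ else PT_PAR, children=children)


# ---------------------------------------------------------------------------
# Editing, freezing, reduction
# ---------------------------------------------------------------------------


def replace_subtree(
    tree: ProcessTree, path: Sequence[int], replacement: ProcessTree
) -> ProcessTree:
    """Swap the subtree at ``path``; refuses to touch a frozen region."""
    path = tuple(path)
    node = tree
    for i in path:
        if node.frozen:
            raise FrozenSubtreeError(
                f"cannot edit inside frozen subtree {node.serialize()}"
            )
        node = node.subtree((i,))
    if node.frozen:
        raise FrozenSubtreeError(f"subtree at {path} is frozen")

    def rebuild(node: ProcessTree, path: tuple[int, ...]) -> ProcessTree:
        if not path:
            return replacement
        i = path[0]
        if i >= len(node.children):
            raise ModelError(f"invalid path component {i} at {node.serialize()}")
        children = list(node.children)
        children[i] = rebuild(children[i], path[1:])
        return replace(node, children=tuple(children))

    return rebuild(tree, path)


def freeze_subtree(tree: ProcessTree, path: Sequence[int]) -> ProcessTree:
    """Mark the subtree at ``path`` immutable for discovery and reduction."""
    target = tree.subtree(path)
    frozen = replace(target, frozen=True)

    def rebuild(node: ProcessTree, path: tuple[int, ...]) -> ProcessTree:
        if not path:
            return frozen
        children = list(node.children)
        children[path[0]] = rebuild(children[path[0]], path[1:])
        return replace(node, children=tuple(children))

    return rebuild(tree, tuple(path))


def frozen_subtrees(tree: ProcessTree) -> tuple[str, ...]:
    """Serializations of all frozen-rooted subtrees."""
    found = []

    def walk(node: ProcessTree) -> None:
        if node.frozen:
            found.append(node.serialize())
            return
        for c in node.children:
            walk(c)

    walk(tree)
    return tuple(found)


def contains_subtree(tree: ProcessTree, target: ProcessTree) -> bool:
    """Structural (serialization) occurrence of ``target`` within ``tree``."""
    wanted = target.serialize()

    def walk(node: ProcessTree) -> bool:
        if node.serialize() == wanted:
            return True
        return any(walk(c) for c in node.children)

    return walk(tree)


def reduce_tree(tree: ProcessTree) -> ProcessTree:
    """Language-preserving cleanup.

    Flattens nested SEQ/XOR/PAR, drops tau from a SEQ that has another
    child, deduplicates identical XOR branches and collapses single-child
    operators. Frozen subtrees are opaque: they are neither rewritten nor
    spliced into their parents.
    """
    if tree.frozen or tree.kind in (ACTIVITY, TAU):
        return tree
    children = [reduce_tree(c) for c in tree.children]
    if tree.kind == PT_LOOP:
        return replace(tree, children=tuple(children))
    if tree.kind in (PT_SEQ, PT_XOR, PT_PAR):
        flat: list[ProcessTree] = []
        for c in children:
            if c.kind == tree.kind and not c.frozen:
                flat.extend(c.children)
            else:
                flat.append(c)
        children = flat
    if tree.kind == PT_SEQ:
        non_tau = [c for c in children if c.kind != TAU or c.frozen]
        # all-silent sequence collapses to a single tau
        children = non_tau if non_tau else [children[0]]
    if tree.kind == PT_XOR:
        seen: dict[str, ProcessTree] = {}
        for c in children:
            key = c.serialize()
            if key not in seen or (c.frozen and not seen[key].frozen):
                seen[key] = c
        children = list(seen.values())
    if len(children) == 1 and not children[0].frozen:
        return children[0]
    return replace(tree, children=tuple(children))


# ---------------------------------------------------------------------------
# Incremental discovery
# ---------------------------------------------------------------------------

#: A strategy takes (current tree, non-fitting variant) and returns a tree in
#: which the variant fits, all prior behaviour is retained and frozen
#: subtrees are preserved verbatim.
Strategy = Callable[[ProcessTree, Variant], ProcessTree]


def xor_augmentation(tree: ProcessTree, variant: Variant) -> ProcessTree:
    """Baseline: add the variant's own tree as a new choice branch."""
    return reduce_tree(pt_xor(tree, variant_as_tree(variant)))


@dataclass(frozen=True)
class DiscoveryState:
    """Evolving model plus the variants guaranteed to fit it."""

    tree: ProcessTree
    incorporated: tuple[Variant, ...] = ()


def discover_initial(variants: Sequence[Variant]) -> DiscoveryState:
    """Start a model from one or more variants; all of them fit it."""
    unique: list[Variant] = []
    for v in variants:
        if v not in unique:
            unique.append(v)
    if not unique:
        raise ModelError("discover_initial requires at least one variant")
    if len(unique) == 1:
        tree = variant_as_tree(unique[0])
    else:
        tree = pt_xor(*(variant_as_tree(v) for v in unique))
    return DiscoveryState(tree=tree, incorporated=tuple(unique))


def add_variant(
    state: DiscoveryState,
    variant: Variant,
    strategy: Strategy = xor_augmentation,
    validate: bool = False,
) -> DiscoveryState:
    """Incorporate a variant; every previously incorporated variant keeps
    fitting, and frozen subtrees are untouched."""
    if variant in state.incorporated or fits_variant(state.tree, variant):
        if variant in state.incorporated:
            return state
        return DiscoveryState(
            tree=state.tree, incorporated=state.incorporated + (variant,)
        )
    new_tree = strategy(state.tree, variant)
    if validate:
        for frozen in frozen_subtrees(state.tree):
            if frozen not in frozen_subtrees(new_tree):
                raise ModelError(
                    f"strategy violated freezing: {frozen} not preserved"
                )
        for v in state.incorporated + (variant,):
            if not fits_variant(new_tree, v):
                raise ModelError(
                    f"strategy violated the fit guarantee for {v.serialization}"
                )
    return DiscoveryState(
        tree=new_tree, incorporated=state.incorporated + (variant,)
    )
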