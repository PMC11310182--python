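"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's optimized code paths:
linearizations are enumerated straight from the variant's precedence
relation (topological orders), so agreement with the synchronized-search
and tree-walk implementations is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from povmine import examples
from povmine.model import (
    ProcessTree,
    activity,
    pt_loop,
    pt_par,
    pt_seq,
    pt_xor,
    tau,
)
from povmine.variants import Variant, VariantNode, leaf, par, seq


@pytest.fixture
def excerpt_log():
    return examples.excerpt_log()


def topo_linearizations(variant: Variant) -> set[tuple[str, ...]]:
    """All linearizations, enumerated from the precedence relation alone."""
    preds = variant.predecessors
    labels = variant.leaves
    n = len(labels)
    out: set[tuple[str, ...]] = set()

    def extend(done: frozenset[int], word: tuple[str, ...]) -> None:
        if len(done) == n:
            out.add(word)
            return
        for i in range(n):
            if i not in done and preds[i] <= done:
                extend(done | {i}, word + (labels[i],))

    extend(frozenset(), ())
    return out


def random_variant(
    rng: np.random.Generator,
    labels: tuple[str, ...] = ("a", "b", "c", "d"),
    max_events: int = 8,
    nested: bool = True,
) -> Variant:
    """A random series-parallel variant with at most ``max_events`` leaves.

    Group sizes are kept small so exhaustive linearization stays cheap.
    """
    budget = int(rng.integers(1, max_events + 1))
    groups: list[VariantNode] = []
    while budget > 0:
        size = int(min(budget, rng.integers(1, 4)))
        members = [
            leaf(str(rng.choice(np.asarray(labels, dtype=object))))
            for _ in range(size)
        ]
        if size == 1:
            groups.append(members[0])
        elif nested and size >= 3 and rng.random() < 0.3:
            # nested shape as produced by sequentialization rewriting
            groups.append(par(seq(members[0], members[1]), *members[2:]))
        else:
            groups.append(par(*members))
        budget -= size
    return Variant(root=groups[0] if len(groups) == 1 else seq(*groups))


def random_process_tree(
    rng: np.random.Generator,
    labels: tuple[str, ...] = ("a", "b", "c", "d"),
    max_depth: int = 3,
) -> ProcessTree:
    """A random process tree over a small alphabet."""

    def build(depth: int) -> ProcessTree:
        if depth >= max_depth or rng.random() < 0.4:
            if rng.random() < 0.1:
                return tau()
            return activity(str(rng.choice(np.asarray(labels, dtype=object))))
        op = rng.integers(4)
        if op == 3:
            return pt_loop(build(depth + 1), build(depth + 1))
        n_children = int(rng.integers(2, 4))
        children = [build(depth + 1) for _ in range(n_children)]
        ctor = (pt_seq, pt_xor, pt_par)[int(op)]
        return ctor(*children)

    return build(0)
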