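"""Variant construction, canonical form, tabulation and query predicates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_variant, topo_linearizations
from povmine import examples
from povmine.event_log import Trace
from povmine.variants import (
    ConcurrentAny,
    Contains,
    NDistinct,
    NEvents,
    PrecedesFirst,
    UnknownLabelError,
    Variant,
    VariantError,
    VariantTable,
    canonicalize,
    evaluate_predicate,
    filter_variant_table,
    leaf,
    linearizations,
    noise_predicate,
    par,
    parse_variant,
    predicate_from_dict,
    seq,
    variant_of_trace,
    variant_table,
)


class TestConstruction:
    def test_same_day_groups_become_parallel(self, excerpt_log):
        v = variant_of_trace(excerpt_log["47777"])
        root = v.root
        assert root.kind == "seq"
        assert len(root.children) == 6
        assert root.children[0].label == "GPE"
        group = root.children[1]
        assert group.kind == "par"
        assert sorted(c.label for c in group.children) == [
            "CTC",
            "Cal",
            "Cre",
            "Glu",
            "LiB",
            "Mag",
        ]
        # repeated same-day executions stay distinct
        assert [c.label for c in root.children[4].children] == ["ONOP", "ONOP"]

    def test_three_block_case(self, excerpt_log):
        v = variant_of_trace(excerpt_log["25480"])
        assert v.serialization == (
            "->( +( 'Cal', 'ChX', 'Cre', 'Glu', 'GPE', 'Mag' ), 'Spi', 'GPE' )"
        )

    def test_single_event_trace_is_a_leaf(self, excerpt_log):
        e = excerpt_log["25480"].events[0]
        v = variant_of_trace(Trace(case_id=e.case_id, events=(e,)))
        assert v.root.kind == "leaf"
        assert v.n_events == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(VariantError, match="no events"):
            variant_of_trace(Trace(case_id="x", events=()))

    def test_leaf_multiset_is_conserved(self, excerpt_log):
        for trace in excerpt_log:
            v = variant_of_trace(trace)
            assert sorted(v.leaves) == sorted(trace.activities)


class TestCanonicalForm:
    def test_parallel_children_are_sorted(self):
        assert canonicalize(par(leaf("b"), leaf("a"))).serialize() == "+( 'a', 'b' )"

    def test_nested_sequences_flatten(self):
        node = seq(seq(leaf("a"), leaf("b")), leaf("c"))
        assert canonicalize(node).serialize() == "->( 'a', 'b', 'c' )"

    def test_canonicalize_idempotent(self):
        node = seq(par(leaf("b"), leaf("a")), seq(leaf("c"), leaf("d")))
        once = canonicalize(node)
        assert canonicalize(once) == once

    def test_serialization_round_trip(self, excerpt_log):
        v = variant_of_trace(excerpt_log["47777"])
        assert parse_variant(v.serialization) == v

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_same_day_row_order_is_not_semantic(self, rnd):
        """Permuting same-day rows of a trace never changes the variant."""
        log = examples.excerpt_log()
        trace = log["47777"]
        by_day: dict = {}
        for e in trace.events:
            by_day.setdefault(e.timestamp, []).append(e)
        shuffled = []
        for day in sorted(by_day):
            events = list(by_day[day])
            rnd.shuffle(events)
            shuffled.extend(events)
        permuted = Trace(case_id=trace.case_id, events=tuple(shuffled))
        assert variant_of_trace(permuted) == variant_of_trace(trace)


class TestVariantTable:
    def test_equal_variants_merge(self, excerpt_log):
        trace = excerpt_log["25480"]
        twin = Trace(
            case_id="99999",
            events=tuple(
                type(e)(
                    case_id="99999",
                    activity=e.activity,
                    timestamp=e.timestamp,
                    category=e.category,
                )
                for e in trace.events[::-1][-6:][::-1] + trace.events[6:]
            ),
        )
        # twin permutes the first same-day group but keeps dates
        table = VariantTable.from_pairs(
            [
                (variant_of_trace(trace), ["25480"]),
                (variant_of_trace(twin), ["99999"]),
            ]
        )
        assert len(table) == 1
        assert table.total_cases == 2

    def test_excerpt_gives_two_entries(self, excerpt_log):
        table = variant_table(excerpt_log)
        assert len(table) == 2
        assert table.total_cases == 2

    def test_frequencies_sum_to_cases(self):
        rng = np.random.default_rng(7)
        pairs = [
            (random_variant(rng), [f"c{i}"])
            for i in range(30)
        ]
        table = VariantTable.from_pairs(pairs)
        assert table.total_cases == 30

    def test_json_round_trip(self, excerpt_log):
        table = variant_table(excerpt_log)
        assert VariantTable.from_dict(table.to_dict()).to_dict() == table.to_dict()


class TestPredicates:
    def test_precedes_first_on_violation_shape(self):
        v = parse_variant("->( 'LiB', 'GPE', 'CTC' )")
        assert evaluate_predicate(PrecedesFirst("LiB", "CTC"), v)
        assert not evaluate_predicate(PrecedesFirst("CTC", "LiB"), v)

    def test_concurrent_in_parallel_group(self, excerpt_log):
        v = variant_of_trace(excerpt_log["47777"])
        assert evaluate_predicate(ConcurrentAny("CTC", "LiB"), v)
        assert not evaluate_predicate(PrecedesFirst("CTC", "LiB"), v)
        assert evaluate_predicate(PrecedesFirst("GPE", "CTC"), v)

    def test_contains_missing_label_false(self):
        v = parse_variant("->( 'a', 'b' )")
        assert not evaluate_predicate(Contains("z"), v)

    def test_strict_mode_rejects_unknown_labels(self):
        v = parse_variant("->( 'a', 'b' )")
        with pytest.raises(UnknownLabelError):
            evaluate_predicate(
                Contains("z"), v, universe={"a", "b"}, strict=True
            )
        assert not evaluate_predicate(Contains("z"), v, universe={"a", "b"})

    def test_combinators_and_count_atoms(self):
        v = parse_variant("->( 'a', +( 'b', 'b' ) )")
        pred = Contains("a") & NEvents("==", 3) & NDistinct("==", 2)
        assert evaluate_predicate(pred, v)
        assert not evaluate_predicate(~Contains("a"), v)

    def test_predicate_from_dict(self):
        config = {
            "any": [
                {"atom": "n_events", "cmp": "<=", "value": 2},
                {"atom": "precedes_first", "a": "Biopsy", "b": "CT scan"},
            ]
        }
        pred = predicate_from_dict(config)
        assert evaluate_predicate(pred, parse_variant("->( 'x', 'y' )"))
        assert not evaluate_predicate(
            pred, parse_variant("->( 'x', 'y', 'z' )")
        )

    def test_order_atoms_agree_with_linearization_oracle(self):
        """On single-occurrence labels, a<b iff a precedes b in every
        linearization, and concurrency iff the order varies."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(120):
            v = random_variant(rng, labels=("a", "b", "c", "d", "e", "f"))
            labels = v.leaves
            singles = [l for l in set(labels) if labels.count(l) == 1]
            if len(singles) < 2:
                continue
            words = topo_linearizations(v)
            a, b = singles[0], singles[1]
            always_before = all(w.index(a) < w.index(b) for w in words)
            order_varies = not always_before and any(
                w.index(a) < w.index(b) for w in words
            )
            assert evaluate_predicate(PrecedesFirst(a, b), v) == always_before
            assert evaluate_predicate(ConcurrentAny(a, b), v) == order_varies
            checked += 1
        assert checked > 50

    def test_linearizations_match_toposort_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            v = random_variant(rng)
            assert set(linearizations(v)) == topo_linearizations(v)


class TestTableFilter:
    def test_remove_short_variants_reports_fraction(self):
        v1 = parse_variant("'only'")
        v2 = parse_variant("->( 'a', 'b', 'c', 'd', 'e' )")
        table = VariantTable.from_pairs(
            [(v1, [f"s{i}" for i in range(3)]), (v2, [f"l{i}" for i in range(7)])]
        )
        out, report = filter_variant_table(table, NEvents("<=", 2), mode="remove")
        assert out.variants() == (v2,)
        assert report["fraction_cases_removed"] == pytest.approx(0.3)

    def test_never_true_predicate_is_identity(self, excerpt_log):
        table = variant_table(excerpt_log)
        out, report = filter_variant_table(table, NEvents("<", 0), mode="remove")
        assert out.to_dict() == table.to_dict()
        assert report["n_removed_variants"] == 0

    def test_injected_violation_is_removed(self):
        clean = [
            parse_variant("->( 'X-ray', 'CT scan', 'Biopsy', 'Surgery' )"),
            parse_variant("->( 'X-ray', +( 'CT scan', 'Lab' ), 'Surgery' )"),
            parse_variant("->( 'CT scan', 'Bronchoscopy', 'Surgery', 'ONOP' )"),
            parse_variant("->( 'X-ray', 'Surgery', 'ONOP', 'Lab' )"),
        ]
        bad = parse_variant("->( 'Biopsy', 'X-ray', 'CT scan', 'Surgery' )")
        table = VariantTable.from_pairs(
            [(v, [f"c{i}"]) for i, v in enumerate(clean)] + [(bad, ["v0"])]
        )
        pred = PrecedesFirst("Biopsy", "X-ray") | PrecedesFirst(
            "Bronchoscopy", "X-ray"
        )
        out, report = filter_variant_table(table, pred, mode="remove")
        assert len(out) == 4
        assert report["removed_variants"][0]["variant"] == bad.serialization

    def test_noise_predicate_flags_all_three_shapes(self):
        assert evaluate_predicate(noise_predicate(), parse_variant("->( 'a', 'b' )"))
        assert evaluate_predicate(
            noise_predicate(), parse_variant("->( 'a', 'a', 'a' )")
        )
        assert evaluate_predicate(
            noise_predicate(),
            parse_variant("->( 'Biopsy', 'X-ray', 'c', 'd' )"),
        )
        assert not evaluate_predicate(
            noise_predicate(),
            parse_variant("->( 'X-ray', 'Biopsy', 'c', 'd' )"),
        )
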