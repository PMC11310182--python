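"""Process-tree semantics, fitness, editing and incremental discovery."""

import itertools

import numpy as np
import pytest

from conftest import random_process_tree, random_variant, topo_linearizations
from povmine.model import (
    DiscoveryState,
    FrozenSubtreeError,
    ModelError,
    ProcessTree,
    activity,
    add_variant,
    contains_subtree,
    discover_initial,
    fitness,
    fits_variant,
    freeze_subtree,
    frozen_subtrees,
    parse_tree,
    pt_loop,
    pt_par,
    pt_seq,
    pt_xor,
    reduce_tree,
    replace_subtree,
    serialize_tree,
    tau,
    variant_as_tree,
    word_in_language,
)
from povmine.variants import Variant, VariantTable, parse_variant

EXAMPLE_TREE = (
    "->( 'Biopsy', +( 'Spi', 'GPE', *( 'LabTest', tau ) ), "
    "+( 'OpChestWall', 'X-ray' ), 'RemovalTherAppl' )"
)


def _language_upto(tree: ProcessTree, alphabet: tuple[str, ...], max_len: int):
    """Exhaustive accepted-word set: the enumeration oracle."""
    words = set()
    for n in range(max_len + 1):
        for word in itertools.product(alphabet, repeat=n):
            if word_in_language(tree, word):
                words.add(word)
    return words


class TestSerialization:
    def test_example_tree_round_trips(self):
        tree = parse_tree(EXAMPLE_TREE)
        assert serialize_tree(tree) == EXAMPLE_TREE
        assert tree.kind == "pt_seq"
        loop = tree.children[1].children[2]
        assert loop.kind == "pt_loop"
        assert loop.children[1].kind == "tau"

    def test_single_activity(self):
        assert serialize_tree(parse_tree("'a'")) == "'a'"

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tree = random_process_tree(rng)
            assert parse_tree(serialize_tree(tree)) == tree

    def test_malformed_text_reports_position(self):
        from povmine.grammar import ParseError

        with pytest.raises(ParseError, match="position"):
            parse_tree("->( 'a', ")


class TestLanguage:
    def test_accepts_valid_run_of_example(self):
        tree = parse_tree(EXAMPLE_TREE)
        word = ("Biopsy", "GPE", "Spi", "LabTest", "X-ray", "OpChestWall",
                "RemovalTherAppl")
        assert word_in_language(tree, word)

    def test_rejects_run_not_starting_with_first_activity(self):
        tree = parse_tree(EXAMPLE_TREE)
        word = ("Spi", "Biopsy", "GPE", "LabTest", "X-ray", "OpChestWall",
                "RemovalTherAppl")
        assert not word_in_language(tree, word)

    def test_loop_requires_at_least_one_execution(self):
        tree = parse_tree(EXAMPLE_TREE)
        word = ("Biopsy", "GPE", "Spi", "X-ray", "OpChestWall",
                "RemovalTherAppl")
        assert not word_in_language(tree, word)
        # and allows repetition
        word = ("Biopsy", "LabTest", "LabTest", "GPE", "Spi", "X-ray",
                "OpChestWall", "RemovalTherAppl")
        assert word_in_language(tree, word)

    def test_empty_word_iff_silent_run_exists(self):
        assert word_in_language(tau(), ())
        assert word_in_language(pt_xor(activity("a"), tau()), ())
        assert not word_in_language(activity("a"), ())
        assert not word_in_language(pt_loop(activity("a"), tau()), ())
        assert word_in_language(pt_loop(tau(), activity("r")), ())


class TestFitsVariant:
    def test_parallel_variant_fits_sequential_model(self):
        assert fits_variant(parse_tree("->( 'a', 'b' )"), parse_variant("+( 'a', 'b' )"))

    def test_contradicting_order_does_not_fit(self):
        assert not fits_variant(
            parse_tree("->( 'a', 'b' )"), parse_variant("->( 'b', 'a' )")
        )

    def test_variant_fits_xor_containing_its_own_tree(self, excerpt_log):
        from povmine.variants import variant_of_trace

        v = variant_of_trace(excerpt_log["47777"])
        tree = pt_xor(variant_as_tree(v), activity("other"))
        assert fits_variant(tree, v)

    def test_capacity_bound_raises_rather_than_answering(self):
        from povmine.model import CapacityError

        v = parse_variant("->( " + ", ".join(f"'a{i}'" for i in range(10)) + " )")
        with pytest.raises(CapacityError):
            fits_variant(parse_tree("'x'"), v, event_bound=5)

    def test_agrees_with_linearization_enumeration_oracle(self):
        """fits <=> some linearization is in the language (brute force)."""
        rng = np.random.default_rng(2024)
        labels = ("a", "b", "c", "d")
        fitting = 0
        for _ in range(150):
            tree = random_process_tree(rng, labels=labels)
            variant = random_variant(rng, labels=labels, max_events=6)
            expected = any(
                word_in_language(tree, w) for w in topo_linearizations(variant)
            )
            assert fits_variant(tree, variant) == expected
            fitting += expected
        assert 0 < fitting < 150


class TestVariantAsTree:
    def test_language_is_exactly_the_linearization_set(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            v = random_variant(rng, max_events=6)
            tree = variant_as_tree(v)
            words = topo_linearizations(v)
            n = v.n_events
            accepted = {
                w
                for w in _language_upto(tree, ("a", "b", "c", "d"), n)
                if len(w) == n
            }
            assert accepted == words
            assert fits_variant(tree, v)

    def test_duplicate_parallel_activities_preserved(self):
        tree = variant_as_tree(parse_variant("+( 'ONOP', 'ONOP' )"))
        assert serialize_tree(tree) == "+( 'ONOP', 'ONOP' )"


class TestFitness:
    def test_case_weighted_fraction(self):
        v_fit = parse_variant("+( 'a', 'b' )")
        v_not = parse_variant("->( 'b', 'a' )")
        table = VariantTable.from_pairs(
            [(v_fit, [f"f{i}" for i in range(3)]), (v_not, [f"n{i}" for i in range(7)])]
        )
        result = fitness(parse_tree("->( 'a', 'b' )"), table)
        assert result.percent == pytest.approx(30.0)
        assert result.fitting_cases == 3

    def test_all_and_none(self):
        v = parse_variant("->( 'a', 'b' )")
        table = VariantTable.from_pairs([(v, ["c1", "c2"])])
        assert fitness(parse_tree("->( 'a', 'b' )"), table).percent == 100.0
        assert fitness(parse_tree("'z'"), table).percent == 0.0

    def test_empty_table_is_an_error(self):
        with pytest.raises(ModelError):
            fitness(parse_tree("'a'"), VariantTable(entries=()))


class TestReduceTree:
    def test_duplicate_choice_children_merge(self):
        assert serialize_tree(reduce_tree(parse_tree("X( 'a', 'a' )"))) == "'a'"

    def test_nested_sequence_flattens(self):
        assert (
            serialize_tree(reduce_tree(parse_tree("->( ->( 'a', 'b' ), 'c' )")))
            == "->( 'a', 'b', 'c' )"
        )

    def test_tau_dropped_from_sequence_with_other_children(self):
        assert (
            serialize_tree(reduce_tree(parse_tree("->( 'a', tau, 'b' )")))
            == "->( 'a', 'b' )"
        )
        assert serialize_tree(reduce_tree(parse_tree("->( tau, tau )"))) == "tau"

    def test_language_preserved_exhaustively(self):
        """Enumeration oracle: all words up to length 6 over 4 letters."""
        rng = np.random.default_rng(31)
        alphabet = ("a", "b", "c", "d")
        for _ in range(12):
            tree = random_process_tree(rng, labels=alphabet, max_depth=3)
            reduced = reduce_tree(tree)
            assert _language_upto(tree, alphabet, 6) == _language_upto(
                reduced, alphabet, 6
            )

    def test_frozen_subtree_is_opaque(self):
        tree = pt_seq(pt_seq(activity("a"), activity("b")), activity("c"))
        frozen = freeze_subtree(tree, (0,))
        reduced = reduce_tree(frozen)
        # the frozen inner sequence must not be spliced into its parent
        assert frozen_subtrees(reduced) == ("->( 'a', 'b' )",)


class TestEditing:
    def test_replace_leaf_with_loop(self):
        tree = parse_tree("->( 'Lab Test', 'Surgery' )")
        out = replace_subtree(tree, (0,), pt_loop(activity("Lab Test"), tau()))
        assert serialize_tree(out) == "->( *( 'Lab Test', tau ), 'Surgery' )"

    def test_replace_root(self):
        replacement = parse_tree("'new'")
        assert replace_subtree(parse_tree("->( 'a', 'b' )"), (), replacement) == replacement

    def test_refuses_to_edit_frozen_region(self):
        tree = freeze_subtree(parse_tree("->( +( 'a', 'b' ), 'c' )"), (0,))
        with pytest.raises(FrozenSubtreeError):
            replace_subtree(tree, (0, 1), parse_tree("'z'"))
        with pytest.raises(FrozenSubtreeError):
            replace_subtree(tree, (0,), parse_tree("'z'"))
        # outside the frozen region editing is fine
        out = replace_subtree(tree, (1,), parse_tree("'z'"))
        assert out.children[1].label == "z"


class TestIncrementalDiscovery:
    def test_initial_model_from_one_variant(self):
        v = parse_variant("->( 'a', +( 'b', 'c' ) )")
        state = discover_initial([v])
        assert fits_variant(state.tree, v)
        assert state.incorporated == (v,)

    def test_initial_model_from_several_variants(self):
        vs = [
            parse_variant("->( 'a', 'b' )"),
            parse_variant("+( 'x', 'y' )"),
            parse_variant("'solo'"),
        ]
        state = discover_initial(vs)
        assert state.tree.kind == "pt_xor"
        for v in vs:
            assert fits_variant(state.tree, v)

    def test_duplicates_deduplicated(self):
        v = parse_variant("'a'")
        state = discover_initial([v, v, v])
        assert state.tree == activity("a")

    def test_already_fitting_variant_leaves_tree_unchanged(self):
        state = discover_initial([parse_variant("->( 'a', 'b' )")])
        out = add_variant(state, parse_variant("+( 'a', 'b' )"))
        assert out.tree == state.tree
        assert len(out.incorporated) == 2

    def test_augmentation_keeps_all_incorporated_fitting(self):
        rng = np.random.default_rng(77)
        variants = [random_variant(rng, max_events=5) for _ in range(12)]
        state = discover_initial([variants[0]])
        for v in variants[1:]:
            state = add_variant(state, v, validate=True)
        for v in state.incorporated:
            assert fits_variant(state.tree, v)

    def test_fitness_on_incorporated_is_always_100(self):
        rng = np.random.default_rng(123)
        variants = [random_variant(rng, max_events=5) for _ in range(8)]
        state = discover_initial([variants[0]])
        for v in variants[1:]:
            state = add_variant(state, v)
            table = VariantTable.from_pairs(
                [(u, [f"c{i}"]) for i, u in enumerate(state.incorporated)]
            )
            assert fitness(state.tree, table).percent == 100.0

    def test_frozen_subtree_survives_incorporation_verbatim(self):
        base = parse_variant("->( 'Surgery', 'X-ray' )")
        state = discover_initial([base])
        state = DiscoveryState(
            tree=freeze_subtree(state.tree, ()), incorporated=state.incorporated
        )
        frozen_text = serialize_tree(state.tree)
        rng = np.random.default_rng(5)
        for _ in range(6):
            state = add_variant(state, random_variant(rng, max_events=4))
        assert frozen_text in frozen_subtrees(state.tree)
        assert contains_subtree(state.tree, parse_tree(frozen_text))
        for v in state.incorporated:
            assert fits_variant(state.tree, v)

    def test_augmentation_never_removes_words(self):
        """Sampled accepted words of the old tree stay accepted."""
        rng = np.random.default_rng(9)
        old = discover_initial(
            [random_variant(rng, max_events=5) for _ in range(3)]
        )
        words = [
            w
            for v in old.incorporated
            for w in list(topo_linearizations(v))[:5]
        ]
        new = add_variant(old, parse_variant("->( 'q', 'r', 'q' )"))
        for w in words:
            assert word_in_language(new.tree, w)
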