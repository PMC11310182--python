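# Methods

## Problem setting

Hospital information systems commonly record only the calendar day of an
activity execution. Within one patient case, events sharing a day carry no
mutual order information, so a case is a *partially ordered* trace rather
than a sequence. This package provides the machinery to analyze such logs:
concurrency-aware trace variants, query-based filtering, rewriting of
variants with clinical domain knowledge (sequentialization), and incremental
discovery of a process-tree model that is guaranteed to fit every variant a
user chose to incorporate.

## Variants as series-parallel orders

A trace maps to a variant by grouping its events per day: a day with one
event contributes a single activity, a day with several contributes a
parallel group, and the groups are concatenated sequentially. The result is
a series-parallel (SP) tree over activity executions with two operators,
sequence and parallel. Directly after construction the tree is two-level
(sequence of leaf/parallel groups); deeper nesting arises only from
sequentialization.

Canonical form makes variant identity a string comparison: operators are
flattened (no sequence under sequence, no parallel under parallel),
single-child operators collapse, and parallel children are sorted by a
case-insensitive total key over their serialization. Parallel child order is
a display convention only — it carries no semantics — so any fixed total key
works; case-insensitive ordering was chosen because clinical labels mix
cases heavily. Duplicate same-day executions of one activity are kept as
distinct leaves (multiset semantics): a repeated same-day procedure is two
executions, not one.

Order queries are evaluated on the partial order the SP tree induces: two
executions are ordered iff their lowest common ancestor is a sequence node.
`precedes_first(a, b)` compares the *first occurrences* of two labels (the
earliest occurrence in the canonical depth-first traversal, which is a
linear extension of the order) and requires strict precedence;
`concurrent_any(a, b)` asks whether some pair of occurrences is
incomparable. With single occurrences these definitions coincide with
"before in every linearization" and "order differs across linearizations",
which is what the test oracles check. With duplicated labels a convention is
unavoidable; first-occurrence semantics matches how guideline-order
violations are phrased ("a biopsy was performed before any CT scan").

## Sequentialization as order extension

A rule is a source/target pattern pair. The source is a single parallel
group naming explicit activities plus an optional wildcard `...` for the
unnamed remainder; the target arranges exactly those activities into any SP
shape, keeping the remainder parallel. A group matches when the multiset of
its leaves (at any depth) contains the explicit labels — and nothing else
when the source has no wildcard. Duplicate labels bind canonically-first.

Application is defined as **order extension** rather than literal subtree
substitution: the target's order relations over the bound leaves are added
to the group's existing partial order, the transitive closure is taken, and
the group is rebuilt from the extended order as an SP tree. On a group of
plain leaves this coincides exactly with substituting the target shape, but
it additionally lets rules *compose*: after one rule orders `a` before `b`
inside a group, a second rule ordering `b` before `c` still matches (the
leaf `b` is no longer a direct child, but it is still a leaf of the group)
and the combined order `a<b<c` is rebuilt correctly. Two safeguards apply,
both leaving the site unchanged: if the added constraints contradict order
already present (a cycle appears in the closure), or if the extended order
is not series-parallel (it contains an N-shaped suborder and hence has no SP
tree), the rule does not fire at that site.

Consequences, verified by property tests against a brute-force
linearization oracle: rewriting conserves the activity multiset; the
result's linearization set is always a subset of the input's (order is only
added, never removed); and application is monotone, so per-rule fixpoint
iteration terminates. The iteration cap (default 100) is retained as a
safety net and flagged in the rewrite report if ever reached. Rules apply in
file order, each to per-variant fixpoint; rewritten variants are
re-canonicalized and re-merged in the variant table, so the total case count
is conserved.

Discovery and fitness run on the rewritten table by default; evaluating a
model against the unrewritten table is a one-line change (pass the other
table), and is expected to show deviations, since the raw log still contains
the coarse same-day stamps the rules corrected.

## Process trees and exact boolean conformance

Process trees use sequence (`->`), exclusive choice (`X`), parallel
interleaving (`+`), loop (`*(do, redo)`, do executed at least once, default
redo silent) and the silent step `tau`. Serialization is bit-exact and child
order is preserved verbatim everywhere; only variant (not model) parallel
groups are canonically sorted, so that parse/serialize are mutual inverses.

Word membership is decided by an operational semantics: a configuration
records per-node progress (sequence position, committed choice branch,
parallel child configurations, loop phase), and membership is a set-of-states
simulation over the word. Loops with nullable bodies are handled by a
guarded silent-closure expansion.

A variant **fits** a tree iff *some* linearization of its partial order is
in the tree's language. Day-equal timestamps carry no order information, so
they cannot contradict an order the model imposes — a model `->( a, b )`
fits a variant where `a` and `b` share a day. Fitting is decided by a
synchronized search over (set of executed variant events × tree
configuration) with memoization of failed states; it is exact and never
materializes linearizations. A configurable event bound (default 400)
raises a capacity error instead of risking state blow-up on degenerate
inputs. Fitness over a variant table is case-weighted and boolean: the
fraction of cases whose variant fits. Reported percentages are therefore
exact fractions, and the guarantee below makes the 100% endpoint a theorem
rather than an observation.

## Incremental discovery, freezing, reduction

`discover_initial` turns one variant into its own tree (leaves to
activities, sequence to sequence, parallel to parallel — the tree's language
is exactly the variant's linearization set) and several variants into a
choice over their trees. `add_variant` maintains three guarantees: every
previously incorporated variant still fits (G1), the new variant fits (G2),
and every frozen subtree occurs verbatim in the result (G3). The baseline
strategy returns the tree unchanged if the variant already fits and
otherwise augments the root with a new choice branch for the variant's tree,
followed by language-preserving reduction. The strategy is pluggable; an
optional `validate` flag re-checks G1–G3 after any custom strategy.

Reduction applies only language-preserving rules: flattening nested
sequence/choice/parallel, dropping `tau` from a sequence with another child
(an all-silent sequence collapses to a single `tau`), deduplicating
identical choice branches and collapsing single-child operators. Frozen
subtrees are opaque to reduction: they are neither rewritten nor spliced
into their parents, which is what makes G3 hold through arbitrarily many
incorporation steps. Manual edits (`replace_subtree`) refuse to touch any
node at or below a frozen root.

## Synthetic data: what it emulates, what it does not

The generator emits logs shaped like a one-year lung-cancer treatment
extract: hundreds of cases, 19 activity labels, same-day collisions, and
three noise mechanisms observed in such data — truncated one- or two-event
traces, single-activity traces (possibly repeated), and invasive-before-
non-invasive order violations.

The ground-truth pathway tree has three phases. Diagnostics: a general
physical examination, a repeatable choice of non-invasive exams, a mandatory
same-day imaging block (X-ray ∥ CT scan), then an optional invasive
procedure (biopsy or bronchoscopy). Surgery: a single-day parallel block of
four activities whose true order the day-granularity stamping hides — this
is the block the shipped sequentialization rules re-order. Follow-up: a
repeatable choice of treatments. Placing the invasive choice strictly after
the imaging block is a deliberate design decision: it encodes the clinical
guideline inside the ground truth, so clean runs can *never* satisfy the
violation query and the shipped filters recover the injected noise with
precision and recall exactly 1.0 by construction. A generator whose clean
behaviour could legitimately trigger the guideline filter would make that
recovery property unattainable, and real screening pathways do order
non-invasive imaging before invasive confirmation.

Defaults are desk-scale study conditions: 200 cases, noise probabilities
5% truncation / 5% singleton / 10% violation draws (violation draws fall
back to clean when the sampled trace has no invasive procedure, so realized
violation counts are lower), geometric day gaps with mean 3 days (clinical
logs show multi-day to two-week gaps; no distribution is prescribed by such
data, so a geometric with a small mean is used), loop-repeat probability
0.4, and a start date spread across one year. Scaling up to a thousand
cases is a config change, not a code change.

What the generator does not emulate: resource and attribute data, episode
structure beyond one case per patient, seasonal admission patterns, and the
heavy-tailed variant-frequency distribution of real logs. Passing recovery
tests therefore demonstrate correctness of the *mechanisms* (filters catch
exactly what was injected; rules restore exactly the hidden order), not
performance on real hospital data, which is noisier in ways the ledger
cannot label.

## Numerical and procedural choices

- Problem sizes in tests and the acceptance run are desk-scale by design:
  200–300 simulated cases, random variants of at most 8 events where a
  brute-force linearization oracle is the comparator, exhaustive word
  enumeration up to length 6 over a 4-letter alphabet for language-equality
  checks. These sizes make every oracle exact.
- All randomness flows through a single integer seed per run
  (`numpy.random.default_rng`); same seed, same bytes.
- Discovery incorporates variants most-frequent-first (ties broken by
  canonical serialization) — the order a practitioner would choose, and the
  order that makes early fitness climb fastest; any order reaches the same
  100% endpoint on the incorporated set.
- Batch fractions in the demo pipeline (20% / 40% / 40%) mirror a staged
  expert workflow; fitness is reported after each batch and is
  non-decreasing for cumulative batches.
- Duplicate same-day rows are kept as genuine repeated executions; no
  de-duplication heuristic is applied (double-entry cannot be distinguished
  from a repeated procedure without attributes the log does not carry).

## Known limitations

- Events are instantaneous (dates); interval events with separate start and
  complete stamps are out of scope, so no overlap-based concurrency beyond
  same-day equality is detected.
- Boolean fitness gives no partial credit: a case either fits or it does
  not. Alignment-based partial conformance is out of scope.
- The baseline discovery strategy (choice augmentation plus reduction)
  guarantees fitting but does not generalize: it will not invent loops or
  shared structure across variants. It is the contract's reference
  implementation; smarter strategies plug in behind the same guarantees.
- Rule application skips sites where the extended order would not be
  series-parallel; such constraints are silently not imposed at that site
  (visible in the rewrite report as an unmatched rule).
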