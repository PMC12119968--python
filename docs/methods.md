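# Methods

## The model class

`cldkit` analyses *causal loop diagrams* (CLDs): signed directed graphs in
which nodes are factors named by workshop participants and an edge
`cause → effect` asserts a causal influence.  Edge polarity follows the
system-dynamics convention: `+` means the two factors move in the same
direction, `-` in opposite directions.  An optional delay flag marks
influences participants described as slow; it is annotation only and never
enters any computation.  Self-edges are rejected: a factor's influence on
itself is representable only through multi-node feedback, which matches how
facilitated workshops actually draw these maps and keeps cycle semantics
simple.

Edge identity is the triple `(cause, effect, polarity)`.  The same ordered
pair may therefore carry both signs at once — two groups (or one group at
two moments) can disagree about the direction of an influence — and such
conflicts are surfaced by `polarity_conflicts` rather than resolved.

## Label standardization

Free-text factor labels are standardized by case-folding, trimming, and
collapsing internal whitespace to single underscores, optionally composed
with a user-supplied raw → canonical synonym map.  Synonym chains
(a → b, b → c) are resolved transitively at load time and cyclic chains are
rejected, which makes canonicalization idempotent — a property the test
suite checks.  A mapping that would merge the two endpoints of an edge into
one label is an error rather than a silent self-edge.

## Feedback loops

A feedback loop is a simple directed cycle.  Its class is decided by the
sign product of its edges: an even number of negative links makes the loop
*reinforcing* (it amplifies change), an odd number makes it *balancing* (it
counteracts change).  This negative-parity rule is the universal
system-dynamics convention and the only rule consistent with labelling an
all-positive cycle reinforcing.

Node cycles are found with networkx's elementary-cycle search under a
length bound; each node cycle is then expanded over the sign combinations
of its arcs, so a pair carrying both polarities contributes one loop per
sign.  Loops are reported in canonical rotation (lexicographically smallest
node first) and sorted, so equal cycles compare equal regardless of
discovery order.  Defaults `max_len = 12` and `max_count = 100 000` reflect
that participant-built CLDs are small; when a dense graph exceeds the count
cap, enumeration raises a `LoopCapExceeded` carrying the partial inventory —
results are never truncated silently.

Cycle *membership* of an edge (as opposed to full enumeration) uses the
strongly-connected-component rule: with self-edges excluded, `u → v` lies on
a simple cycle iff `u` and `v` share an SCC of at least two nodes.  The test
suite checks this against the edge union of exhaustive enumeration.

Exogenous factors are the nodes with in-degree zero: things that influence
the system while nothing in the system causes them.

## Union aggregation

All groups are treated as describing aspects of one underlying system, so
their models are merged as the union of edges.  Each union edge records its
*support*: the set (and count) of distinct groups whose model contains it.
Support counts groups, not mentions — "at least two groups" is a group-level
criterion — and per-group duplicates are collapsed at read time, so the
audit field `instance_count` equals the support count here.  Per-group
descriptive statistics (factors, edges, action ideas; mean to one decimal
plus min–max range) are computed exactly.

Edges "connected to action ideas" are counted with either endpoint flagged
(the weakest faithful reading); a stricter cause-only count is reported
alongside.

## Core extraction

The consensus core model keeps the union edges that at least `min_support`
groups mentioned (default 2) *and* that carry systemic meaning relative to
the focal problem variable.  Concretely, extraction runs a fixed-point
filter:

1. drop edges with support below `min_support`;
2. within the surviving edge set, keep an edge iff it lies on a simple
   cycle (feedback) or on a directed path that starts or ends at the focal
   node (causal connectivity);
3. repeat step 2 until nothing changes;
4. drop nodes left without edges.

Iteration matters: removing an unsupported edge can break the only cycle or
focal path that justified a neighbour, and incomplete feedback structure
must not survive.  "Causally connected" is read in both directions —
ancestors *and* descendants of the focal node — because the focal problem is
narrated both as an effect and as a cause of other factors.  The support
threshold is applied before the structural filter, never after.  Each
surviving edge records its qualifying reason (`feedback`,
`focal_connected`, or `both`).  The filter is deterministic, monotone in
`min_support`, and idempotent on its own output; all three properties are
tested against a brute-force oracle.

## Indirect-path consensus

For every union edge, groups that did not draw the edge directly may still
endorse it indirectly: a group counts toward *effective support* when its
own CLD contains a simple directed path from the edge's cause to its effect
with at most `max_intermediates` intervening nodes (default 2) whose sign
product equals the edge's polarity.  One witness path per group is
recorded.  This is a reporting layer only — it never adds edges to the
extracted core, because admitting an edge on indirect evidence would change
the meaning of the support threshold.

## Action-idea leverage

Action ideas are participant-proposed interventions represented as nodes.
Their leverage is measured by enumerating simple directed paths of at most
`max_path_len` edges (default 4) from each action node to any core-model
node.  Paths traverse the full aggregate graph, not only core edges,
because an intervention influences the system through any elicited linkage.
Two totals are always reported side by side — distinct (action, core node)
pairs and distinct pathways — since either is a defensible way to count
"ways an action affects the core", and the package does not choose one.

## Synthetic batteries and recovery

Because multi-group workshop transcripts are typically not deposited, core
extraction is validated on synthetic batteries with a known latent system.

`generate_true_system` builds a truth graph of `n_factors` (default 70)
factors: a focal node on one all-positive (reinforcing) and one
odd-negative (balancing) cycle, a side loop, ancestor and descendant
chains, one exogenous driver, `n_action_nodes` (default 18) action nodes
attached by outgoing edges into focal ancestors, and extra random core
edges up to `n_core_edges` (default 50).  Peripheral structure
(`n_peripheral_edges`, default 38) hangs off *pure ancestors* of the focal
node or chains between peripheral nodes, acyclically and with no path to
or from the focal node — so by construction it must not survive a faithful
extraction.  The generator verifies these guarantees on every call.

`sample_group_models` emulates `n_groups` (default 8) independent
workshops: each latent edge is detected with probability `p_detect`
(default 0.85); a detected edge's sign is flipped with probability
`flip_prob` (default 0.02, modelling elicitation/transcription
disagreement); and each group adds Poisson(`noise_rate`, default 40) noise
edges whose endpoints are mostly group-unique local labels, so noise almost
never repeats across groups and a two-group support filter removes it.
Noise never duplicates a latent factor pair — a coincidence with real
structure would be structure, not noise.  Defaults were calibrated once to
the scale of real multi-group dementia-risk workshops (per-group means of
roughly 70–80 factors and ~115 edges, 18 distinct action ideas across the
battery) and are not tuned per experiment.  Under these defaults the
per-group action-idea count runs higher than a typical workshop's (uniform
detection makes most of the 18 actions visible to every group); the
battery-level count of distinct action ideas is the calibrated quantity.

Recovery is scored edge-level and sign-sensitively: precision and recall of
the extracted core against the latent core edges, matching on
`(cause, effect, polarity)`, with the conventions precision = 1 for an
empty extraction and recall = 1 for an empty latent core.
`run_recovery_experiment` repeats generate → sample → canonicalize → union
→ extract → score with per-replicate seeds drawn from one root seed.  The
frozen acceptance thresholds (median precision ≥ 0.95, median recall ≥ 0.90
over 50 replicates at defaults) come from a pre-registered pilot run of the
brute-force-validated pipeline; in that regime precision sits near 1
because group-unique noise fails the two-group filter, and recall is
governed by the small chance that a latent core edge is correctly seen by
fewer than two of eight groups.

What the generator does *not* emulate: participant demographics and group
dynamics, facilitator effects, systematically biased label vocabularies
across groups (every group shares the truth labels after standardization),
and semantic near-synonyms that a synonym map would have to catch.  Passing
recovery tests therefore show the *pipeline* is sound under honest
detection noise, not that real workshop data are this well behaved.

## The shipped demo

`cldkit.demo` ships a one-group transcription of a published workshop's
narrated feedback loops around dementia risk (trauma/substance-abuse/
domestic-violence, health-literacy information loops, criminal-justice and
caregiving loops, a discriminatory-policy loop, stigma loops, plus two
action nodes).  Two narrated loop labels describe open chains that feed
other loops rather than closed cycles; the transcription records exactly
the narrated edges and lets the parity rule classify the cycles that
actually exist.  Notably, the narrated signs of the discriminatory-policy
loop carry an even number of negative links, so the parity rule classifies
that cycle as reinforcing even though the narration presents it as
balancing; the fixture preserves the narrated signs and reports the parity
result.  With a single group the demo is run at `min_support = 1`.

## Numerical and engineering choices

- Everything is integer counting and set algebra; there are no tolerances.
  Floating point appears only in means and recovery rates.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; derived seeds stay below 2^31.
- All outputs (CSV, DOT, GraphML, JSON) emit nodes, edges and keys in
  lexicographic order, so identical inputs give byte-identical reports.
  The run manifest omits the run directory's own path for the same reason.
- Degenerate inputs: empty edge files, empty synonym maps, an unconnected
  focal variable, and empty cores all have defined behaviour (error or
  empty report) covered by tests.
- Problem sizes in the test suite and acceptance script — 200 random
  digraphs of ≤5 nodes for enumeration oracles, 100 random aggregates of
  ≤25 nodes for extraction oracles, 30–50 recovery replicates — were chosen
  to exercise the combinatorics exhaustively at small scale while keeping a
  full run in the order of seconds.

## Known limitations

- Loop enumeration is exponential in dense graphs; the caps make this
  explicit rather than solving it.
- Indirect-path witness search returns one witness per group (shortest-first
  DFS), not all witnesses.
- The aggregate treats groups as exchangeable; there is no weighting by
  group size or composition.
- No quantitative system-dynamics simulation: the package analyses the
  qualitative signed structure only.
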