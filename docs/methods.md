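# Methods

## Model and scope

`bqsnet` treats a gene regulatory network as a directed graph with a
designated transcription-factor (TF) subset.  By definition only TFs
have outgoing edges; where no explicit TF set is given it is inferred
as exactly the nodes with out-degree ≥ 1.  Random-network models and
some analyses need a *designated* TF set instead, because a designated
TF may end up with no realised out-edges and must still count as a TF.
Self-regulating interactions are parsed and stored but excluded from
every census; they matter only for the positive-self-regulation check
in the stability-condition report.

The structural conditions checked for qualitative stability are: (1)
no positive self-regulation, (2) no double-positive or double-negative
2-node feedback loops (mixed-sign 2-node loops are allowed; isolated
double-negative loops act as bistable switches rather than sources of
instability), (3) no feedback loops of more than two nodes, and (4)
sign-matrix invertibility, which is structurally trivial for
reconstructed GRNs because two biochemically indistinguishable TFs
would have been collapsed into one node.  Condition 3 carries
essentially all of the discriminating power and is what the censuses
quantify.  The differential-equation side of the theory is out of
scope: only the structural conditions are evaluated.

All censuses, motif counts and probes run on the TF-induced
subnetwork.  Genes that regulate nothing cannot participate in a cycle,
so scoring them would only dilute the comparison and make any network
look more stable than its regulatory core is.

## Censuses

Feedback loops of length L are directed simple cycles on L distinct
nodes, counted once per cycle (equivalently, the directed-cycle
sub-isomorphism count divided by L to absorb the cyclic
automorphisms).  Cycle enumeration is delegated to networkx's
length-bounded `simple_cycles` (a bounded Johnson-style enumerator);
simple paths and incomplete loops are counted by a dedicated
depth-first traversal that checks the closing edge of every path as it
is extended.  The two are tied together by the identity
`incomplete[L] = paths[L] − (L+1)·cycles[L+1]`, which the test suite
verifies against an independent brute-force enumerator over vertex
sequences on hundreds of small random digraphs.

The enumeration horizon defaults to `max_len = 14` edges.  The cap is
a practical necessity — exhaustive simple-path enumeration in dense
random networks grows exponentially with length — and at that horizon
random ensembles at realistic GRN sizes already carry hundreds of
loops per length, so nothing discriminating lies beyond it.  "Long"
means ≥ 3 nodes throughout: a new 2-node loop is never counted as
destabilising, since suitably signed 2-node loops are compatible with
qualitative stability.

## Motif classification

Motif instances are connected induced subgraphs (the standard census
convention; every node subset counted once under its induced class),
enumerated with Wernicke's ESU algorithm and canonicalised by
exhaustive relabelling (3! or 4! permutations; canonical form = the
lexicographically smallest row-major 0/1 adjacency string).  Buffering
is judged non-induced on the motif's concrete edge set: an absent
ordered pair is destabilising if inserting it creates a ≥ 3-node cycle
inside the motif.  Categories: buffered (0 such additions, no existing
long cycle), mono-unbuffered (1), poly-unbuffered (≥ 2), and unstable
(already contains a long cycle) — the fourth category makes the
classification total; real GRNs should contain essentially none.
Classes sharing `(n_nodes, n_edges, placements)` with
`placements = n!/|Aut|` have identical expected counts under the
TF-fixed edge-uniform random model, which is what licenses
within-group comparisons of observed counts.

## Destabilisation probe

Inserting `u -> v` creates a long loop iff a simple directed path
`v ⇝ u` with 2..max_len−1 edges exists.  The implementation uses
breadth-first bounded reachability (ignoring a direct `v -> u` edge,
which only 2-loops could use); the choice of *bounded* reachability
keeps the probe consistent with the census horizon — at realistic
network sizes the difference from unbounded reachability is nil.  The
exhaustive probe tries every ordered absent TF pair; the sampled probe
draws candidates uniformly *with replacement* and reports the hit
fraction, matching the `NS / n_samples` estimator used for large
random ensembles.  A `candidate scope` switch optionally restricts
endpoints to TFs carrying at least one TF-TF edge, since published
candidate counts for some datasets imply a restricted TF universe and
the right restriction is not documented; both scopes are first-class
and neither is guessed silently.

## Random-network models

Five generative models cross two axes — TF set fixed vs emergent, and
isolated genes allowed vs forbidden — plus degree-preserving rewiring:

- *IG allowed*: draw edges uniformly (source from the eligible source
  set, target from the other genes) with rejection of duplicates and
  self-targets, which leaves the edge-count distribution unchanged.
- *IG forbidden, V1*: seed every gene with one incoming edge from a
  random eligible source, then top up uniformly.  Less biased, but it
  requires at least as many edges as genes.
- *IG forbidden, V2*: add uniform edges until no gene is isolated,
  then add or remove uniform edges (removals never isolating a node)
  until the edge count is exact.  More biased, always feasible down to
  the coverage bound.
- *Rewire*: repeated double-edge swaps `(a,b),(c,d) -> (a,d),(c,b)`
  rejecting self-loops and duplicates; every node keeps its exact in-
  and out-degree.  The attempt count (default 100 × edges) is a
  parameter, since rewiring depth is a known sensitivity of this null.

For TF-variable models the source distribution is uniform over all
genes — the natural reading of "TF count variable", recorded here as
an assumption.  All draws use numpy's PCG64; replicate `r` of an
ensemble seeded `s` uses `SeedSequence((s, r))`, making ensembles
reproducible and parallelisable.  Under the TF-fixed uniform model the
expected TF-TF edge count is `m(t−1)/(n−1)` and the expected
unregulated-TF fraction is approximately `(1−q)^(t−1)` with
`q = m/(t(n−1))`; both closed forms are verified against simulation in
the tests.

## Statistics

Ensemble loop counts are skewed; `y = log(n+1)` (natural log — the
tail probability is invariant to the base) brings them close to
normality, which a Shapiro–Wilk test reports diagnostically: a low
Shapiro p warns but does not block estimation.  Tail probabilities are
one-sided in the direction of the stability prediction — fewer loops,
more unregulated TFs — and always per loop length, never pooled:
counts at different lengths are strongly dependent, so no omnibus
statistic or multiplicity correction across lengths is attempted.
Degenerate (constant) ensembles raise an explicit error rather than
returning a sham p-value.

## Synthetic data

`planted_network` composes node-disjoint cycles, paths and filler
edges.  Disjointness makes the ground truth additive and exact: an
L-cycle contributes one loop of length L and L incomplete loops at
each length 2..L−2; a k-edge path contributes k+1−j incomplete loops
at each length j = 2..k; filler edges run from one extra TF to non-TF
sinks and are invisible to the TF-restricted censuses.  Frozen
expected values for the shipped fixtures were computed with the
brute-force enumerator, and every fixture's ground truth is reverified
against the census code — the primary cross-module oracle.

`bqs_compliant_grn` emulates the published scale of bacterial GRNs
(default TF fraction 0.10, mirroring 154/1470; edge counts and the
constitutive-TF fraction are caller-chosen): TFs form a layered DAG —
edges only run from lower to higher layer order, so the loop census is
provably zero — with an exact count of TF-unregulated TFs and roughly
one tenth of edges inside the TF subnetwork.  What it does *not*
emulate: scale-free degree tails, interaction signs, self-regulation,
and correlated (operon-like) target structure.  Tests passing on these
fixtures therefore certify the *machinery* (censuses, probes,
statistics) and the qualitative contrast with random ensembles; they
do not certify distributional detail of any real organism.

## Study sizes used in the tests

Chosen once as the package's study conditions: oracle equivalence on
500 random digraphs of 4–7 nodes; ensemble prevalence and
incomplete-loop magnitude at the published E. coli size (1470 genes /
154 TFs / 2909 edges; 1000 and 30 replicates respectively); null-model
constraint checks on 100 draws per model at 200/30/260; motif
equiprobability on 100 TF-fixed draws at 150/30/450, where the
within-group pairwise means agree to well under three combined
standard errors; coverage of the log-normal tail estimator on
ensembles of 1000.

## Known limitations

- Censuses are exact only up to `max_len`; no extrapolation beyond it.
- The sub-isomorphism convention counts an edge or node many times
  across loops, which is informative about structure but can be
  counter-intuitive; `loops_per_gene` and `critical_edges` inherit it.
- Identifier matching is exact and case-preserving; no aliasing
  against gene-annotation databases.
- Stabilising-pair search is brute force over TF pairs, quadratic in
  the TF count — fine for hundreds of TFs, not for tens of thousands.
- No motif significance profiles against rewired ensembles beyond the
  equiprobability group comparison, and no motifs of five or more
  nodes.
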