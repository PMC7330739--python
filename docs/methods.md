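# Methods

## The model

A temporal Bayesian network `B = (G, P)` over binary nodes `(condition,
year)` for `n_c` chronic conditions observed across `T` years. `G` is a
DAG whose edges respect time: a parent `(c_i, y_s)` of `(c_j, y_t)`
requires `s < t`, or `s = t` with `i < j` in a fixed condition order
(same-year comorbidity links are representable without breaking
acyclicity; both restrictions are switches on `ScoreConfig`). `P` factors
as the usual product of per-node CPTs, so the joint is exact and cheap,
and any posterior is computable by variable elimination.

## Graph Laplacians and λ₂

The algebraic connectivity λ₂ — the second-smallest eigenvalue of a
Laplacian — is the workhorse. Three constructions are available through
`LaplacianConfig`:

* `undirected`: `L = D − A` with weighted degrees. λ₂ = 0 iff the graph is
  disconnected; closed forms λ₂(K_n) = n, λ₂(P_n) = 2(1 − cos π/n),
  λ₂(C_n) = 2(1 − cos 2π/n) are used as test anchors.
* `directed_chung` (default for general spectral work and for the
  summarizer): the random-walk symmetrization
  `L = I − (Φ^{1/2} P' Φ^{−1/2} + Φ^{−1/2} P'ᵀ Φ^{1/2})/2`, where `P'` is
  the row-normalized adjacency with dangling rows replaced by the uniform
  distribution and smoothed by teleportation,
  `P' = a·P + (1 − a)/n` with `a = teleport` (default 0.85; `a = 1`
  disables smoothing), and `Φ` is the stationary distribution of `P'`.
  Using the *same* smoothed walk in both the stationary solve and the
  symmetrization is what guarantees symmetry, positive semidefiniteness
  and a smallest eigenvalue of exactly zero (eigenvector `Φ^{1/2}1`);
  mixing the raw walk into the symmetrization would lose all three. A DAG
  is never ergodic, hence the teleportation; for strongly connected
  reversible graphs `a = 1` recovers the symmetric normalized Laplacian
  exactly.
* `directed_simple` (default for the learner's penalty): `(L + Lᵀ)/2`
  with `L = D_total − A`, `D_total` = diagonal of in+out weighted degree.
  Adding an edge adds a PSD rank-one-like block, so λ₂ is weakly
  non-decreasing under edge addition. That monotonicity is essential for
  a *sparsity* penalty: under the normalized `directed_chung` spectrum an
  empty graph has λ₂ = 1 and adding edges frequently *lowers* λ₂, which
  would reward density. With `directed_simple` the penalty is inert while
  the learned graph is still disconnected (λ₂ = 0) and bites exactly in
  the dense regime the penalty exists for.

Numerics: dense symmetric eigensolver (`scipy.linalg.eigvalsh`); negative
eigenvalues in `[−1e−9, 0)` are round-off and clipped to zero; the
stationary distribution is solved directly (augmented least squares) for
`n ≤ 200` and by power iteration beyond. Sparse/iterative eigensolvers
are out of scope — the graphs of interest have tens of nodes.

## Structure learning

1. Plug-in pairwise mutual information (natural log, clipped at 0) over
   all column pairs; constant columns get MI 0 with a logged warning.
2. Maximum-weight spanning tree (Kruskal, ties broken by the smaller
   index pair), rooted by default at the node with the largest total MI;
   the node ordering is the breadth-first traversal of that tree,
   stable-sorted by year for temporal data so time flows along the
   ordering.
3. K2 greedy parent search in ordering position: for each node, the
   allowed predecessor whose addition most improves the penalized score
   `local_score − λ·λ₂(G ∪ {edge})` is added until no improvement or
   `max_parents` (default 5) is reached. The local score is the
   Cooper–Herskovits log marginal likelihood
   `Σ_j [log(r−1)! − log(N_j + r − 1)! + Σ_k log N_jk!]` with `r = 2`,
   computed with log-gamma; AIC (`LL − 2^{|pa|}`) and BIC
   (`LL − 2^{|pa|−1} ln m`) are drop-in alternatives.

`penalty_reference` controls what the penalty is evaluated on:
`"candidate"` (default) recomputes λ₂ on the graph including each tested
edge, so the penalty acts on every individual decision; `"previous"`
freezes it at the last accepted graph, where it cancels inside the greedy
comparison and only shifts sweep-level totals. The canonical λ sweep is
`0, 10⁻², 10⁻¹, …, 10⁵`; `sweep_lambda` stops early once λ₂ of the
learned graph changes by < 10⁻⁶ between consecutive grid points
(diminishing returns — larger λ can no longer change the spectrum).

## Summarization

Given a model (directed, possibly weighted) the summarizer:

1. Extracts a DFS spanning forest of the undirected view, rooted at all
   year-1 nodes (or node 0 for non-temporal graphs), and freezes it —
   these edges are never pruned, which structurally forbids isolated
   nodes. Neighbors are visited in descending pair-weight order with ties
   by ascending index, so the protected skeleton follows the strongest
   connections (on unweighted graphs this reduces to plain index order);
   zero-weight edges represent no dependence at all and are skipped on a
   first pass, used only to attach nodes unreachable through
   positive-weight edges. The skeleton is computed once on the input
   graph: recomputing per round could silently change what is protected
   mid-run.
2. Scores every candidate edge by the relative spectral impact
   `|λ₂(G) − λ₂(G∖e)| / λ₂(G)` of its (temporary) deletion; when the
   intact graph is already disconnected (λ₂ ≤ 10⁻⁹) the absolute change
   is used and flagged in the trace. Ranking ties break lexicographically
   by (source, target), making every run deterministic.
3. Prunes: `single` mode removes the argmin each round; `multi` mode
   removes every candidate below the threshold per round. Stopping: a
   `target_ratio`, when set, binds — pruning continues to
   `round(ratio·e0)` removals or candidate exhaustion (recorded as a
   warning) regardless of the threshold; otherwise pruning stops once the
   smallest candidate Δλ₂ exceeds the threshold (default 0.05, read as a
   relative fraction, i.e. a 5% change in λ₂).
4. With supporting data, re-estimates all CPTs once on the final
   structure (additive smoothing, pseudo-count 1 by default; a
   pseudo-count of 0 marks never-observed parent configurations and sets
   them to 0.5). Without data, surviving edge weights are returned
   bit-identical. Per-round re-estimation is intentionally not offered:
   parameters do not influence the spectral ranking, so estimating them
   before the structure is final is wasted work.

Every run emits a `PruneTrace` (one record per removal with Δλ₂, the
relative/absolute flag and λ₂ after) that replays exactly onto the input
graph, plus a report with raw and display (half-up, 2-decimal) removal
percentages.

## Evaluation

Year-ahead prediction: for each patient, the posterior of a
`(condition, year ≥ 2)` node given that patient's year-1 profile as
evidence, computed exactly by variable elimination in reverse topological
order after barren-node pruning, memoized over distinct evidence
configurations (cost scales with distinct year-1 profiles, ≤ 2^{n_c},
not with cohort size). AUC is the rank-based Mann–Whitney statistic with
half-credit for ties — invariant to monotone transforms of the scores.
`cross_validate` shuffles patients by seed into k near-equal folds
(default 10, unstratified; the folds are large enough that class balance
is stable), fits the supplied pipeline per fold and averages per-fold
AUCs; a fold whose held-out target is single-class yields a logged NaN
cell. Per-fold averaging (not pooling) is the reported convention.

## The synthetic generator

The real study population — a quarter-million-patient multi-year care
cohort — is restricted, so `eagl.synth` generates stand-ins with known
truth. CPTs follow a logistic link:
`logit P(node = 1 | pa) = logit(prevalence_c) + Σ effects of active
parents`, with |logit| capped at 30 so extreme effects saturate cleanly.
Year-1 baseline prevalences default to values typical of a deployed-
veteran care population (TBI 0.15, PTSD 0.25, BaPa 0.35, SuAb 0.15,
Depr 0.30); same-condition year-to-year persistence defaults to +2.2
log-odds, cross-condition pathways to +0.9…+1.4. Edge weights in the
generated graph equal the effect magnitudes, so spectral pruning of the
weighted model sees weak dependencies as weak connections.

Three stock configurations:

* `default_spec` — 5 conditions × 5 years (25 nodes, 18 edges:
  persistence chains for the three chronically persisting conditions plus
  six short-range pathways). Calibrated so the generating model's year-2
  AUCs land near 0.66–0.75, the discriminability band plausible for
  administrative comorbidity data.
* `recovery_spec` — 3 conditions × 5 years, 18 strong edges; the
  structure-recovery benchmark (best-λ edge F1 measured against it).
* `contamination_spec` — full persistence chains (26 edges) so the true
  skeleton spans every node; used for spurious-edge experiments, where
  injected edges must close cycles rather than attach otherwise-isolated
  nodes (attachment edges would be DFS-protected and the experiment would
  measure protection artifacts, not ranking quality).

`inject_spurious_edges` adds temporally legal random edges with effects
drawn in `±effect_cap`; `effect_cap = 0` yields pure-noise edges —
structure wrongly present in the model with no counterpart in the data —
which is the regime in which summarization is expected not to cost
predictive accuracy. With `effect_cap > 0` the injected edges carry real
(weak) signal and their removal necessarily trades a little AUC for
sparsity. The labeled-edge recovery experiment injects 24 weak edges
(cap 0.3 against true effects ≥ 0.9), roughly doubling the edge count,
and removes a matched number.

What the generator does **not** emulate: demographic covariates, dropout
and censoring, unmeasured confounding, drifting prevalence, and the
inter-condition correlation structure of real administrative data.
Passing results on these cohorts show the algorithms are implemented
correctly and behave as designed under a known truth — not that the same
accuracy would be obtained on clinical data.

`make_lexicon_graph` emulates the data-free use case: a connected
weighted undirected co-occurrence graph, by default the 200 heaviest term
pairs over 60 terms with log-normal (heavy-tailed) weights, built as a
random spanning tree plus random extra pairs. Sixty terms keeps deep
summarization ratios feasible: a connected graph on `t` nodes needs at
least `t − 1` edges, so a 70% cut of 200 edges (down to 60) requires
`t ≤ 61`.

## Problem sizes

The shipped experiments use 15–25-node networks, cohorts of 4 000–20 000
patients (five seeded replicates), the full nine-point λ grid, and
20-replicate oracle comparisons on 6-node graphs — sizes at which every
spectral quantity is computed by dense eigendecomposition in milliseconds
and the complete suite runs in well under a minute of CPU.

## Known limitations

* The greedy K2 search inherits its ordering sensitivity: a poor MWST
  ordering cannot be repaired by the penalty.
* The spectral ranking is structural; it cannot distinguish a weak true
  edge from a noise edge of equal weight and topology.
* The score/penalty scales (log marginal likelihood vs an eigenvalue in
  `[0, ~n]`) are deliberately not normalized — the λ grid spans the
  mismatch, mirroring how the tuning parameter is swept in practice.
* Binary variables only; rows with missing entries are rejected rather
  than imputed.
* Cyclic (feedback) dependence between conditions is not representable
  in a DAG per year-pair; only forward-in-time structure is modeled.
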