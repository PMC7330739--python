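"""Greedy spectral summarization of an existing graphical model.

Candidate edges (those off a depth-first-search skeleton, which is frozen
up front to guarantee no node is ever islanded) are ranked by the relative
change their deletion causes in the second Laplacian eigenvalue; the least
spectrally important edges are pruned one at a time (``single`` mode) or in
threshold batches (``multi`` mode) until the 0.05 stopping rule fires or a
target removal ratio is reached.  With supporting data the conditional
probability tables are re-estimated once, on the final structure; without
data the surviving edge weights pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .cohort import CohortTable
from .infer import TemporalBayesNet, estimate_cpts
from .spectral import (
    DeltaLambda2,
    Graph,
    LaplacianConfig,
    delta_lambda2,
    lambda2,
    parse_temporal_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SummarizeConfig",
    "PruneRecord",
    "PruneTrace",
    "SummarizeResult",
    "protected_edges",
    "rank_candidates",
    "summarize_model",
    "summarization_report",
    "percent_removed",
    "replay_trace",
]


@dataclass(frozen=True)
class SummarizeConfig:
    mode: str = "single"  # single | multi
    threshold: float = 0.05  # relative Δλ₂ stopping rule
    target_ratio: float | None = None  # fraction of e0 to remove
    with_data: bool = False
    roots: tuple[int, ...] | None = None  # DFS roots; default year-1 nodes
    laplacian: LaplacianConfig = field(default_factory=LaplacianConfig)

    def __post_init__(self):
        if self.mode not in ("single", "multi"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.target_ratio is not None and not (0.0 <= self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in [0, 1]")


@dataclass
class PruneRecord:
    round: int
    edge: tuple[str, str]  # node labels
    delta_lambda2: float
    relative: bool  # False = absolute fallback (λ₂ of intact graph ≈ 0)
    lambda2_after: float


@dataclass
class PruneTrace:
    records: list[PruneRecord]
    e0: int
    e_final: int
    lambda2_initial: float
    lambda2_final: float
    warnings: list[str] = field(default_factory=list)

    @property
    def removed_count(self) -> int:
        return len(self.records)


@dataclass
class SummarizeResult:
    graph: Graph
    trace: PruneTrace
    net: TemporalBayesNet | None = None  # present when with_data


def _default_roots(graph: Graph) -> list[int]:
    """Year-1 nodes for temporal label sets, else node 0."""
    roots = []
    for i, lab in enumerate(graph.nodes):
        try:
            if parse_temporal_label(lab)[1] == 1:
                roots.append(i)
        except ValueError:
            return [0]
    return roots or [0]


def protected_edges(
    graph: Graph, roots: Sequence[int] | None = None
) -> set[tuple[int, int]]:
    """Edges of a DFS spanning forest over the undirected view of the graph.

    DFS starts from each root in order (unvisited remaining nodes become
    extra roots, ascending index) and visits neighbors in descending weight
    order with ties broken by ascending index — so the protected skeleton
    runs along the strongest connections (on an unweighted graph this is
    plain index order).  Zero-weight edges carry no dependence, so they are
    skipped entirely on a first pass and used only afterwards to attach
    nodes that are unreachable through positive-weight edges.  A tree pair
    {u, v} protects every stored edge between u and v (both directions of a
    reciprocated pair).  These edges are never candidates for removal,
    which is what prevents islands.
    """
    if graph.n == 0:
        raise ValueError("cannot protect edges of an empty graph")
    roots = list(roots) if roots is not None else _default_roots(graph)
    visited: set[int] = set()
    tree_pairs: set[frozenset[int]] = set()

    def pair_weight(u: int, v: int) -> float:
        w = 0.0
        if graph.has_edge(u, v):
            w = max(w, graph.weight(u, v))
        if graph.directed and graph.has_edge(v, u):
            w = max(w, graph.weight(v, u))
        return w

    def ordered_neighbors(u: int, zero_ok: bool) -> list[int]:
        nbrs = [
            v for v in graph.undirected_neighbors(u)
            if zero_ok or pair_weight(u, v) > 0
        ]
        return sorted(nbrs, key=lambda v: (-pair_weight(u, v), v))

    def dfs(start: int, zero_ok: bool) -> None:
        stack = [(start, iter(ordered_neighbors(start, zero_ok)))]
        visited.add(start)
        while stack:
            u, it = stack[-1]
            advanced = False
            for v in it:
                if v not in visited:
                    visited.add(v)
                    tree_pairs.add(frozenset((u, v)))
                    stack.append((v, iter(ordered_neighbors(v, zero_ok))))
                    advanced = True
                    break
            if not advanced:
                stack.pop()

    for r in roots:  # positive-weight skeleton
        if r not in visited:
            dfs(r, zero_ok=False)
    for u in sorted(visited):  # zero-weight attachments from the skeleton
        for v in ordered_neighbors(u, zero_ok=True):
            if v not in visited:
                visited.add(v)
                tree_pairs.add(frozenset((u, v)))
                dfs(v, zero_ok=True)
    for extra in range(graph.n):  # components unreachable from the roots
        if extra not in visited:
            dfs(extra, zero_ok=True)
    return {
        (i, j) for (i, j) in graph.edge_keys() if frozenset((i, j)) in tree_pairs
    }


def rank_candidates(
    graph: Graph,
    protected: set[tuple[int, int]],
    config: SummarizeConfig | None = None,
):
    """All non-protected edges scored by Δλ₂ of their (temporary) removal,
    ascending; ties broken lexicographically by (source, target)."""
    config = config or SummarizeConfig()
    if not protected <= set(graph.edge_keys()):
        raise ValueError("protected set contains edges not in the graph")
    lconf = config.laplacian
    lam_full = lambda2(graph, lconf)  # shared across all temporary removals
    out = []
    for edge in graph.edge_keys():
        if edge in protected:
            continue
        lam_rm = lambda2(graph.without_edge(*edge), lconf)
        diff = abs(lam_full - lam_rm)
        if lam_full > lconf.tol:
            d = DeltaLambda2(value=diff / lam_full, relative=True)
        else:
            d = DeltaLambda2(value=diff, relative=False)
        out.append((edge, d))
    out.sort(key=lambda t: (t[1].value, t[0]))
    return out


def summarize_model(
    model: TemporalBayesNet | Graph,
    cohort: CohortTable | None = None,
    config: SummarizeConfig | None = None,
) -> SummarizeResult:
    """Greedy Δλ₂ pruning with a frozen DFS skeleton.

    Stopping: if ``target_ratio`` is set it binds — pruning continues
    (ignoring the threshold) until ``round(ratio * e0)`` edges are removed
    or candidates run out (a warning is then recorded).  Otherwise pruning
    stops as soon as the smallest candidate Δλ₂ exceeds ``threshold``.

    With ``with_data`` the CPTs are re-estimated from ``cohort`` on the
    final structure; in the data-free mode surviving weights are returned
    bit-identical to the input.
    """
    config = config or SummarizeConfig()
    graph = model.graph if isinstance(model, TemporalBayesNet) else model
    if config.with_data and cohort is None:
        raise ValueError("with_data summarization requires a cohort")
    g = graph.copy()
    e0 = g.n_edges
    if e0 == 0:
        raise ValueError("cannot summarize a graph with no edges")
    lconf = config.laplacian
    lam2_0 = lambda2(g, lconf)
    protected = protected_edges(g, config.roots)
    p_target = (
        int(round(config.target_ratio * e0)) if config.target_ratio is not None else None
    )
    records: list[PruneRecord] = []
    warnings: list[str] = []
    round_no = 0
    while True:
        if p_target is not None and len(records) >= p_target:
            break
        cands = rank_candidates(g, protected, config)
        if not cands:
            if p_target is not None and len(records) < p_target:
                msg = (
                    f"target ratio would require removing protected edges; "
                    f"stopped after {len(records)} of {p_target} removals"
                )
                warnings.append(msg)
                logger.warning(msg)
            break
        round_no += 1
        if config.mode == "single":
            batch = cands[:1]
            if p_target is None and batch[0][1].value > config.threshold:
                break
        else:  # multi
            batch = [c for c in cands if c[1].value < config.threshold]
            if p_target is not None:
                if not batch:
                    batch = cands[:1]  # ratio binds: keep pruning the argmin
                batch = batch[: p_target - len(records)]
            elif not batch:
                break
        for edge, d in batch:
            g.remove_edge(*edge)
            records.append(
                PruneRecord(
                    round=round_no,
                    edge=(graph.nodes[edge[0]], graph.nodes[edge[1]]),
                    delta_lambda2=d.value,
                    relative=d.relative,
                    lambda2_after=lambda2(g, lconf),
                )
            )
    trace = PruneTrace(
        records=records,
        e0=e0,
        e_final=g.n_edges,
        lambda2_initial=lam2_0,
        lambda2_final=lambda2(g, lconf),
        warnings=warnings,
    )
    net = None
    if config.with_data:
        assert cohort is not None
        net = estimate_cpts(g, cohort)
    return SummarizeResult(graph=g, trace=trace, net=net)


def percent_removed(e0: int, e_final: int) -> tuple[float, float]:
    """(raw, display) percentage of edges removed; display is rounded
    half-up to 2 decimals the way results tables print it."""
    if e0 <= 0:
        raise ValueError("initial edge count must be positive")
    raw = 100.0 * (e0 - e_final) / e0
    display = float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return raw, display


def summarization_report(trace: PruneTrace) -> dict:
    """Edge accounting and spectral bookkeeping for a pruning run."""
    raw, display = percent_removed(trace.e0, trace.e_final)
    return {
        "edges_before": trace.e0,
        "edges_after": trace.e_final,
        "edges_removed": trace.e0 - trace.e_final,
        "percent_removed": display,
        "percent_removed_raw": raw,
        "lambda2_before": trace.lambda2_initial,
        "lambda2_after": trace.lambda2_final,
        "warnings": list(trace.warnings),
    }


def replay_trace(graph: Graph, trace: PruneTrace) -> Graph:
    """Re-apply a trace's removals to the original graph (consistency check)."""
    g = graph.copy()
    for rec in trace.records:
        g.remove_edge(g.index(rec.edge[0]), g.index(rec.edge[1]))
    return g
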