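"""Parameters and exact inference for the temporal Bayesian network.

CPT estimation with additive smoothing, the joint-probability decomposition,
exact posteriors by variable elimination, rank-based ROC/AUC and the k-fold
cross-validated evaluation protocol (year-1 evidence, year 2..T targets).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable
from .spectral import Graph, parse_temporal_label, temporal_label

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionalProbabilityTable",
    "TemporalBayesNet",
    "estimate_cpts",
    "joint_probability",
    "posterior",
    "predict_future",
    "roc_auc",
    "cross_validate",
    "evaluation_summary",
]


@dataclass
class ConditionalProbabilityTable:
    """P(node = 1 | parent configuration) for a binary node.

    ``p1`` has shape ``(2,) * len(parents)`` (a 0-d array for a root node);
    axis order matches ``parents``.  ``unseen`` lists parent configurations
    that never occurred in the data and were set to 0.5 (only possible with
    ``pseudo_count = 0``).
    """

    node: str
    parents: tuple[str, ...]
    p1: np.ndarray
    pseudo_count: float = 1.0
    unseen: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self):
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.p1.shape != (2,) * len(self.parents):
            raise ValueError("CPT shape does not match parent count")
        if ((self.p1 < 0) | (self.p1 > 1)).any():
            raise ValueError("CPT entries must lie in [0, 1]")

    def prob(self, value: int, config: tuple[int, ...] = ()) -> float:
        p = float(self.p1[config])
        return p if value == 1 else 1.0 - p


@dataclass
class TemporalBayesNet:
    """B = (G, P): a DAG over condition-year nodes plus one CPT per node."""

    graph: Graph
    cpts: dict[str, ConditionalProbabilityTable]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.cpts) != set(self.graph.nodes):
            raise ValueError("CPTs must cover exactly the graph's nodes")
        for label, cpt in self.cpts.items():
            expected = tuple(
                self.graph.nodes[p] for p in self.graph.parents(self.graph.index(label))
            )
            if tuple(cpt.parents) != expected:
                raise ValueError(
                    f"CPT parents {cpt.parents} for {label} do not match graph "
                    f"parents {expected}"
                )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.graph.nodes


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_cpts(
    graph: Graph, cohort: CohortTable, pseudo_count: float = 1.0
) -> TemporalBayesNet:
    """Additive-smoothing CPT estimation on a fixed DAG:
    ``P(x=1 | pa) = (N(1, pa) + a) / (N(pa) + 2a)`` with ``a = pseudo_count``.

    With ``a = 0`` a never-observed parent configuration is set to 0.5 and
    recorded in the CPT's ``unseen`` list.
    """
    missing = set(graph.nodes) - set(cohort.node_labels)
    if missing:
        raise ValueError(f"cohort lacks columns for nodes: {sorted(missing)}")
    X = cohort.values()
    col = {lab: k for k, lab in enumerate(cohort.node_labels)}
    cpts: dict[str, ConditionalProbabilityTable] = {}
    for i, label in enumerate(graph.nodes):
        parents = [graph.nodes[p] for p in graph.parents(i)]
        k = len(parents)
        x = X[:, col[label]]
        if k == 0:
            p1 = np.array(
                (x.sum() + pseudo_count) / (len(x) + 2 * pseudo_count)
            )
            unseen: list[tuple[int, ...]] = []
        else:
            weights = (1 << np.arange(k)).astype(np.int64)
            idx = X[:, [col[p] for p in parents]].astype(np.int64) @ weights
            q = 1 << k
            n_j = np.bincount(idx, minlength=q).astype(float)
            n_j1 = np.bincount(idx[x == 1], minlength=q).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                flat = (n_j1 + pseudo_count) / (n_j + 2 * pseudo_count)
            unseen = []
            if pseudo_count == 0:
                for j in np.flatnonzero(n_j == 0):
                    cfg = tuple((j >> b) & 1 for b in range(k))
                    unseen.append(cfg)
                    flat[j] = 0.5
            # encode index bit b ↔ parents[b]; reshape to (2,)*k with axis
            # order = parents order (axis 0 = parents[0]).
            p1 = np.zeros((2,) * k)
            for j in range(q):
                cfg = tuple((j >> b) & 1 for b in range(k))
                p1[cfg] = flat[j]
        cpts[label] = ConditionalProbabilityTable(
            node=label,
            parents=tuple(parents),
            p1=p1,
            pseudo_count=pseudo_count,
            unseen=tuple(unseen),
        )
    return TemporalBayesNet(graph=graph, cpts=cpts)


# ---------------------------------------------------------------------------
# joint probability and exact posteriors
# ---------------------------------------------------------------------------

def joint_probability(net: TemporalBayesNet, assignment: Mapping[str, int]) -> float:
    """Decomposition: product over nodes of P(x_i | parents(x_i))."""
    if set(assignment) != set(net.nodes):
        raise ValueError("joint_probability needs a full assignment; use posterior()")
    prod = 1.0
    for label, cpt in net.cpts.items():
        cfg = tuple(assignment[p] for p in cpt.parents)
        prod *= cpt.prob(assignment[label], cfg)
    return prod


def _factor_multiply(f1, f2):
    """Multiply two factors represented as (vars tuple, ndarray)."""
    v1, a1 = f1
    v2, a2 = f2
    out_vars = tuple(dict.fromkeys(v1 + v2))
    def expand(vs, arr):
        # insert singleton axes for missing vars, then transpose to out order
        shape = [2 if v in vs else 1 for v in out_vars]
        perm = [vs.index(v) for v in out_vars if v in vs]
        return arr.transpose(perm).reshape(shape)
    return out_vars, expand(v1, a1) * expand(v2, a2)


def _sum_out(factor, var):
    vs, arr = factor
    ax = vs.index(var)
    return tuple(v for v in vs if v != var), arr.sum(axis=ax)


def posterior(
    net: TemporalBayesNet, evidence: Mapping[str, int], query: str
) -> float:
    """Exact P(query = 1 | evidence) by variable elimination.

    Hidden nodes are eliminated in reverse topological order after pruning
    barren leaves (hidden nodes without retained children, whose factors
    sum to one).  Raises on evidence with zero probability.
    """
    if query in evidence:
        raise ValueError("query node must not appear in the evidence")
    unknown = (set(evidence) | {query}) - set(net.nodes)
    if unknown:
        raise ValueError(f"unknown nodes: {sorted(unknown)}")
    g = net.graph
    keep = set(net.nodes)
    fixed = set(evidence) | {query}
    # iteratively drop barren hidden leaves
    changed = True
    while changed:
        changed = False
        for label in list(keep):
            if label in fixed:
                continue
            i = g.index(label)
            if not any(g.nodes[c] in keep for c in g.children(i)):
                keep.discard(label)
                changed = True
    factors = []
    for label in keep:
        cpt = net.cpts[label]
        vars_ = (label,) + cpt.parents
        arr = np.stack([1.0 - cpt.p1, cpt.p1], axis=0)  # axis 0 = node value
        # reduce by evidence
        vs = list(vars_)
        for v in vars_:
            if v in evidence:
                ax = vs.index(v)
                arr = np.take(arr, evidence[v], axis=ax)
                vs.remove(v)
        factors.append((tuple(vs), np.asarray(arr, dtype=float)))
    topo = [g.nodes[i] for i in g.topological_order()]
    hidden = [v for v in reversed(topo) if v in keep and v not in fixed]
    for var in hidden:
        group = [f for f in factors if var in f[0]]
        rest = [f for f in factors if var not in f[0]]
        prod = group[0]
        for f in group[1:]:
            prod = _factor_multiply(prod, f)
        factors = rest + [_sum_out(prod, var)]
    result = ((), np.array(1.0))
    for f in factors:
        result = _factor_multiply(result, f)
    vs, arr = result
    if vs == ():
        # query was pruned/needless; shouldn't happen since query is fixed
        raise RuntimeError("query eliminated unexpectedly")
    ax = vs.index(query)
    arr = np.moveaxis(arr, ax, 0).reshape(2, -1).sum(axis=1)
    z = arr.sum()
    if z <= 0.0:
        raise ValueError("impossible evidence: probability zero under the network")
    return float(arr[1] / z)


def predict_future(
    net: TemporalBayesNet,
    cohort: CohortTable,
    target: tuple[str, int],
    evidence_years: Sequence[int] = (1,),
) -> np.ndarray:
    """Per-patient posterior of the target (condition, year) node given each
    patient's observed conditions in ``evidence_years`` (default: year 1).

    Posteriors are memoized over distinct evidence configurations, so cost
    scales with the number of distinct year-1 profiles, not with m.
    """
    cond, year = target
    if year in evidence_years:
        raise ValueError("target year must not be part of the evidence")
    target_label = temporal_label(cond, year)
    if target_label not in net.nodes:
        raise ValueError(f"target node {target_label!r} not in network")
    ev_labels = [
        lab
        for lab in cohort.node_labels
        if parse_temporal_label(lab)[1] in evidence_years and lab in net.nodes
    ]
    E = cohort.data[ev_labels].to_numpy()
    cache: dict[tuple[int, ...], float] = {}
    scores = np.empty(cohort.m)
    for r in range(cohort.m):
        key = tuple(E[r])
        if key not in cache:
            cache[key] = posterior(
                net, dict(zip(ev_labels, (int(v) for v in key))), target_label
            )
        scores[r] = cache[key]
    return scores


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with half-credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks → tie half-credit
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def cross_validate(
    cohort: CohortTable,
    pipeline: Callable[[CohortTable], TemporalBayesNet],
    k: int = 10,
    seed: int = 0,
    setting: str = "",
    targets: Sequence[tuple[str, int]] | None = None,
    evidence_years: Sequence[int] = (1,),
) -> pd.DataFrame:
    """k-fold cross-validated AUC per (condition, prediction year).

    Patients are shuffled by ``seed`` and split into k near-equal folds;
    per fold the pipeline is fit on the training rows and
    :func:`predict_future` scored on the held-out rows.  Cells whose
    held-out labels are single-class get ``NaN`` and a log entry.
    Returns a tidy frame with columns condition, year, setting, fold, auc.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > cohort.m:
        raise ValueError("more folds than patients")
    if targets is None:
        targets = [
            (c, y) for c in cohort.conditions for y in cohort.years if y not in evidence_years
        ]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.m)
    folds = np.array_split(perm, k)
    rows = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        net = pipeline(cohort.subset(train_idx))
        test = cohort.subset(test_idx)
        for cond, year in targets:
            y = test.column(temporal_label(cond, year))
            try:
                scores = predict_future(net, test, (cond, year), evidence_years)
                auc = roc_auc(scores, y)
            except ValueError:
                logger.warning(
                    "fold %d: single-class target %s_Y%d, AUC missing",
                    fold_id, cond, year,
                )
                auc = np.nan
            rows.append(
                {"condition": cond, "year": year, "setting": setting,
                 "fold": fold_id, "auc": auc}
            )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = seed
    out.attrs["k"] = k
    return out


def evaluation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC across folds, one row per (condition, year, setting)."""
    return (
        table.groupby(["condition", "year", "setting"], sort=True)["auc"]
        .mean()
        .reset_index()
        .rename(columns={"auc": "mean_auc"})
    )
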