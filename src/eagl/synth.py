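"""Synthetic cohorts and graphs emulating the study's two data regimes.

The real inputs — a restricted multi-year cohort of veteran patients
followed for five chronic conditions, and a term co-occurrence (lexicon)
graph mined from the literature — are not redistributable, so this module
generates stand-ins with known ground truth: a layered condition-by-year
Bayesian network with logistic-link CPTs, ancestral cohort sampling,
controlled spurious-edge contamination, and heavy-tailed weighted
co-occurrence graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .infer import ConditionalProbabilityTable, TemporalBayesNet
from .spectral import Graph, parse_temporal_label, temporal_label

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "GroundTruthSpec",
    "default_spec",
    "recovery_spec",
    "contamination_spec",
    "make_ground_truth",
    "sample_cohort",
    "inject_spurious_edges",
    "make_lexicon_graph",
]

#: cap on |logit| so that an "infinite" effect saturates instead of overflowing
LOGIT_CAP = 30.0

DEFAULT_CONDITIONS = ("TBI", "PTSD", "BaPa", "SuAb", "Depr")

#: year-1 baseline prevalences typical of a deployed-veteran care cohort
DEFAULT_PREVALENCE = {
    "TBI": 0.15,
    "PTSD": 0.25,
    "BaPa": 0.35,
    "SuAb": 0.15,
    "Depr": 0.30,
}

#: same-condition year-to-year carry-over (log-odds)
DEFAULT_PERSISTENCE = 2.2


def _persistence_edges(conditions: Sequence[str], years: int, effect: float):
    return [
        (temporal_label(c, y), temporal_label(c, y + 1), effect)
        for c in conditions
        for y in range(1, years)
    ]


def _default_cross_edges():
    # short-range carry-over for the two conditions without full persistence
    # chains, plus cross-condition pathways: brain injury drives PTSD, pain
    # feeds depression, depression feeds substance abuse
    return [
        ("TBI_Y1", "TBI_Y2", 2.0),
        ("SuAb_Y1", "SuAb_Y2", 2.0),
        ("TBI_Y1", "PTSD_Y2", 1.4),
        ("BaPa_Y1", "Depr_Y2", 0.9),
        ("PTSD_Y2", "Depr_Y3", 1.0),
        ("Depr_Y2", "SuAb_Y3", 1.2),
    ]


@dataclass(frozen=True)
class GroundTruthSpec:
    """Generator settings for a layered condition-by-year network.

    ``edges`` is the complete list of (parent_label, child_label, log-odds
    effect); the default is 18 edges — persistence chains for the three
    chronically persisting conditions (PTSD, Depr, BaPa) plus six
    cross-condition pathways.  ``prevalence`` gives the per-condition
    baseline P(condition) entering the logistic intercept.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    years: int = 5
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    persistence: float = DEFAULT_PERSISTENCE
    edges: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.years < 2:
            raise ValueError("need at least 2 years")
        for c in self.conditions:
            p = self.prevalence[c]
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {c} must be in (0,1), got {p}")

    def node_labels(self) -> tuple[str, ...]:
        return tuple(
            temporal_label(c, y) for c in self.conditions for y in range(1, self.years + 1)
        )


def default_spec(seed: int = 0) -> GroundTruthSpec:
    """The standard 5-condition × 5-year truth: 25 nodes, 18 edges."""
    edges = _persistence_edges(("PTSD", "Depr", "BaPa"), 5, DEFAULT_PERSISTENCE)
    edges += _default_cross_edges()
    return GroundTruthSpec(edges=tuple(edges), seed=seed)


def recovery_spec(seed: int = 0) -> GroundTruthSpec:
    """Structure-recovery benchmark: 3 conditions × 5 years, 18 edges
    (12 persistence + 6 cross-condition), with strong, learnable effects."""
    conditions = ("TBI", "PTSD", "Depr")
    edges = _persistence_edges(conditions, 5, DEFAULT_PERSISTENCE)
    edges += [
        ("TBI_Y1", "PTSD_Y2", 1.5),
        ("TBI_Y1", "Depr_Y2", 1.3),
        ("PTSD_Y1", "Depr_Y2", 1.2),
        ("TBI_Y2", "PTSD_Y3", 1.5),
        ("PTSD_Y2", "Depr_Y3", 1.2),
        ("PTSD_Y3", "Depr_Y4", 1.2),
    ]
    return GroundTruthSpec(
        conditions=conditions,
        prevalence={"TBI": 0.2, "PTSD": 0.25, "Depr": 0.3},
        edges=tuple(edges),
        seed=seed,
    )


def contamination_spec(seed: int = 0) -> GroundTruthSpec:
    """Fixture for spurious-edge experiments: full persistence chains for
    all five conditions (20 edges) plus six cross-condition pathways, so the
    true skeleton spans every node and injected edges always close cycles
    (making them prunable candidates rather than protected attachments)."""
    edges = _persistence_edges(DEFAULT_CONDITIONS, 5, DEFAULT_PERSISTENCE)
    edges += [
        ("TBI_Y1", "PTSD_Y2", 1.4),
        ("TBI_Y1", "Depr_Y2", 1.1),
        ("BaPa_Y1", "Depr_Y2", 0.9),
        ("PTSD_Y2", "Depr_Y3", 1.0),
        ("Depr_Y2", "SuAb_Y3", 1.2),
        ("PTSD_Y3", "SuAb_Y4", 1.0),
    ]
    return GroundTruthSpec(edges=tuple(edges), seed=seed)


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -LOGIT_CAP, LOGIT_CAP)))


def _logit(p: float) -> float:
    return float(np.clip(np.log(p / (1.0 - p)), -LOGIT_CAP, LOGIT_CAP))


def make_ground_truth(spec: GroundTruthSpec) -> TemporalBayesNet:
    """Build the ground-truth network with logistic-link CPTs:
    ``logit P(node=1 | pa) = logit(prevalence) + sum of active parents'
    effects``, with |logit| capped so extreme effects saturate."""
    labels = spec.node_labels()
    index = {lab: i for i, lab in enumerate(labels)}
    graph = Graph(labels, directed=True)
    effects: dict[tuple[str, str], float] = {}
    for parent, child, eff in spec.edges:
        py, cy = parse_temporal_label(parent)[1], parse_temporal_label(child)[1]
        pc, cc = parse_temporal_label(parent)[0], parse_temporal_label(child)[0]
        same_year_ok = py == cy and spec.conditions.index(pc) < spec.conditions.index(cc)
        if not (py < cy or same_year_ok):
            raise ValueError(f"edge {parent}->{child} violates the temporal constraint")
        # edge weight = interaction strength, so spectral pruning of the
        # weighted model sees weak dependencies as weak connections
        graph.add_edge(index[parent], index[child], weight=abs(float(eff)))
        effects[(parent, child)] = float(eff)
    cpts: dict[str, ConditionalProbabilityTable] = {}
    for label in labels:
        cond = parse_temporal_label(label)[0]
        parents = tuple(labels[p] for p in graph.parents(index[label]))
        base = _logit(spec.prevalence[cond])
        k = len(parents)
        p1 = np.zeros((2,) * k)
        for cfg in np.ndindex(*((2,) * k)):
            z = base + sum(
                effects[(par, label)] for par, on in zip(parents, cfg) if on
            )
            p1[cfg] = _logistic(z)
        cpts[label] = ConditionalProbabilityTable(
            node=label, parents=parents, p1=p1, pseudo_count=0.0
        )
    net = TemporalBayesNet(graph=graph, cpts=cpts)
    net.meta["spec"] = spec
    return net


def sample_cohort(net: TemporalBayesNet, m: int, seed: int = 0) -> CohortTable:
    """Ancestral sampling in topological order; fully seed-deterministic."""
    if m < 0:
        raise ValueError("m must be >= 0")
    rng = np.random.default_rng(seed)
    labels = net.nodes
    X = np.zeros((m, len(labels)), dtype=np.uint8)
    col = {lab: i for i, lab in enumerate(labels)}
    for i in net.graph.topological_order():
        label = labels[i]
        cpt = net.cpts[label]
        if cpt.parents:
            idx = tuple(X[:, col[p]] for p in cpt.parents)
            p = cpt.p1[idx]
        else:
            p = np.full(m, float(cpt.p1))
        X[:, col[label]] = (rng.random(m) < p).astype(np.uint8)
    df = pd.DataFrame(X, columns=list(labels))
    df.index.name = "patient_id"
    return CohortTable(df, seed=seed)


def inject_spurious_edges(
    net: TemporalBayesNet, count: int, effect_cap: float, seed: int = 0
) -> TemporalBayesNet:
    """Contaminate a ground-truth network with ``count`` random
    temporally-legal extra edges of small effect (|effect| <= effect_cap).

    The network must carry its generating spec (``net.meta["spec"]``); the
    contaminated network is rebuilt from the augmented spec, so acyclicity
    is preserved by construction.  The injected edges are recorded in
    ``meta["injected"]``.
    """
    spec: GroundTruthSpec | None = net.meta.get("spec")
    if spec is None:
        raise ValueError("net does not carry a GroundTruthSpec to contaminate")
    labels = spec.node_labels()
    existing = {(p, c) for p, c, _ in spec.edges}
    legal = [
        (p, c)
        for p in labels
        for c in labels
        if parse_temporal_label(p)[1] < parse_temporal_label(c)[1]
        and (p, c) not in existing
    ]
    if count > len(legal):
        raise ValueError(f"cannot inject {count} edges; only {len(legal)} legal slots")
    rng = np.random.default_rng(seed)
    chosen = [legal[i] for i in rng.choice(len(legal), size=count, replace=False)]
    effs = rng.uniform(-effect_cap, effect_cap, size=count) if effect_cap > 0 else np.zeros(count)
    new_edges = spec.edges + tuple(
        (p, c, float(e)) for (p, c), e in zip(chosen, effs)
    )
    out = make_ground_truth(replace(spec, edges=new_edges))
    out.meta["injected"] = tuple(chosen)
    return out


def make_lexicon_graph(
    n_terms: int = 60,
    n_pairs: int = 200,
    weight_law: str = "lognormal",
    seed: int = 0,
) -> Graph:
    """A connected weighted undirected co-occurrence graph.

    Defaults mirror the scale of a literature lexicon graph: the 200 most
    frequent co-occurring pairs over 60 terms (few enough terms that deep
    summarization ratios can keep the graph connected).  Connectivity is
    guaranteed
    by seeding with a random spanning tree before adding extra pairs;
    weights follow a heavy-tailed law (co-occurrence counts are Zipf-like).
    """
    max_pairs = n_terms * (n_terms - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError("n_pairs exceeds the number of distinct term pairs")
    if n_pairs < n_terms - 1:
        raise ValueError("need at least n_terms - 1 pairs for a connected graph")
    rng = np.random.default_rng(seed)
    labels = [f"term{i:03d}" for i in range(n_terms)]
    edges: set[tuple[int, int]] = set()
    order = rng.permutation(n_terms)
    for pos in range(1, n_terms):  # random spanning tree
        a = int(order[pos])
        b = int(order[rng.integers(0, pos)])
        edges.add((min(a, b), max(a, b)))
    while len(edges) < n_pairs:
        a, b = rng.integers(0, n_terms, size=2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    if weight_law == "lognormal":
        w = rng.lognormal(mean=2.0, sigma=1.0, size=len(edges))
    elif weight_law == "pareto":
        w = 1.0 + rng.pareto(a=1.5, size=len(edges))
    elif weight_law == "uniform":
        w = rng.uniform(1.0, 10.0, size=len(edges))
    else:
        raise ValueError(f"unknown weight law {weight_law!r}")
    return Graph(
        labels,
        [(i, j, float(wt)) for (i, j), wt in zip(sorted(edges), w)],
        directed=False,
    )
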