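"""File formats: cohort CSV, edge-list TSV, GraphML, CPT JSON, trace JSONL,
evaluation CSV, and run-report JSON with config hashing."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .infer import ConditionalProbabilityTable, TemporalBayesNet
from .spectral import Graph
from .summarize import PruneRecord, PruneTrace

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_graph",
    "write_graph",
    "read_cpts",
    "write_cpts",
    "write_trace",
    "read_trace",
    "write_report",
    "write_evaluation",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- cohort CSV --------------------------------------------------------------

def read_cohort(path) -> CohortTable:
    df = pd.read_csv(path, index_col=0)
    table = CohortTable(df)  # validates binary cells and column labels
    logger.info(
        "read cohort %s: m=%d, nodes=%d, mean prevalence %.3f",
        path, table.m, table.n, float(table.prevalence().mean()) if table.m else 0.0,
    )
    return table


def write_cohort(table: CohortTable, path) -> None:
    df = table.data.copy()
    df.index.name = df.index.name or "patient_id"
    df.to_csv(path)


# -- graphs ------------------------------------------------------------------

def write_graph(graph: Graph, path, format: str = "edgelist") -> None:
    """Edge-list TSV (with a ``# nodes:`` comment carrying isolated nodes
    and node order) or GraphML."""
    path = Path(path)
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"# directed: {graph.directed}\n")
            fh.write("# nodes: " + "\t".join(graph.nodes) + "\n")
            fh.write("# source\ttarget\tweight\n")
            for i, j, w in graph.edge_list():
                fh.write(f"{graph.nodes[i]}\t{graph.nodes[j]}\t{w!r}\n")
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(graph.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str = "edgelist", directed: bool = True) -> Graph:
    path = Path(path)
    if format == "graphml":
        import networkx as nx

        return Graph.from_networkx(nx.read_graphml(path))
    if format != "edgelist":
        raise ValueError(f"unknown graph format {format!r}")
    nodes: list[str] = []
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("directed:"):
                    directed = body.split(":", 1)[1].strip() == "True"
                elif body.startswith("nodes:"):
                    nodes = body.split(":", 1)[1].strip().split("\t")
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"malformed edge line: {line!r}")
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) == 3 else 1.0
            edges.append((u, v, w))
    if not nodes:
        seen: list[str] = []
        for u, v, _ in edges:
            for lab in (u, v):
                if lab not in seen:
                    seen.append(lab)
        nodes = seen
    idx = {lab: i for i, lab in enumerate(nodes)}
    g = Graph(nodes, directed=directed)
    for u, v, w in edges:
        g.add_edge(idx[u], idx[v], w)  # raises on duplicate edges
    return g


# -- CPT JSON ----------------------------------------------------------------

def write_cpts(net: TemporalBayesNet, path) -> None:
    """Schema: [{node, parents, rows: [{config: [...], p1: float}]}]."""
    payload = []
    for label in net.nodes:
        cpt = net.cpts[label]
        rows = [
            {"config": [int(v) for v in cfg], "p1": float(cpt.p1[cfg])}
            for cfg in np.ndindex(*((2,) * len(cpt.parents)))
        ]
        payload.append(
            {
                "node": label,
                "parents": list(cpt.parents),
                "pseudo_count": cpt.pseudo_count,
                "rows": rows,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_cpts(graph: Graph, path) -> TemporalBayesNet:
    with open(path) as fh:
        payload = json.load(fh)
    cpts = {}
    for entry in payload:
        parents = tuple(entry["parents"])
        k = len(parents)
        p1 = np.zeros((2,) * k)
        for row in entry["rows"]:
            p1[tuple(row["config"])] = row["p1"]
        cpts[entry["node"]] = ConditionalProbabilityTable(
            node=entry["node"],
            parents=parents,
            p1=p1,
            pseudo_count=entry.get("pseudo_count", 1.0),
        )
    return TemporalBayesNet(graph=graph, cpts=cpts)


# -- trace / report / evaluation --------------------------------------------

def write_trace(trace: PruneTrace, path) -> None:
    """JSON lines: one header record then one record per removal."""
    with open(path, "w") as fh:
        header = {
            "e0": trace.e0,
            "e_final": trace.e_final,
            "lambda2_initial": trace.lambda2_initial,
            "lambda2_final": trace.lambda2_final,
            "warnings": trace.warnings,
        }
        fh.write(json.dumps(header) + "\n")
        for rec in trace.records:
            fh.write(json.dumps(asdict(rec)) + "\n")


def read_trace(path) -> PruneTrace:
    with open(path) as fh:
        lines = [json.loads(s) for s in fh if s.strip()]
    header, rest = lines[0], lines[1:]
    records = [
        PruneRecord(
            round=r["round"],
            edge=tuple(r["edge"]),
            delta_lambda2=r["delta_lambda2"],
            relative=r["relative"],
            lambda2_after=r["lambda2_after"],
        )
        for r in rest
    ]
    return PruneTrace(
        records=records,
        e0=header["e0"],
        e_final=header["e_final"],
        lambda2_initial=header["lambda2_initial"],
        lambda2_final=header["lambda2_final"],
        warnings=list(header.get("warnings", [])),
    )


def write_report(report: dict, path, config: dict | None = None, seed=None) -> None:
    """JSON report embedding the config echo, its hash, and the seed."""
    out = dict(report)
    if config is not None:
        out["config"] = config
        out["config_hash"] = config_hash(config)
    if seed is not None:
        out["seed"] = seed
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, default=str)


def write_evaluation(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
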