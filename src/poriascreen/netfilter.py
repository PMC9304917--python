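"""Network-pharmacology filtering and topology ranking on user-supplied tables.

Operates entirely on offline CSV-style tables (no live TCMSP /
SwissTargetPrediction / DAVID queries): component records with oral
bioavailability (OB, percent) and drug-likeness (DL) columns are kept at
OB >= 30 and DL >= 0.18 (inclusive); target-target interaction edges are kept
at confidence score strictly > 0.9 with isolated nodes dropped; core targets
are the nodes with degree >= 6 whose betweenness and closeness centralities
both exceed their network medians; and component/target/pathway nodes are
ranked by simple-graph degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

OB_MIN = 30.0
DL_MIN = 0.18
PPI_SCORE_MIN = 0.9
CORE_DEGREE_MIN = 6


@dataclass
class TopologyResult:
    degree: dict
    betweenness: dict
    closeness: dict
    core_targets: set = field(default_factory=set)


def filter_components(records: pd.DataFrame) -> pd.DataFrame:
    """Keep components with OB >= 30% and DL >= 0.18 (both inclusive).

    Rows missing either field are rejected with a warning that counts them.
    """
    required = {"component", "OB", "DL"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"missing column(s): {sorted(missing_cols)}")
    bad = records["OB"].isna() | records["DL"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} row(s) rejected for missing OB/DL")
    ok = records[~bad]
    return ok[(ok["OB"] >= OB_MIN) & (ok["DL"] >= DL_MIN)].reset_index(drop=True)


def build_ppi(edges: pd.DataFrame, score_min: float = PPI_SCORE_MIN) -> nx.Graph:
    """Undirected simple PPI graph from scored target-target edges.

    Edges with confidence score strictly > ``score_min`` are kept; duplicate
    rows collapse to one edge; self-loops and nodes left without edges are
    removed.
    """
    tt = edges[edges["kind"] == "target-target"] if "kind" in edges.columns else edges
    if tt["score"].isna().any():
        raise ValueError("target-target edges must carry a confidence score")
    g = nx.Graph()
    for _, row in tt.iterrows():
        if row["source"] == row["target"]:
            continue
        if row["score"] > score_min:
            g.add_edge(row["source"], row["target"], score=float(row["score"]))
    return g


def core_targets(graph: nx.Graph, degree_min: int = CORE_DEGREE_MIN) -> TopologyResult:
    """Degree/centrality screen for core targets.

    Core = degree >= degree_min AND betweenness > median AND closeness >
    median (medians over all nodes). In a fully symmetric network nothing
    strictly exceeds the median, so the core is empty — by design.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(graph.degree())
    btw = nx.betweenness_centrality(graph)
    cls = nx.closeness_centrality(graph)
    med_b = float(np.median(list(btw.values())))
    med_c = float(np.median(list(cls.values())))
    core = {
        n
        for n in graph.nodes
        if degree[n] >= degree_min and btw[n] > med_b and cls[n] > med_c
    }
    return TopologyResult(degree=degree, betweenness=btw, closeness=cls, core_targets=core)


def degree_ranking(edges: pd.DataFrame) -> list[tuple[str, int]]:
    """Nodes of the component-target-pathway network by descending degree.

    Duplicate edges collapse (simple graph); ties break alphabetically.
    """
    g = nx.Graph()
    for _, row in edges.iterrows():
        if row["source"] != row["target"]:
            g.add_edge(row["source"], row["target"])
    ranked = sorted(g.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    return [(str(n), int(d)) for n, d in ranked]


def load_toy_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shipped toy component and edge tables for offline testing and demos.

    Synthetic stand-ins shaped like TCMSP/STRING exports (columns OB, DL,
    kind, score); they are not a real database snapshot.
    """
    pkg = resources.files("poriascreen.data")
    comp = pd.read_csv(pkg / "toy_components.csv")
    edges = pd.read_csv(pkg / "toy_edges.csv")
    return comp, edges
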