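"""Directed acyclic gene regulatory networks.

A :class:`Grn` is a DAG over genes: an edge A -> B with probability p says
gene A regulates gene B with posterior probability p.  Node classes follow
the usual convention: roots have no incoming edges (isolated nodes count as
roots), leaves have no outgoing edges, everything else is intermediate.

The module also implements the network-construction steps: greedy maximal
DAG assembly from an asymmetric edge-score matrix, probability thresholding,
the global FDR of the retained edges, topology-preserving randomization, and
summary reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import DataValidationError

__all__ = [
    "Grn",
    "NetworkSummary",
    "greedy_dag",
    "threshold_edges",
    "global_fdr",
    "randomize_grn",
    "network_summary",
    "threshold_grid",
    "read_edge_list",
    "write_edge_list",
]


class Grn:
    """A directed acyclic graph over genes with per-edge probabilities."""

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str, float]] = (),
    ):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for source, target, prob in edges:
            g.add_edge(source, target, probability=float(prob))
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DataValidationError(f"edge set contains a cycle: {cycle}")
        self._g = g

    # -- basic queries ------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(s, t, d["probability"]) for s, t, d in self._g.edges(data=True)]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, gene_id: str) -> bool:
        return self._g.has_node(gene_id)

    def parents(self, gene_id: str) -> list[str]:
        return sorted(self._g.predecessors(gene_id))

    def children(self, gene_id: str) -> list[str]:
        return sorted(self._g.successors(gene_id))

    def grandparents(self, gene_id: str) -> list[str]:
        gp: set[str] = set()
        for p in self._g.predecessors(gene_id):
            gp.update(self._g.predecessors(p))
        return sorted(gp)

    def node_class(self, gene_id: str) -> str:
        has_in = self._g.in_degree(gene_id) > 0
        has_out = self._g.out_degree(gene_id) > 0
        if not has_in:
            return "root"
        return "intermediate" if has_out else "leaf"

    def topological_order(self) -> list[str]:
        # lexicographic tie-break keeps the order deterministic
        return list(nx.lexicographical_topological_sort(self._g))

    def edge_probability(self, source: str, target: str) -> float:
        return self._g.edges[source, target]["probability"]

    def in_degrees(self) -> dict[str, int]:
        return dict(self._g.in_degree())

    def out_degrees(self) -> dict[str, int]:
        return dict(self._g.out_degree())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grn):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(
            other.edges
        )

    def __repr__(self) -> str:
        return f"Grn({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_roots: int
    n_intermediate: int
    n_leaves: int
    threshold: float | None = None
    global_fdr: float | None = None


def greedy_dag(scores: "EdgeScoreMatrix") -> Grn:  # noqa: F821
    """Build a maximal DAG by inserting edges in decreasing score order.

    Candidate edges are every off-diagonal, non-NaN entry of the score
    matrix.  They are visited by decreasing score — ties broken by
    (source id, target id) so the result is deterministic — and an edge is
    kept iff it does not create a cycle with the edges already accepted.

    Cycle checking maintains the transitive closure as a boolean reachability
    matrix, making each rejection O(1) and each insertion one vectorized
    outer-product update; adequate for the gene-panel sizes (hundreds of
    nodes) this package targets.
    """
    gene_ids = list(scores.gene_ids)
    mat = np.asarray(scores.scores, dtype=float)
    n = len(gene_ids)
    if mat.shape != (n, n):
        raise ValueError("score matrix must be square over gene_ids")
    src, tgt = np.nonzero(~np.isnan(mat) & ~np.eye(n, dtype=bool))
    order = sorted(
        range(len(src)),
        key=lambda k: (-mat[src[k], tgt[k]], gene_ids[src[k]], gene_ids[tgt[k]]),
    )
    reach = np.zeros((n, n), dtype=bool)  # reach[a, b]: path a -> b exists
    edges: list[tuple[str, str, float]] = []
    idx = np.arange(n)
    for k in order:
        u, v = int(src[k]), int(tgt[k])
        if reach[v, u] or u == v:
            continue  # would close a cycle
        edges.append((gene_ids[u], gene_ids[v], float(mat[u, v])))
        anc = reach[:, u] | (idx == u)
        desc = reach[v, :] | (idx == v)
        reach |= np.outer(anc, desc)
    return Grn(gene_ids, edges)


def threshold_edges(grn: Grn, threshold: float) -> Grn:
    """Keep edges whose probability strictly exceeds ``threshold``.

    The node set is unchanged; nodes losing all edges become isolated roots.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [(s, t, p) for s, t, p in grn.edges if p > threshold]
    return Grn(grn.nodes, kept)


def global_fdr(grn: Grn) -> float | None:
    """One minus the mean posterior probability of the retained edges.

    Returns None for an edgeless network (the quantity is undefined).
    """
    probs = [p for _, _, p in grn.edges]
    if not probs:
        return None
    return 1.0 - float(np.mean(probs))


def randomize_grn(grn: Grn, seed: int) -> Grn:
    """Topology-preserving randomization by node relabelling.

    A topological order of the DAG is computed and shuffled; node at
    position i of the original order takes the label at position i of the
    shuffled order.  The unlabeled edge structure — hence acyclicity, degree
    multisets and node-class counts — is preserved exactly.
    """
    order = grn.topological_order()
    rng = np.random.default_rng(seed)
    shuffled = [order[i] for i in rng.permutation(len(order))]
    relabel = dict(zip(order, shuffled))
    edges = [(relabel[s], relabel[t], p) for s, t, p in grn.edges]
    return Grn(grn.nodes, edges)


def network_summary(grn: Grn, threshold: float | None = None) -> NetworkSummary:
    classes = [grn.node_class(g) for g in grn.nodes]
    return NetworkSummary(
        n_nodes=grn.n_nodes,
        n_edges=grn.n_edges,
        n_roots=classes.count("root"),
        n_intermediate=classes.count("intermediate"),
        n_leaves=classes.count("leaf"),
        threshold=threshold,
        global_fdr=global_fdr(grn),
    )


def threshold_grid(grn: Grn, thresholds: Sequence[float]) -> pd.DataFrame:
    """Network characteristics across a grid of edge-probability thresholds.

    Supports choosing thresholds that equalize characteristics (node, edge
    and node-class counts) across networks built from different recipes.
    """
    rows = []
    for thr in thresholds:
        s = network_summary(threshold_edges(grn, thr), threshold=thr)
        rows.append(
            {
                "threshold": thr,
                "n_edges": s.n_edges,
                "n_roots": s.n_roots,
                "n_intermediate": s.n_intermediate,
                "n_leaves": s.n_leaves,
                "global_fdr": s.global_fdr if s.global_fdr is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Edge-list IO

_NODE_HEADER = "# nodes:"


def write_edge_list(grn: Grn, path: str | Path) -> None:
    """Write a Grn as TSV (source_gene, target_gene, probability).

    A leading comment line lists every node so that isolated nodes survive
    the round trip.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_NODE_HEADER + "\t" + ",".join(grn.nodes) + "\n")
        fh.write("source_gene\ttarget_gene\tprobability\n")
        for s, t, p in grn.edges:
            fh.write(f"{s}\t{t}\t{p!r}\n")


def read_edge_list(path: str | Path) -> Grn:
    """Inverse of :func:`write_edge_list`; raises on a cyclic edge set."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        nodes: list[str] = []
        if first.startswith(_NODE_HEADER):
            listing = first.split("\t", 1)[1] if "\t" in first else ""
            nodes = [n for n in listing.split(",") if n]
            header = fh.readline().rstrip("\n")
        else:
            header = first
        if header.split("\t")[:3] != ["source_gene", "target_gene", "probability"]:
            raise DataValidationError(
                f"bad edge-list header in {path}: {header!r}"
            )
        edges = []
        for line in fh:
            if not line.strip():
                continue
            s, t, p = line.rstrip("\n").split("\t")
            edges.append((s, t, float(p)))
    all_nodes = list(dict.fromkeys(nodes + [e[0] for e in edges] + [e[1] for e in edges]))
    return Grn(all_nodes, edges)
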