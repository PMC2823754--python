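"""Directed gene-labeled networks, path enumeration, and binary path datasets.

A metabolic network is modeled as a directed multigraph whose nodes are
compounds and whose edges are reactions labeled by the gene catalyzing them.
A path from the designated start compound to the end compound is encoded as a
binary vector over the network's edges (1 = edge traversed), so a dataset of
observed paths is an N x P binary matrix where P is the number of edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger("hme3m")

__all__ = [
    "GeneNetwork",
    "ExpressionMatrix",
    "PathwayDataset",
    "enumerate_paths",
    "count_paths",
    "binarize_expression",
    "build_pathway_dataset",
]


class ConfigurationError(ValueError):
    """Invalid network / run configuration."""


@dataclass(frozen=True)
class GeneNetwork:
    """A directed compound network with gene-labeled edges.

    The edge list order is fixed at construction and defines the coordinate
    system of every path vector: coordinate ``t`` of a path vector is 1 iff
    edge ``t`` (0-based) is traversed.  Parallel edges between the same
    compound pair (distinct genes) are distinct coordinates.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, gene)
    start: str
    end: str

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if self.start not in nodeset:
            raise ConfigurationError(f"start node {self.start!r} not in network")
        if self.end not in nodeset:
            raise ConfigurationError(f"end node {self.end!r} not in network")
        for u, v, _g in self.edges:
            if u not in nodeset or v not in nodeset:
                raise ConfigurationError(f"edge ({u!r}, {v!r}) references unknown node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for _u, _v, g in self.edges)

    def out_edges(self, node: str) -> list[int]:
        """Indices of edges leaving ``node``, in coordinate order."""
        return self._adjacency().get(node, [])

    def _adjacency(self) -> dict[str, list[int]]:
        adj = getattr(self, "_adj_cache", None)
        if adj is None:
            adj = {}
            for t, (u, _v, _g) in enumerate(self.edges):
                adj.setdefault(u, []).append(t)
            object.__setattr__(self, "_adj_cache", adj)
        return adj

    def source_node_groups(self) -> list[list[int]]:
        """Edge-index groups sharing a source compound (normalization blocks)."""
        return list(self._adjacency().values())

    def to_multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for t, (u, v, gene) in enumerate(self.edges):
            g.add_edge(u, v, key=t, gene=gene, index=t)
        return g

    # ----- TSV round trip -------------------------------------------------
    @classmethod
    def from_tsv(cls, path, start: str, end: str) -> "GeneNetwork":
        """Read a network from a TSV with header columns source, target, gene."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"source", "target", "gene"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"network TSV missing columns: {sorted(missing)}")
        edges = tuple(zip(df["source"], df["target"], df["gene"]))
        nodes = tuple(dict.fromkeys([n for u, v, _ in edges for n in (u, v)]))
        return cls(nodes=nodes, edges=edges, start=start, end=end)

    def to_tsv(self, path) -> None:
        pd.DataFrame(list(self.edges), columns=["source", "target", "gene"]).to_csv(
            path, sep="\t", index=False
        )

    def replay(self, x: Sequence[int]) -> bool:
        """True iff the binary vector ``x`` encodes a connected start->end walk."""
        chosen = [t for t, b in enumerate(x) if b]
        if not chosen:
            return False
        node = self.start
        remaining = set(chosen)
        while remaining:
            nxt = [t for t in remaining if self.edges[t][0] == node]
            if len(nxt) != 1:
                return False
            (t,) = nxt
            node = self.edges[t][1]
            remaining.discard(t)
        return node == self.end


@dataclass
class ExpressionMatrix:
    """Real-valued gene expression (genes x samples) with binary sample labels."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    labels: pd.Series  # index = sample ids, values in {0, 1}

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ConfigurationError(f"samples without labels: {missing}")
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise ConfigurationError("labels must be binary (0/1)")

    @classmethod
    def from_tsv(cls, expr_path, labels_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        lab = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0].astype(int)
        return cls(values=values, labels=lab)


@dataclass
class PathwayDataset:
    """Binary path observations: X is N x P over network edges, y the response."""

    X: np.ndarray
    y: np.ndarray
    provenance: list | None = None
    network: GeneNetwork | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y row counts differ")
        vals = np.unique(self.X) if self.X.size else np.array([0])
        if not set(vals.tolist()).issubset({0, 1}):
            raise ValueError("X entries must be exactly 0 or 1")
        self.X = self.X.astype(np.int8)
        self.y = self.y.astype(np.int8)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path) -> None:
        """Write 0/1 edge columns plus a final ``y`` column (lossless)."""
        cols = [f"e{t + 1}" for t in range(self.p)]  # 1-based edge names
        df = pd.DataFrame(self.X, columns=cols)
        df["y"] = self.y
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, network: GeneNetwork | None = None) -> "PathwayDataset":
        df = pd.read_csv(path, sep="\t")
        if "y" not in df.columns:
            raise ValueError("pathway TSV must contain a final 'y' column")
        y = df.pop("y").to_numpy()
        return cls(X=df.to_numpy(), y=y, network=network)


# ---------------------------------------------------------------------------
# Path enumeration
# ---------------------------------------------------------------------------

def enumerate_paths(
    network: GeneNetwork, active_edges: Iterable[int] | None = None
) -> list[np.ndarray]:
    """All simple directed start->end paths as binary edge vectors.

    Only edges whose index is in ``active_edges`` may be traversed (all edges
    when ``None``).  Paths are simple — no compound is visited twice — so
    enumeration terminates on cyclic networks.  The output order is
    deterministic: lexicographic in the sequence of traversed edge indices.
    """
    if active_edges is None:
        active = set(range(network.n_edges))
    else:
        active = set(active_edges)
        bad = active - set(range(network.n_edges))
        if bad:
            raise ConfigurationError(f"active edge indices out of range: {sorted(bad)}")

    paths: list[np.ndarray] = []
    stack: list[int] = []
    visited = {network.start}

    def dfs(node: str) -> None:
        if node == network.end:
            vec = np.zeros(network.n_edges, dtype=np.int8)
            vec[stack] = 1
            paths.append(vec)
            return
        for t in network.out_edges(node):
            if t not in active:
                continue
            v = network.edges[t][1]
            if v in visited:
                continue
            visited.add(v)
            stack.append(t)
            dfs(v)
            stack.pop()
            visited.discard(v)

    if network.start != network.end:
        dfs(network.start)
    return paths


def count_paths(network: GeneNetwork) -> int:
    """Number of simple start->end paths with every edge active."""
    return len(enumerate_paths(network))


# ---------------------------------------------------------------------------
# Expression -> binary activity -> path dataset
# ---------------------------------------------------------------------------

def binarize_expression(expr: ExpressionMatrix, tolerance: float) -> pd.DataFrame:
    """Per-gene z-score across samples, then call a gene active iff z > tolerance.

    Each gene's observations are standardized to mean 0, standard deviation 1
    (sample sd); activity is a strict threshold on the z-score, so a value
    exactly at the tolerance is inactive.  Zero-variance genes cannot be
    standardized and are marked inactive everywhere with a warning.
    """
    vals = expr.values
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene to standardize")
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "zero-variance genes set inactive everywhere: %s",
            list(vals.index[zero_var]),
        )
    sd_safe = sd.replace(0, np.nan)
    z = vals.sub(mu, axis=0).div(sd_safe, axis=0)
    activity = (z > tolerance).astype(np.int8)
    activity[zero_var] = 0
    return activity


def build_pathway_dataset(
    network: GeneNetwork, expr: ExpressionMatrix, tolerance: float
) -> PathwayDataset:
    """Extract every valid start->end path from each sample's active genes.

    A network edge is traversable for a sample iff its gene is active (z-score
    above ``tolerance``) in that sample.  All simple start->end paths through
    the traversable edges become rows, labeled with the sample's response.
    Samples yielding no path are skipped with a warning.
    """
    gene_rows = set(expr.values.index)
    needed = set(network.genes)
    missing = sorted(needed - gene_rows)
    if missing:
        raise ConfigurationError(f"genes on network edges missing from expression: {missing}")

    activity = binarize_expression(expr, tolerance)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    provenance: list[str] = []
    for sample in expr.values.columns:
        act = activity[sample]
        active_edges = [t for t, g in enumerate(network.genes) if act.loc[g] == 1]
        paths = enumerate_paths(network, active_edges)
        if not paths:
            logger.warning("sample %s yields no start->end path; skipped", sample)
            continue
        rows.extend(paths)
        labels.extend([int(expr.labels.loc[sample])] * len(paths))
        provenance.extend([sample] * len(paths))
    X = np.array(rows, dtype=np.int8) if rows else np.zeros((0, network.n_edges), np.int8)
    return PathwayDataset(X=X, y=np.array(labels, dtype=np.int8),
                          provenance=provenance, network=network)
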