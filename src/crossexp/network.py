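"""Thresholded Pearson co-expression networks.

Each gene's replicate-averaged expression profile across conditions is
correlated against every other gene's (sample Pearson coefficient r). The
two-sided p-value comes from the exact t transform

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2,

with |r| = 1 mapped to p = 0 (the limit). Gene pairs with r strictly above
the PCC cutoff and p strictly below the p-value cutoff become undirected,
unweighted edges; nodes with no surviving edge are dropped from the network
node set (they cannot affect modularity) while the full candidate-pair
count C(n_genes, 2) is kept for provenance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "CoexpressionNetwork",
    "from_edges",
    "pearson_matrix",
    "build_edge_list",
    "network_stats",
]


@dataclass
class CorrelationResult:
    """Symmetric Pearson r and two-sided p matrices over a gene set."""

    genes: list[str]
    r: np.ndarray
    p: np.ndarray
    n_conditions: int


@dataclass
class CoexpressionNetwork:
    """Undirected, unweighted per-species co-expression network.

    Edges are stored once in canonical (lexicographically sorted) tuple
    order; ``nodes`` are the genes incident to at least one edge (isolated
    nodes may be added explicitly, e.g. when a network is assembled from an
    external edge list plus a node list). ``n_candidate_pairs`` records how
    many gene pairs were screened before thresholding.
    """

    species_tag: str = ""
    nodes: list[str] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)
    degree: dict[str, int] = field(default_factory=dict)
    m: int = 0
    n_candidate_pairs: int = 0

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge on node {u!r}")
            if u > v:
                raise ValueError(f"edge ({u!r}, {v!r}) not in canonical order")
        if not self.degree and self.edges:
            self.degree = _degrees(self.edges, self.nodes)
        if self.m == 0:
            self.m = len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        if u == v:
            return False
        return ((u, v) if u < v else (v, u)) in self.edges

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        return adj


def _degrees(edges: set[tuple[str, str]], nodes: list[str]) -> dict[str, int]:
    deg: Counter = Counter()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    out = {n: 0 for n in nodes}
    out.update(deg)
    return out


def from_edges(
    edges: set[tuple[str, str]],
    species_tag: str = "",
    extra_nodes: list[str] | None = None,
    n_candidate_pairs: int | None = None,
) -> CoexpressionNetwork:
    """Build a network from raw unordered pairs (canonicalizing order)."""
    canon = set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-edge on node {u!r}")
        canon.add((u, v) if u < v else (v, u))
    incident = sorted({n for e in canon for n in e})
    nodes = sorted(set(incident) | set(extra_nodes or []))
    n_nodes = len(nodes)
    return CoexpressionNetwork(
        species_tag=species_tag,
        nodes=nodes,
        edges=canon,
        degree=_degrees(canon, nodes),
        m=len(canon),
        n_candidate_pairs=(
            n_candidate_pairs
            if n_candidate_pairs is not None
            else n_nodes * (n_nodes - 1) // 2
        ),
    )


def pearson_matrix(m: ExpressionMatrix | pd.DataFrame) -> CorrelationResult:
    """All-pairs sample Pearson r and exact-t two-sided p-values.

    Requires at least 3 conditions and no zero-variance gene (enforce with
    :func:`crossexp.expression.filter_genes` upstream).
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    X = values.to_numpy(dtype=float)
    n_genes, n_cond = X.shape
    if n_cond < 3:
        raise ValueError(f"need >= 3 conditions, got {n_cond}")
    sd = X.std(axis=1)
    if (sd == 0).any():
        gene = values.index[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {gene!r} has zero variance across conditions")
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = n_cond - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0  # |r| = 1 limit
    np.fill_diagonal(p, 0.0)
    p = np.minimum(p, p.T)  # enforce exact symmetry
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationResult(genes=list(values.index), r=r, p=p, n_conditions=n_cond)


def build_edge_list(
    c: CorrelationResult,
    pcc_cutoff: float = 0.99,
    p_cutoff: float = 0.001,
    species_tag: str = "",
) -> CoexpressionNetwork:
    """Threshold a correlation result into a co-expression network.

    Edge (i, j) is included iff r[i, j] > pcc_cutoff AND p[i, j] < p_cutoff
    (both strict). Only positively correlated pairs can pass (the cutoff is
    on r, not |r|).
    """
    if not -1.0 <= pcc_cutoff <= 1.0:
        raise ValueError(f"pcc_cutoff must be in [-1, 1], got {pcc_cutoff}")
    if not 0.0 <= p_cutoff <= 1.0:
        raise ValueError(f"p_cutoff must be in [0, 1], got {p_cutoff}")
    n = len(c.genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = (c.r[iu, ju] > pcc_cutoff) & (c.p[iu, ju] < p_cutoff)
    genes = np.asarray(c.genes, dtype=object)
    edges = {
        tuple(sorted((genes[i], genes[j])))
        for i, j in zip(iu[keep], ju[keep])
    }
    return from_edges(
        edges, species_tag=species_tag, n_candidate_pairs=n * (n - 1) // 2
    )


def network_stats(net: CoexpressionNetwork) -> dict:
    """Node count, edge count, degree histogram, candidate-pair count."""
    hist = Counter(net.degree.values())
    return {
        "species_tag": net.species_tag,
        "n_nodes": len(net.nodes),
        "n_edges": net.m,
        "n_candidate_pairs": net.n_candidate_pairs,
        "degree_histogram": dict(sorted(hist.items())),
    }
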