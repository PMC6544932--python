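"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's efficient code paths: the objective
is evaluated by explicit loops over all node pairs, best hits by exhaustive
per-gene scans, and small-instance optima by full set-partition enumeration.
"""

from __future__ import annotations

import itertools
import math


def pair_modularity(net, i, j) -> float:
    """A_ij - k_i k_j / (2m) straight from the edge set and degree map."""
    key = (i, j) if i < j else (j, i)
    a = 1.0 if key in net.edges else 0.0
    if net.m == 0:
        return a
    return a - net.degree.get(i, 0) * net.degree.get(j, 0) / (2.0 * net.m)


def brute_objective(x, sigma, kappa: float) -> float:
    """Triple-loop evaluation of H over all within-species pairs and
    every ortholog pair."""
    s = sigma.sigma if hasattr(sigma, "sigma") else sigma
    H = 0.0
    for nodes, net in (
        (sorted(x.species1_nodes), x.net1),
        (sorted(x.species2_nodes), x.net2),
    ):
        for i, j in itertools.combinations(nodes, 2):
            if s[i] == s[j]:
                H -= pair_modularity(net, i, j)
    for (a, b) in x.orthologs.pairs:
        if s[a] == s[b]:
            H -= kappa * x.orthologs.weights.get((a, b), 1.0)
    return H


def set_partitions(items):
    """Yield every partition of ``items`` into non-empty groups."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [smaller[k] + [first]] + smaller[k + 1 :]
        yield smaller + [[first]]


def exhaustive_minimum(x, kappa: float) -> float:
    """Global minimum of H by enumerating all partitions of the universe."""
    best = math.inf
    for parts in set_partitions(x.universe):
        sigma = {}
        for label, group in enumerate(parts):
            for g in group:
                sigma[g] = label
        best = min(best, brute_objective(x, sigma, kappa))
    return best


def best_hits_oracle(hits, scheme, direction) -> dict[str, str]:
    """Exhaustive per-query-gene minimum scan with the deterministic
    ranking (evalue asc, bitscore desc, subject gene id asc)."""
    best: dict[str, tuple] = {}
    for row in hits.itertuples():
        qs = scheme.species_of(row.qseqid)
        ss = scheme.species_of(row.sseqid)
        if (qs, ss) != tuple(direction):
            continue
        qg = scheme.gene_of(row.qseqid, qs)
        sg = scheme.gene_of(row.sseqid, ss)
        key = (row.evalue, -row.bitscore, sg)
        if qg not in best or key < best[qg]:
            best[qg] = key
    return {q: key[2] for q, key in best.items()}


def rbh_oracle(hits, scheme) -> set[tuple[str, str]]:
    """Double-loop reciprocity check over the two best-hit directions."""
    fwd = best_hits_oracle(hits, scheme, ("a", "b"))
    rev = best_hits_oracle(hits, scheme, ("b", "a"))
    return {
        (a, b)
        for a, b in fwd.items()
        for b2, a2 in rev.items()
        if b == b2 and a == a2
    }
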