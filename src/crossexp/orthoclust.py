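"""Ortholog-coupled cross-species module finding by simulated annealing.

Two per-species co-expression networks are joined by weighted orthology
links and partitioned jointly by minimizing

    H = -( sum_{i<j in S1} L1_ij d(si, sj)
         + sum_{i<j in S2} L2_ij d(si, sj)
         + kappa * sum_{(i,j') in O} w_ij' d(si, sj') )

where L^N_ij = A_ij - k_i k_j / (2m) is the Newman-Girvan modularity score
of a node pair within its species' network (observed adjacency minus the
expected adjacency under the degree-preserving configuration null), d is 1
when the two nodes share a module label and 0 otherwise, O is the set of
cross-species ortholog pairs with coupling weights w, and the coupling
constant kappa sets the relative weight of orthology against co-expression.
Species sums run over unordered pairs; each ortholog pair is counted once.

H is minimized by single-node label moves under Metropolis acceptance with
geometric cooling. Moves are proposed from the labels of a node's
interacting neighbours (co-expression neighbours, plus ortholog partners
when kappa > 0) or a fresh label, so at kappa = 0 labels can never spread
across species and all modules are single-species by construction. All
nodes start in their own singleton module (H = 0), and the best state
visited is returned, so the result never scores worse than the singleton
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .homology import OrthologPairSet
from .network import CoexpressionNetwork

__all__ = [
    "CrossSpeciesNetwork",
    "OrthoClustParams",
    "ModuleAssignment",
    "modularity_score",
    "objective_H",
    "build_caches",
    "delta_H_single_move",
    "sa_optimize",
    "rank_labels",
    "summarize_modules",
    "count_modules",
    "parameter_sweep",
]


@dataclass
class CrossSpeciesNetwork:
    """Two species' co-expression networks coupled by ortholog links.

    The node universe is the union of both networks' nodes and every gene
    named in the ortholog pair set; genes present only in the ortholog list
    are retained as isolated nodes (coupling can still pull them into
    modules). Ortholog pairs are oriented (species-1 gene, species-2 gene).
    """

    net1: CoexpressionNetwork
    net2: CoexpressionNetwork
    orthologs: OrthologPairSet

    species1_nodes: set[str] = field(init=False)
    species2_nodes: set[str] = field(init=False)
    universe: list[str] = field(init=False)

    def __post_init__(self) -> None:
        n1, n2 = set(self.net1.nodes), set(self.net2.nodes)
        overlap = n1 & n2
        if overlap:
            raise ValueError(
                f"species node sets overlap: {sorted(overlap)[:5]}"
            )
        o1 = self.orthologs.genes(0)
        o2 = self.orthologs.genes(1)
        if (o1 & n2) or (o2 & n1):
            bad = sorted((o1 & n2) | (o2 & n1))[:5]
            raise ValueError(f"ortholog pair member(s) on the wrong side: {bad}")
        if o1 & o2:
            raise ValueError("ortholog pairs must span the two species")
        self.species1_nodes = n1 | o1
        self.species2_nodes = n2 | o2
        self.universe = sorted(self.species1_nodes) + sorted(self.species2_nodes)

    def species_of(self, node: str) -> int:
        if node in self.species1_nodes:
            return 1
        if node in self.species2_nodes:
            return 2
        raise KeyError(f"node {node!r} not in either species")

    def net_of(self, node: str) -> CoexpressionNetwork:
        return self.net1 if node in self.species1_nodes else self.net2

    def ortholog_neighbors(self) -> dict[str, list[tuple[str, float]]]:
        """node -> [(cross-species partner, coupling weight w), ...]."""
        out: dict[str, list[tuple[str, float]]] = {}
        for (a, b) in sorted(self.orthologs.pairs):
            w = self.orthologs.weights.get((a, b), 1.0)
            out.setdefault(a, []).append((b, w))
            out.setdefault(b, []).append((a, w))
        return out


@dataclass
class OrthoClustParams:
    """Coupling constant and annealing schedule.

    kappa >= 0 weighs orthology links against co-expression modularity
    (kappa = 0 decouples the species). One "sweep" proposes |nodes| single
    node moves; the temperature follows T <- cooling_alpha * T from T0 down
    to T_min. Restarts reuse seed + restart index; the lowest-H restart
    wins.
    """

    kappa: float = 3.0
    seed: int = 0
    n_restarts: int = 5
    T0: float = 1.0
    cooling_alpha: float = 0.9
    sweeps_per_T: int = 1
    T_min: float = 1e-4

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.T0 <= 0 or self.T_min <= 0:
            raise ValueError("temperatures must be > 0")
        if not 0.0 < self.cooling_alpha < 1.0:
            raise ValueError("cooling_alpha must be in (0, 1)")
        if self.sweeps_per_T < 1:
            raise ValueError("sweeps_per_T must be >= 1")


@dataclass
class ModuleAssignment:
    """Map node -> module label for the union of both species' genes."""

    sigma: dict[str, int]

    def __getitem__(self, node: str) -> int:
        return self.sigma[node]

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, label in self.sigma.items():
            out.setdefault(label, []).append(node)
        return out


def modularity_score(net: CoexpressionNetwork, i: str, j: str) -> float:
    """Pairwise modularity L_ij = A_ij - k_i k_j / (2m) within one network.

    Nodes absent from the network have degree 0 (score 0 unless adjacent,
    which they cannot be). An empty network scores every pair 0.
    """
    if i == j:
        raise ValueError(f"modularity score undefined for i == j ({i!r})")
    a = 1.0 if net.has_edge(i, j) else 0.0
    if net.m == 0:
        return a
    ki = net.degree.get(i, 0)
    kj = net.degree.get(j, 0)
    return a - ki * kj / (2.0 * net.m)


def _species_term(net: CoexpressionNetwork, sigma: dict[str, int]) -> float:
    """sum_{i<j same label} L_ij for one species, via the k-sum identity.

    Equals  sum_{edges same label} 1  -  sum_labels (K_L^2 - S_L) / (4m)
    with K_L the label's degree sum and S_L its sum of squared degrees.
    """
    if net.m == 0:
        return 0.0
    edge_term = sum(1.0 for u, v in net.edges if sigma[u] == sigma[v])
    ksum: dict[int, float] = {}
    ksq: dict[int, float] = {}
    for node in net.nodes:
        k = net.degree.get(node, 0)
        lab = sigma[node]
        ksum[lab] = ksum.get(lab, 0.0) + k
        ksq[lab] = ksq.get(lab, 0.0) + k * k
    null_term = sum((ksum[l] ** 2 - ksq[l]) for l in ksum) / (4.0 * net.m)
    return edge_term - null_term


def objective_H(
    x: CrossSpeciesNetwork, sigma: ModuleAssignment | dict[str, int], kappa: float
) -> float:
    """Evaluate H for a full labeling (lower is better; singletons give 0)."""
    s = sigma.sigma if isinstance(sigma, ModuleAssignment) else sigma
    missing = [n for n in x.universe if n not in s]
    if missing:
        raise ValueError(f"nodes missing a module label: {missing[:5]}")
    coupling = sum(
        x.orthologs.weights.get((a, b), 1.0)
        for (a, b) in x.orthologs.pairs
        if s[a] == s[b]
    )
    return -(_species_term(x.net1, s) + _species_term(x.net2, s) + kappa * coupling)


@dataclass
class _Caches:
    """Incremental-evaluation state for single-node and merge moves."""

    adj: dict[str, list[str]]            # same-species co-expression neighbours
    orth: dict[str, list[tuple[str, float]]]
    ksum: tuple[dict[int, float], dict[int, float]]  # per species: label -> degree sum
    members: dict[int, set[str]] = field(default_factory=dict)


def build_caches(x: CrossSpeciesNetwork, sigma: dict[str, int]) -> _Caches:
    adj: dict[str, list[str]] = {n: [] for n in x.universe}
    for net in (x.net1, x.net2):
        for u, v in net.edges:
            adj[u].append(v)
            adj[v].append(u)
    ksum1: dict[int, float] = {}
    ksum2: dict[int, float] = {}
    members: dict[int, set[str]] = {}
    for node in x.universe:
        sp = x.species_of(node)
        k = x.net_of(node).degree.get(node, 0)
        tgt = ksum1 if sp == 1 else ksum2
        lab = sigma[node]
        tgt[lab] = tgt.get(lab, 0.0) + k
        members.setdefault(lab, set()).add(node)
    return _Caches(
        adj=adj, orth=x.ortholog_neighbors(), ksum=(ksum1, ksum2), members=members
    )


def delta_H_single_move(
    x: CrossSpeciesNetwork,
    sigma: dict[str, int],
    node: str,
    new_label: int,
    kappa: float,
    caches: _Caches,
) -> float:
    """H(after) - H(before) for relabeling one node; O(degree) time.

    Consistent with full recomputation via :func:`objective_H` to within
    1e-9. Requires ``new_label != sigma[node]``.
    """
    old_label = sigma[node]
    if new_label == old_label:
        raise ValueError("new_label must differ from the node's current label")
    sp = x.species_of(node)
    net = x.net_of(node)
    k_v = net.degree.get(node, 0)

    e_old = e_new = 0
    for u in caches.adj[node]:
        if sigma[u] == old_label:
            e_old += 1
        elif sigma[u] == new_label:
            e_new += 1

    if net.m > 0 and k_v > 0:
        ksum = caches.ksum[sp - 1]
        K_old = ksum.get(old_label, 0.0) - k_v  # exclude the node itself
        K_new = ksum.get(new_label, 0.0)
        lam_old = e_old - k_v * K_old / (2.0 * net.m)
        lam_new = e_new - k_v * K_new / (2.0 * net.m)
    else:
        lam_old = float(e_old)
        lam_new = float(e_new)

    w_old = w_new = 0.0
    for partner, w in caches.orth.get(node, ()):
        if sigma[partner] == old_label:
            w_old += w
        elif sigma[partner] == new_label:
            w_new += w

    return -(lam_new - lam_old) - kappa * (w_new - w_old)


def _apply_move(
    x: CrossSpeciesNetwork,
    sigma: dict[str, int],
    node: str,
    new_label: int,
    caches: _Caches,
) -> None:
    sp = x.species_of(node)
    k_v = x.net_of(node).degree.get(node, 0)
    ksum = caches.ksum[sp - 1]
    old = sigma[node]
    ksum[old] = ksum.get(old, 0.0) - k_v
    if ksum[old] == 0.0:
        del ksum[old]
    ksum[new_label] = ksum.get(new_label, 0.0) + k_v
    sigma[node] = new_label
    grp = caches.members[old]
    grp.discard(node)
    if not grp:
        del caches.members[old]
    caches.members.setdefault(new_label, set()).add(node)


def _delta_H_merge(
    x: CrossSpeciesNetwork,
    sigma: dict[str, int],
    label_a: int,
    label_b: int,
    kappa: float,
    caches: _Caches,
) -> float:
    """H change from relabeling every member of module a to module b."""
    e_sp = [0, 0]
    w_ab = 0.0
    for v in caches.members[label_a]:
        sp = x.species_of(v)
        for u in caches.adj[v]:
            if sigma[u] == label_b:
                e_sp[sp - 1] += 1
        for partner, w in caches.orth.get(v, ()):
            if sigma[partner] == label_b:
                w_ab += w
    dH = 0.0
    for sp, net in ((1, x.net1), (2, x.net2)):
        lam = float(e_sp[sp - 1])
        if net.m > 0:
            ka = caches.ksum[sp - 1].get(label_a, 0.0)
            kb = caches.ksum[sp - 1].get(label_b, 0.0)
            lam -= ka * kb / (2.0 * net.m)
        dH -= lam
    return dH - kappa * w_ab


def _apply_merge(
    x: CrossSpeciesNetwork,
    sigma: dict[str, int],
    label_a: int,
    label_b: int,
    caches: _Caches,
) -> None:
    for sp in (0, 1):
        ksum = caches.ksum[sp]
        if label_a in ksum:
            ksum[label_b] = ksum.get(label_b, 0.0) + ksum.pop(label_a)
    moved = caches.members.pop(label_a)
    for v in moved:
        sigma[v] = label_b
    caches.members.setdefault(label_b, set()).update(moved)


def sa_optimize(
    x: CrossSpeciesNetwork, params: OrthoClustParams
) -> tuple[ModuleAssignment, float, list[dict]]:
    """Minimize H by simulated annealing over single-node label moves.

    Starts from the all-singleton labeling (H = 0). At each step a uniformly
    random node is proposed either a single-node relabeling — to a label
    drawn from its interacting neighbours' labels (co-expression
    neighbours; ortholog partners too when kappa > 0) or a fresh label — or,
    15% of the time, a collective move merging its whole module into an
    interacting neighbour's module (single-node dynamics alone cannot cross
    the energy barrier between two fully-formed modules that the coupling
    term favours joining). Moves are accepted if dH <= 0, else with
    probability exp(-dH / T); temperature cools geometrically. The best
    (lowest-H) state visited across ``n_restarts`` independent restarts is
    returned along with its H and a per-restart cooling trace.

    Deterministic given ``params.seed``.
    """
    nodes = x.universe
    best_sigma: dict[str, int] | None = None
    best_H = math.inf
    traces: list[dict] = []

    for restart in range(params.n_restarts):
        rng = np.random.default_rng(params.seed + restart)
        sigma = {node: i for i, node in enumerate(nodes)}
        next_label = len(nodes)
        caches = build_caches(x, sigma)
        H = 0.0
        run_best_H = H
        run_best_sigma = dict(sigma)
        trace: list[tuple[float, float]] = []

        use_orth = params.kappa > 0
        T = params.T0
        n = len(nodes)
        while T > params.T_min and n > 0:
            for _ in range(params.sweeps_per_T * n):
                node = nodes[int(rng.integers(n))]
                cur = sigma[node]
                cand = {sigma[u] for u in caches.adj[node]}
                if use_orth:
                    cand.update(sigma[p] for p, _ in caches.orth.get(node, ()))
                cand.discard(cur)
                merging = cand and rng.random() < 0.15
                if merging:
                    # collective move: merge this node's whole module into an
                    # interacting neighbour's module
                    options = sorted(cand)
                    target = options[int(rng.integers(len(options)))]
                    dH = _delta_H_merge(x, sigma, cur, target, params.kappa, caches)
                    if dH <= 0 or rng.random() < math.exp(-dH / T):
                        _apply_merge(x, sigma, cur, target, caches)
                        H += dH
                else:
                    options = sorted(cand)
                    options.append(-1)  # fresh-label sentinel
                    choice = options[int(rng.integers(len(options)))]
                    new_label = next_label if choice == -1 else choice
                    dH = delta_H_single_move(
                        x, sigma, node, new_label, params.kappa, caches
                    )
                    if dH <= 0 or rng.random() < math.exp(-dH / T):
                        _apply_move(x, sigma, node, new_label, caches)
                        if choice == -1:
                            next_label += 1
                        H += dH
                if H < run_best_H - 1e-12:
                    run_best_H = H
                    run_best_sigma = dict(sigma)
            trace.append((T, H))
            T *= params.cooling_alpha

        traces.append({"restart": restart, "trace": trace, "best_H": run_best_H})
        if run_best_H < best_H:
            best_H = run_best_H
            best_sigma = run_best_sigma

    assert best_sigma is not None or not nodes
    if best_sigma is None:
        best_sigma, best_H = {}, 0.0
    return ModuleAssignment(sigma=best_sigma), best_H, traces


def rank_labels(
    sigma: ModuleAssignment, x: CrossSpeciesNetwork
) -> ModuleAssignment:
    """Relabel modules 1..K by decreasing size (ties by smallest member id)."""
    groups = sigma.modules()
    order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    remap = {old: rank for rank, (old, _) in enumerate(order, start=1)}
    return ModuleAssignment(sigma={n: remap[l] for n, l in sigma.sigma.items()})


def _round_pct(count: int, total: int) -> float:
    """Percentage with one decimal, round-half-up (presentation convention)."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_modules(
    sigma: ModuleAssignment, x: CrossSpeciesNetwork
) -> pd.DataFrame:
    """Per-module species composition, sorted by total size descending.

    Returns a DataFrame with columns ``module`` (rank id 1..K), ``total``,
    ``n_species1``, ``n_species2``, ``pct_species1``, ``pct_species2``.
    Percentages are printed to one decimal with round-half-up.
    """
    columns = [
        "module", "total", "n_species1", "n_species2",
        "pct_species1", "pct_species2",
    ]
    if not sigma.sigma:
        return pd.DataFrame(columns=columns)
    rows = []
    for label, members in sigma.modules().items():
        n1 = sum(1 for g in members if g in x.species1_nodes)
        n2 = len(members) - n1
        total = len(members)
        rows.append(
            {
                "total": total,
                "n_species1": n1,
                "n_species2": n2,
                "pct_species1": _round_pct(n1, total),
                "pct_species2": _round_pct(n2, total),
                "_tie": min(members),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["total", "_tie"], ascending=[False, True], kind="mergesort"
    )
    out.insert(0, "module", range(1, len(out) + 1))
    return out.drop(columns="_tie").reset_index(drop=True)


def count_modules(
    sigma: ModuleAssignment, x: CrossSpeciesNetwork, min_size: int = 2
) -> dict:
    """Module counts: all, >= min_size, and cross-species (both species)."""
    groups = sigma.modules()
    n_all = len(groups)
    big = [m for m in groups.values() if len(m) >= min_size]
    cross = sum(
        1
        for m in big
        if any(g in x.species1_nodes for g in m)
        and any(g in x.species2_nodes for g in m)
    )
    return {
        "n_modules_all": n_all,
        "n_modules_ge2": len(big),
        "n_cross_species_modules": cross,
    }


def parameter_sweep(
    rebuild,
    kappas: list[float],
    pcc_cutoffs: list[float],
    base_params: OrthoClustParams | None = None,
) -> pd.DataFrame:
    """Grid of module counts over (kappa, PCC cutoff) combinations.

    ``rebuild(pcc_cutoff)`` must return the :class:`CrossSpeciesNetwork`
    built at that co-expression threshold (the upstream network stage is
    rerun per cutoff). Each grid cell runs the annealer with a seed derived
    deterministically from the base seed and the cell indices. Module counts
    exclude singletons; a cross-species module contains genes of both
    species.
    """
    params = base_params or OrthoClustParams()
    rows = []
    for ci, cutoff in enumerate(pcc_cutoffs):
        x = rebuild(cutoff)
        for ki, kappa in enumerate(kappas):
            cell = OrthoClustParams(
                kappa=kappa,
                seed=params.seed + 1000 * ci + 100_000 * ki,
                n_restarts=params.n_restarts,
                T0=params.T0,
                cooling_alpha=params.cooling_alpha,
                sweeps_per_T=params.sweeps_per_T,
                T_min=params.T_min,
            )
            sigma, H, _ = sa_optimize(x, cell)
            counts = count_modules(sigma, x)
            rows.append(
                {"kappa": kappa, "pcc_cutoff": cutoff, "H": H, **counts}
            )
    return pd.DataFrame(rows)
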