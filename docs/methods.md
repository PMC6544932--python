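# Methods

## The model

`crossexp` treats cross-species module finding as energy minimization on a
two-layer network. Each species contributes an undirected, unweighted
co-expression network (S₁, S₂); orthology contributes weighted inter-layer
links O(S₁, S₂). A labeling σ assigning every gene a module id is scored by

    H(σ) = −( Σ_{i<j∈S₁} Λ¹ᵢⱼ δ(σᵢ,σⱼ)
            + Σ_{i<j∈S₂} Λ²ᵢⱼ δ(σᵢ,σⱼ)
            + κ Σ_{(i,j′)∈O} w_{ij′} δ(σᵢ,σⱼ′) )

* Λᴺᵢⱼ = Aᵢⱼ − kᵢkⱼ/(2m): the difference between the observed adjacency and
  the expected number of edges between i and j under the degree-preserving
  configuration null (the Newman–Girvan form; the verbal definition —
  observed minus expected edges — admits others, and this is the standard
  choice). An empty network scores every pair 0.
* δ is 1 when the two genes share a module label, else 0.
* w is the orthology coupling weight: 1 for one-to-one RBH pairs; for
  k-best mappings, 1/(number of cross-species counterparts of the query
  gene), so the RBH case is the k = 1 specialization. (The weight's
  normalization is only loosely constrained by its verbal definition —
  "from the number of orthologous genes" — so the query-side convention is
  fixed here and documented.)
* κ ≥ 0 sets the price of separating an ortholog pair relative to
  co-expression modularity. At κ = 0 the problem decomposes into two
  independent per-species modularity problems.

**Pair-summation convention.** Species sums run over *unordered* pairs
i < j; each ortholog pair is counted once. Summing ordered pairs would
scale the species terms by 2 and hence halve κ's effective meaning, so the
convention is fixed and all reported κ values refer to it.

Lower H is better. The all-singleton labeling scores exactly 0, so H ≤ 0
is always achievable; assigning orthologous genes the same label lowers H
by κw per pair.

## Optimization

H is minimized by simulated annealing:

* **Initialization:** every node in its own module (H = 0).
* **Moves:** at each step a uniformly random node is selected.
  * With probability 0.85, a *single-node* relabeling: the new label is
    drawn uniformly from the labels of the node's interacting neighbours
    plus one fresh label. Interacting neighbours are the node's
    co-expression neighbours, plus its ortholog partners when κ > 0.
    Because labels can only spread along interactions that carry weight in
    the objective, at κ = 0 no label can cross species: single-species
    modules at κ = 0 are a structural guarantee, not a tendency.
  * With probability 0.15 (when the node has interacting neighbours in
    another module), a *collective merge*: the node's entire module is
    relabeled into a neighbour module. Single-node dynamics alone cannot
    cross the energy barrier between two fully formed modules that the
    coupling term favours joining — every intermediate configuration is
    strongly uphill — which in practice left matching per-species blocks
    unmerged. Mixing individual and collective moves is the standard
    remedy in annealing-based community detection.
* **Acceptance:** Metropolis — accept if ΔH ≤ 0, else with probability
  exp(−ΔH/T).
* **Schedule:** geometric cooling T ← αT from T0 = 1.0 with α = 0.9 down
  to T_min = 1e-4; one sweep (|nodes| proposals) per temperature by
  default (`sweeps_per_T` scales this).
* **ΔH evaluation:** both move types are scored incrementally in O(degree)
  using per-module degree sums (the k-sum identity
  Σ_{i<j∈L} kᵢkⱼ = (K_L² − Σk²)/2); tests verify agreement with full
  recomputation to 1e-9.
* **Restarts and determinism:** `n_restarts` independent runs seeded
  `seed + restart_index`; the best (lowest-H) state *visited* in any run is
  returned — this also guarantees the result never scores worse than the
  singleton baseline. All randomness flows from one integer seed.

Genes named only in the ortholog list (absent from both networks) are kept
as isolated nodes: their Λ terms are zero but coupling can still pull them
into modules — with κ > 0 an isolated ortholog pair forms its own 2-gene
module, which is exactly why switching the coupling on multiplies the
module count on real RBH lists.

Modules are presented ranked 1..K by size (ties broken by smallest member
id); composition percentages are printed to one decimal with round-half-up.
Sweep module counts exclude singletons; both counts are available.

## Upstream stages

**Orthology.** Alignment is assumed to have been run at the isoform level
against a merged two-species protein database, so the raw table contains
self and within-species hits; these are discarded. Hits with E-value
≥ 1e-5 are removed (strict `<`). Isoform ids collapse to gene ids by
stripping a trailing `.digits` suffix (configurable; the default is
idempotent and safe for dot-containing gene ids like `Glyma.01G006400`).
Best hits are ranked by minimum E-value, ties by maximum bitscore, then by
smallest subject gene id — a deterministic total order chosen because
upstream tools leave tie-breaking unspecified. RBH keeps pair (a, b) iff a
is b's best hit and vice versa. Identifiers matching neither species
pattern raise an error listing the offending ids rather than being dropped.

**Expression.** FPKM[g,s] = 1e9·count/(length·total_counts[s]). The
library size is the plain per-sample column total — a deliberately simple
normalizer; robust median-of-ratios size factors change FPKM by a
per-sample constant and leave Pearson correlations over conditions nearly
unchanged, which is all the downstream pipeline consumes. Replicates are
averaged arithmetically per condition (condition order = first appearance
in the design table). Gene filtering keeps genes with max FPKM ≥ 0.5
(inclusive) AND cross-condition sample variance > 0.5 (strict, n−1
denominator), optionally intersected with a curated gene list first; each
criterion can be disabled independently. The combination rule is AND
because the filters serve different failure modes (unexpressed vs flat),
but the published protocol phrases them disjunctively, so both switches
are exposed.

**Networks.** Correlations are computed on replicate-averaged condition
profiles (matching the pipeline order), never on per-replicate samples.
p-values use the exact transform t = r√(n−2)/√(1−r²) with n−2 degrees of
freedom, two-sided; |r| = 1 maps to p = 0 as the limit. Both cutoffs are
strict. Nodes without a surviving edge are excluded from the network node
set (they cannot affect modularity), while the candidate-pair count
C(n_genes, 2) is retained for provenance — at the published scale of 1,092
genes this is 595,686 screened pairs.

## The synthetic benchmark

The generator emulates two species' developmental time courses: 4 planted
blocks × 25 genes per species over 7 and 10 conditions (the two species'
time-course lengths), plus 20 independent background genes per species.

* **Templates:** each block's shared profile is a smooth low-order curve —
  logistic rise, logistic decay, or a Gaussian bump over the time axis —
  with random midpoint/width, a baseline of 5–15 and amplitude of 30–80 on
  an FPKM-like scale. Template draws that correlate above 0.9 with an
  earlier block's template are rejected (up to 50 redraws), because
  planted blocks must be distinguishable at the edge cutoff; smooth
  monotone curves otherwise correlate near 1 on short grids.
* **Noise calibration:** each block gene is template + iid Gaussian noise
  with sd = s·√(1/ρ − 1) (s = template sd), so the expected within-block
  correlation is the target ρ (default 0.995, chosen so planted edges
  survive the r > 0.99 cutoff; ρ = 1 gives exactly-correlated genes).
  Values are clipped at 0; baselines keep clipping negligible.
* **Orthologs:** the i-th gene of block b in species 1 pairs with the i-th
  gene of block b in species 2, each pair kept with probability 0.8
  (real RBH maps are incomplete). Background genes are paired the same
  way: real ortholog lists are dominated by genes outside the analyzed
  networks, and these network-absent pairs are what drives the module
  count up when κ > 0 — a synthetic map without them could not reproduce
  that direction.
* **Alignment table:** every true pair is emitted as a mutually best
  isoform-level hit in both directions (E-value exponents −180…−100);
  decoys (self, within-species, and cross-species rows) are strictly worse
  (−30…−7) and cross-species decoys always target an already-paired gene,
  so the RBH of the table is the planted map by construction — with
  decoys exercising, not threatening, the selection logic.

**What passing these benchmarks does not show:** the generator produces
clean block structure, Gaussian noise, and orthology uncorrelated with
expression divergence. Real embryo time courses have overlapping modules,
heteroscedastic counts, and partially diverged ortholog expression, so
recovery rates here (ARI ≈ 1) are an upper bound on real-data behaviour,
and published real-data counts (filter survivors, edge counts, 353 modules
from one trial) are treated as qualitative context, not reproduction
targets — they depend on downloaded data and an unspecified annealing
schedule.

## Problem sizes and numerical choices

Acceptance-style checks run at sizes chosen to make the properties sharp
yet quick: 20 random toy instances (8–16 nodes) for the brute-force
objective comparison (tolerance 1e-9), 1,000 random moves for the
incremental-delta comparison (1e-9), exhaustive set-partition enumeration
up to 8 nodes (Bell(8) = 4,140 partitions) against 20-restart annealing,
10 seeds for planted recovery and for the κ sweep, and ~500-gene alignment
tables for the RBH oracle. Ties in best-hit selection, module ranking, and
edge canonicalization are all broken lexicographically so every output is
byte-stable under a fixed seed.

## Known limitations

* Exactly two species; many-species coupling is out of scope.
* Hard (non-overlapping) module membership; no significance test on
  modules.
* Unweighted networks: correlation strength beyond the cutoff is ignored.
* The annealing schedule is heuristic; on large instances the returned
  labeling is a good local optimum, not a certified global one (restarts
  mitigate, the small-instance enumeration quantifies).
* FPKM uses total-count library sizes; between-sample normalization beyond
  that (and differential-expression analysis generally) is intentionally
  not implemented.
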