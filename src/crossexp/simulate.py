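"""Seeded synthetic fixtures for the whole cross-species pipeline.

Emulates two species' embryo-development-style time courses (7 and 10
conditions by default) with planted co-expressed gene blocks, a one-to-one
ortholog map linking corresponding blocks (and a matching fraction of
background genes) across species, and a 12-column alignment table from
which the same ortholog map is recoverable by the reciprocal-best-hit
procedure. Everything is bit-reproducible given the design seed.

Block expression profiles follow smooth low-order time-course templates
(logistic rise, logistic decay, or a Gaussian bump over the time axis) on
an FPKM-like scale; each block gene is the shared template plus independent
Gaussian noise whose scale is set so the expected within-block Pearson
correlation matches ``correlation_target`` (noise sd = template sd *
sqrt(1/rho - 1)). Background genes are condition-independent noise around a
gene-specific baseline. Values are clipped at zero; template baselines keep
clipping negligible at realistic targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .homology import OrthologPairSet

__all__ = [
    "PlantedDesign",
    "simulate_expression",
    "simulate_orthologs",
    "simulate_alignment_table",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Study conditions of the planted-block benchmark.

    Defaults: 4 blocks of 25 genes per species observed over 7 (species 1)
    and 10 (species 2) time points, within-block correlation target 0.995
    (so planted edges survive a PCC > 0.99 cutoff), 20 independent
    background genes per species, and 80% of corresponding genes linked
    one-to-one across species.
    """

    n_blocks: int = 4
    genes_per_block: int = 25
    n_conditions: tuple[int, int] = (7, 10)
    correlation_target: float = 0.995
    noise_sd: float = 5.0          # background-gene condition-to-condition sd (FPKM)
    fraction_orthologous: float = 0.8
    background_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.genes_per_block < 1:
            raise ValueError("block counts must be positive")
        if not 0.0 < self.correlation_target <= 1.0:
            raise ValueError("correlation_target must be in (0, 1]")
        if not 0.0 <= self.fraction_orthologous <= 1.0:
            raise ValueError("fraction_orthologous must be in [0, 1]")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")
        if min(self.n_conditions) < 3:
            raise ValueError("need >= 3 conditions per species")


def _gene_ids(species: int, n: int) -> list[str]:
    if species == 1:
        return [f"AT1G{(i + 1) * 10:05d}" for i in range(n)]
    return [f"Glyma.{1 + i // 100:02d}G{((i % 100) + 1) * 100:06d}" for i in range(n)]


def _template(kind: int, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth unit-scale time-course shape on t in [0, 1]."""
    mid = rng.uniform(0.25, 0.75)
    width = rng.uniform(0.08, 0.2)
    if kind == 0:    # logistic rise
        return 1.0 / (1.0 + np.exp(-(t - mid) / width))
    if kind == 1:    # logistic decay
        return 1.0 / (1.0 + np.exp((t - mid) / width))
    return np.exp(-((t - mid) ** 2) / (2.0 * width**2))  # transient bump


def simulate_expression(
    d: PlantedDesign, species: int
) -> tuple[ExpressionMatrix, pd.Series]:
    """Planted-block FPKM matrix for one species plus true block labels.

    Block labels are 1..n_blocks; background genes carry label 0. Blocks
    with the same label in the two species share the block index (their
    templates differ per species, as real orthologs sample different time
    grids), which is what the ortholog map links.
    """
    if species not in (1, 2):
        raise ValueError("species must be 1 or 2")
    rng = np.random.default_rng([d.seed, species])
    n_cond = d.n_conditions[species - 1]
    t = np.linspace(0.0, 1.0, n_cond)

    rows: list[np.ndarray] = []
    labels: list[int] = []
    shapes: list[np.ndarray] = []
    for b in range(d.n_blocks):
        amplitude = rng.uniform(30.0, 80.0)
        base = rng.uniform(5.0, 15.0)
        # distinct blocks must be distinguishable at the edge cutoff: reject
        # template draws that correlate too highly with an earlier block
        best_shape, best_worst = None, np.inf
        for attempt in range(50):
            shape = _template((b + attempt) % 3, t, rng)
            worst = max(
                (abs(np.corrcoef(shape, prev)[0, 1]) for prev in shapes),
                default=0.0,
            )
            if worst < best_worst:
                best_shape, best_worst = shape, worst
            if worst < 0.9:
                break
        shapes.append(best_shape)
        curve = base + amplitude * best_shape
        s = float(curve.std())
        if d.correlation_target >= 1.0:
            sd = 0.0
        else:
            sd = s * np.sqrt(1.0 / d.correlation_target - 1.0)
        for _ in range(d.genes_per_block):
            rows.append(curve + rng.normal(0.0, sd, n_cond))
            labels.append(b + 1)
    for _ in range(d.background_genes):
        baseline = rng.uniform(5.0, 50.0)
        rows.append(baseline + rng.normal(0.0, max(d.noise_sd, 1e-6), n_cond))
        labels.append(0)

    values = np.clip(np.asarray(rows), 0.0, None)
    genes = _gene_ids(species, len(rows))
    cols = [f"c{j + 1}" for j in range(n_cond)]
    em = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols),
        unit="fpkm",
        column_kind="conditions",
    )
    return em, pd.Series(labels, index=genes, name="block")


def simulate_orthologs(
    d: PlantedDesign, labels1: pd.Series, labels2: pd.Series
) -> OrthologPairSet:
    """One-to-one ortholog map linking corresponding genes across species.

    The i-th gene of block b in species 1 pairs with the i-th gene of block
    b in species 2, each pair kept independently with probability
    ``fraction_orthologous``; background genes (label 0) are paired the same
    way, positionally, so the map also contains genes that carry no
    co-expression signal — as real RBH lists do. All weights are 1 (RBH
    mode).
    """
    rng = np.random.default_rng([d.seed, 17])
    pairs: set[tuple[str, str]] = set()
    for b in sorted(set(labels1.unique()) & set(labels2.unique())):
        g1 = list(labels1.index[labels1 == b])
        g2 = list(labels2.index[labels2 == b])
        for a, o in zip(g1, g2):
            if rng.random() < d.fraction_orthologous:
                pairs.add((a, o))
    return OrthologPairSet(
        pairs=pairs, weights={p: 1.0 for p in pairs}, mode="rbh", direction=("a", "b")
    )


def simulate_alignment_table(
    pairs: OrthologPairSet, decoys: int = 0, seed: int = 0
) -> str:
    """12-column alignment text whose RBH result is exactly ``pairs``.

    Each true pair is emitted as a mutually best isoform-level hit in both
    directions (E-value exponents in [-180, -100]); decoy rows are strictly
    worse (exponents in [-30, -7]) and consist of self hits, within-species
    hits, and cross-species hits that always target a gene which already has
    a better true partner, so no decoy can ever be reciprocal-best.
    """
    if decoys < 0:
        raise ValueError("decoys must be >= 0")
    rng = np.random.default_rng([seed, 99])
    lines: list[str] = []

    def row(q: str, s: str, evalue: float, bitscore: float) -> str:
        pident = rng.uniform(40.0, 99.0)
        length = int(rng.integers(80, 600))
        mism = int(rng.integers(0, max(2, length // 4)))
        gaps = int(rng.integers(0, 10))
        return "\t".join(
            [
                q, s, f"{pident:.2f}", str(length), str(mism), str(gaps),
                "1", str(length), "1", str(length),
                f"{evalue:.3e}", f"{bitscore:.1f}",
            ]
        )

    ordered = pairs.sorted_pairs()
    for a, b in ordered:
        ev = 10.0 ** rng.uniform(-180.0, -100.0)
        bits = rng.uniform(500.0, 900.0)
        lines.append(row(f"{a}.1", f"{b}.1", ev, bits))
        lines.append(row(f"{b}.1", f"{a}.1", ev * rng.uniform(0.5, 2.0), bits - 1.0))

    if decoys and ordered:
        genes_a = sorted({a for a, _ in ordered})
        genes_b = sorted({b for _, b in ordered})
        partner = dict(ordered)
        partner.update({b: a for a, b in ordered})
        everything = genes_a + genes_b
        for _ in range(decoys):
            kind = int(rng.integers(3))
            q = everything[int(rng.integers(len(everything)))]
            ev = 10.0 ** rng.uniform(-30.0, -7.0)
            bits = rng.uniform(50.0, 300.0)
            if kind == 0:      # self hit
                s = q
            elif kind == 1:    # within-species decoy
                pool = genes_a if q in genes_a else genes_b
                s = pool[int(rng.integers(len(pool)))]
            else:              # cross-species decoy onto an already-paired gene
                pool = genes_b if q in genes_a else genes_a
                s = pool[int(rng.integers(len(pool)))]
                if s == partner.get(q):
                    s = pool[(pool.index(s) + 1) % len(pool)]
            iso_q = f"{q}.{int(rng.integers(1, 3))}"
            iso_s = f"{s}.1"
            lines.append(row(iso_q, iso_s, ev, bits))

    return "\n".join(lines) + ("\n" if lines else "")


def simulate_dataset(d: PlantedDesign, out_dir: str | Path | None = None) -> dict:
    """Generate the full fixture bundle; optionally write it to ``out_dir``.

    Returns a dict with keys ``fpkm1``, ``fpkm2`` (ExpressionMatrix),
    ``labels1``, ``labels2`` (Series), ``orthologs`` (OrthologPairSet) and
    ``blast`` (alignment-table text). Files written: fpkm_species1.tsv,
    fpkm_species2.tsv, orthologs.tsv, blast.tsv, truth_labels.tsv.
    """
    fpkm1, labels1 = simulate_expression(d, 1)
    fpkm2, labels2 = simulate_expression(d, 2)
    orthologs = simulate_orthologs(d, labels1, labels2)
    blast = simulate_alignment_table(
        orthologs, decoys=4 * len(orthologs.pairs), seed=d.seed
    )
    out = {
        "fpkm1": fpkm1,
        "fpkm2": fpkm2,
        "labels1": labels1,
        "labels2": labels2,
        "orthologs": orthologs,
        "blast": blast,
    }
    if out_dir is not None:
        from . import io as cio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cio.write_fpkm_matrix(fpkm1, out_dir / "fpkm_species1.tsv")
        cio.write_fpkm_matrix(fpkm2, out_dir / "fpkm_species2.tsv")
        cio.write_ortholog_pairs(orthologs, out_dir / "orthologs.tsv")
        (out_dir / "blast.tsv").write_text(blast)
        truth = pd.concat(
            [
                pd.DataFrame({"gene": labels1.index, "species": 1, "block": labels1.values}),
                pd.DataFrame({"gene": labels2.index, "species": 2, "block": labels2.values}),
            ]
        )
        truth.to_csv(out_dir / "truth_labels.tsv", sep="\t", index=False)
    return out
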