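"""Shared fixtures: random toy instances and alignment-table builders."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from crossexp.homology import BLAST_COLUMNS, OrthologPairSet, SpeciesIdScheme
from crossexp.network import from_edges
from crossexp.orthoclust import CrossSpeciesNetwork


def make_cross_instance(
    rng: np.random.Generator,
    n1: int = 6,
    n2: int = 6,
    p_edge: float = 0.35,
    n_orth: int = 4,
    weighted: bool = False,
) -> CrossSpeciesNetwork:
    """Random two-species instance with Erdos-Renyi co-expression layers."""
    g1 = [f"A{i}" for i in range(n1)]
    g2 = [f"B{i}" for i in range(n2)]
    e1 = {(u, v) for u, v in itertools.combinations(g1, 2) if rng.random() < p_edge}
    e2 = {(u, v) for u, v in itertools.combinations(g2, 2) if rng.random() < p_edge}
    candidates = list(itertools.product(g1, g2))
    idx = rng.choice(len(candidates), size=min(n_orth, len(candidates)), replace=False)
    pairs = {candidates[i] for i in idx}
    weights = {
        p: (float(rng.uniform(0.3, 1.0)) if weighted else 1.0) for p in pairs
    }
    orth = OrthologPairSet(pairs=pairs, weights=weights, mode="kbest" if weighted else "rbh")
    return CrossSpeciesNetwork(
        net1=from_edges(e1, species_tag="s1", extra_nodes=g1),
        net2=from_edges(e2, species_tag="s2", extra_nodes=g2),
        orthologs=orth,
    )


def random_sigma(rng: np.random.Generator, x: CrossSpeciesNetwork, n_labels: int = 4):
    return {node: int(rng.integers(n_labels)) for node in x.universe}


@pytest.fixture
def cross_instance_factory():
    return make_cross_instance


def hits_frame(rows: list[tuple]) -> pd.DataFrame:
    """Build an alignment-hit table from (q, s, evalue, bitscore) tuples."""
    records = [
        {
            "qseqid": q,
            "sseqid": s,
            "pident": 90.0,
            "length": 100,
            "mismatch": 5,
            "gapopen": 1,
            "qstart": 1,
            "qend": 100,
            "sstart": 1,
            "send": 100,
            "evalue": ev,
            "bitscore": bits,
        }
        for q, s, ev, bits in rows
    ]
    return pd.DataFrame(records, columns=BLAST_COLUMNS)


def random_hits(
    rng: np.random.Generator, n_a: int = 30, n_b: int = 30, n_rows: int = 300
) -> pd.DataFrame:
    """Random isoform-level cross- and within-species hits (A*/B* ids)."""
    rows = []
    for _ in range(n_rows):
        qa = rng.random() < 0.5
        q = f"A{int(rng.integers(n_a))}.{int(rng.integers(1, 4))}" if qa else \
            f"B{int(rng.integers(n_b))}.{int(rng.integers(1, 4))}"
        sa = rng.random() < 0.5
        s = f"A{int(rng.integers(n_a))}.{int(rng.integers(1, 4))}" if sa else \
            f"B{int(rng.integers(n_b))}.{int(rng.integers(1, 4))}"
        rows.append((q, s, 10.0 ** rng.uniform(-50, -3), float(rng.uniform(50, 500))))
    return hits_frame(rows)


@pytest.fixture
def ab_scheme() -> SpeciesIdScheme:
    return SpeciesIdScheme(species_a_pattern="A*", species_b_pattern="B*")
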