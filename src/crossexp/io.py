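"""Readers and writers for the pipeline's tabular interchange formats.

All writers are deterministic (stable row ordering) so outputs diff cleanly
across runs with the same seed. Readers perform strict column-count checks
and report malformed lines by number.

Formats
-------
- alignment table: 12-column TSV (tabular aligner output, "-outfmt 6")
- edge list: two-column TSV, one undirected edge per row, no header
- ortholog pairs: two-column TSV (gene_species1, gene_species2), optional
  third column with the coupling weight w
- FPKM matrix: TSV, header row of condition/sample ids, first column gene id
- count matrix: TSV like the FPKM matrix plus an optional ``length_bp``
  column right after the gene id
- design table: CSV with header (sample, condition, replicate)
- module assignment: CSV with header (gene, species, module)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import ExpressionMatrix, SampleDesign
from .homology import OrthologPairSet, parse_alignment_table  # noqa: F401 (re-export)
from .network import CoexpressionNetwork, from_edges
from .orthoclust import CrossSpeciesNetwork, ModuleAssignment

__all__ = [
    "parse_alignment_table",
    "read_edge_list",
    "write_edge_list",
    "read_ortholog_pairs",
    "write_ortholog_pairs",
    "read_fpkm_matrix",
    "write_fpkm_matrix",
    "read_counts_matrix",
    "read_design_table",
    "read_module_assignment",
    "write_module_assignment",
    "write_module_summary",
]


def _rows(path: str | Path, n_cols: tuple[int, ...], sep: str = "\t"):
    """Yield (lineno, fields) from a delimited file, enforcing column counts."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) not in n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {' or '.join(map(str, n_cols))}"
                    f" column(s), got {len(fields)}"
                )
            yield lineno, fields


def read_edge_list(path: str | Path, species_tag: str = "") -> CoexpressionNetwork:
    """Read a two-column TSV edge list into a co-expression network."""
    edges = set()
    for lineno, (u, v) in ((ln, f) for ln, f in _rows(path, (2,))):
        if u == v:
            raise ValueError(f"{path}: line {lineno}: self-edge on {u!r}")
        edges.add((u, v) if u < v else (v, u))
    return from_edges(edges, species_tag=species_tag)


def write_edge_list(net: CoexpressionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_ortholog_pairs(path: str | Path) -> OrthologPairSet:
    """Read a two- or three-column TSV ortholog-pair file."""
    pairs: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    weighted = False
    for lineno, fields in _rows(path, (2, 3)):
        a, b = fields[0], fields[1]
        pair = (a, b)
        pairs.add(pair)
        if len(fields) == 3:
            weighted = True
            try:
                weights[pair] = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: unparseable weight {fields[2]!r}"
                ) from None
        else:
            weights[pair] = 1.0
    return OrthologPairSet(
        pairs=pairs,
        weights=weights,
        mode="kbest" if weighted else "rbh",
        direction=("a", "b"),
    )


def write_ortholog_pairs(ops: OrthologPairSet, path: str | Path) -> None:
    """Two columns for unit weights; a third ``w`` column otherwise."""
    weighted = any(abs(w - 1.0) > 1e-12 for w in ops.weights.values())
    with open(path, "w") as fh:
        for a, b in ops.sorted_pairs():
            if weighted:
                fh.write(f"{a}\t{b}\t{ops.weights.get((a, b), 1.0):g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_fpkm_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None and df.empty:
        raise ValueError(f"{path}: empty FPKM matrix")
    return ExpressionMatrix(values=df, unit="fpkm", column_kind="conditions")


def write_fpkm_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_counts_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a count matrix; a ``length_bp`` (or ``length``) column is used
    as the per-gene feature length."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    for col in ("length_bp", "length"):
        if col in df.columns:
            lengths = df[col].astype(int)
            df = df.drop(columns=[col])
            break
    return ExpressionMatrix(
        values=df, unit="counts", column_kind="samples", lengths=lengths
    )


def read_design_table(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return SampleDesign(table=df)


def read_module_assignment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"gene", "species", "module"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: assignment file missing columns {sorted(missing)}")
    return df


def write_module_assignment(
    sigma: ModuleAssignment, x: CrossSpeciesNetwork, path: str | Path
) -> None:
    """CSV with header (gene, species, module), sorted by module then gene."""
    rows = [
        {"gene": g, "species": x.species_of(g), "module": label}
        for g, label in sigma.sigma.items()
    ]
    df = pd.DataFrame(rows).sort_values(["module", "gene"], kind="mergesort")
    df.to_csv(path, index=False)


def write_module_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)
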