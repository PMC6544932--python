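"""Expression quantification: counts -> FPKM, replicate averaging, filtering.

FPKM (fragments per kilobase of feature per million mapped fragments) is
computed from a raw fragment-count matrix and per-gene feature lengths:

    FPKM[g, s] = 1e9 * count[g, s] / (length_bp[g] * total_counts[s])

The library size is the plain per-sample total of counted fragments; this is
a deliberately simple normalizer (robust median-of-ratios size factors are a
drop-in alternative outside the scope of this package). Replicates are
averaged per condition before correlation, and genes are filtered on
expression level and cross-condition variance before network construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "compute_fpkm",
    "average_replicates",
    "filter_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes x columns expression values with unit and column-kind metadata.

    ``values`` is a DataFrame indexed by unique gene id. ``unit`` is
    ``"counts"`` or ``"fpkm"``; ``column_kind`` is ``"samples"`` (replicate
    columns) or ``"conditions"`` (replicate-averaged). When unit is counts,
    ``lengths`` must give every gene's feature length in bp.
    """

    values: pd.DataFrame
    unit: str = "fpkm"
    column_kind: str = "samples"
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "fpkm"):
            raise ValueError(f"unit must be 'counts' or 'fpkm', got {self.unit!r}")
        if self.column_kind not in ("samples", "conditions"):
            raise ValueError(f"column_kind must be 'samples' or 'conditions'")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit == "counts":
            if self.lengths is None:
                raise ValueError("counts matrices require per-gene lengths")
            missing = self.values.index.difference(self.lengths.index)
            if len(missing):
                raise ValueError(f"genes missing a length: {list(missing[:5])}")
            if (self.lengths.loc[self.values.index] <= 0).any():
                bad = self.lengths.loc[self.values.index]
                bad = bad[bad <= 0].index[0]
                raise ValueError(f"gene {bad!r} has non-positive length")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def columns(self) -> pd.Index:
        return self.values.columns


@dataclass
class SampleDesign:
    """Replicate structure: sample id -> (condition, replicate index)."""

    table: pd.DataFrame  # columns: sample, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"sample {dup!r} listed more than once in design")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(self.table["condition"].drop_duplicates())

    def samples_of(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample"])


def compute_fpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a fragment-count matrix to FPKM.

    FPKM[g, s] = 1e9 * count[g, s] / (length_bp[g] * total_counts[s]).
    Column totals must be positive and every gene must have a length.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    lengths = counts.lengths.loc[counts.values.index].to_numpy(dtype=float)
    fpkm = (
        1e9
        * counts.values.to_numpy(dtype=float)
        / lengths[:, None]
        / totals.to_numpy(dtype=float)[None, :]
    )
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        unit="fpkm",
        column_kind=counts.column_kind,
    )


def average_replicates(m: ExpressionMatrix, design: SampleDesign) -> ExpressionMatrix:
    """Average replicate columns per condition (arithmetic mean).

    Every matrix column must appear in the design; condition order in the
    output follows first appearance in the design table. Design rows for
    samples absent from the matrix are ignored.
    """
    known = set(design.samples)
    missing = [s for s in m.values.columns if s not in known]
    if missing:
        raise ValueError(f"samples missing from design: {missing[:5]}")
    out = {}
    for cond in design.conditions:
        cols = [s for s in design.samples_of(cond) if s in m.values.columns]
        if cols:
            out[cond] = m.values[cols].mean(axis=1)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index),
        unit=m.unit,
        column_kind="conditions",
        lengths=m.lengths,
    )


def filter_genes(
    m: ExpressionMatrix,
    min_fpkm: float | None = 0.5,
    min_variance: float | None = 0.5,
    gene_list: set | None = None,
) -> ExpressionMatrix:
    """Filter genes by expression level, variance, and/or a curated list.

    Keeps genes that (i) appear in ``gene_list`` if one is given, (ii) reach
    ``min_fpkm`` in at least one condition (>=, inclusive), and (iii) vary
    across conditions with sample variance (n-1 denominator) strictly above
    ``min_variance``. Any criterion can be disabled by passing ``None``.
    Gene order is preserved; an empty result warns rather than errors.
    """
    if m.unit != "fpkm":
        raise ValueError(f"filter_genes expects FPKM values, got unit {m.unit!r}")
    mask = pd.Series(True, index=m.values.index)
    if gene_list is not None:
        mask &= m.values.index.isin(set(gene_list))
    if min_fpkm is not None:
        mask &= m.values.max(axis=1) >= min_fpkm
    if min_variance is not None:
        mask &= m.values.var(axis=1, ddof=1) > min_variance
    if not mask.any():
        warnings.warn("filter_genes removed every gene", stacklevel=2)
    return ExpressionMatrix(
        values=m.values.loc[mask],
        unit=m.unit,
        column_kind=m.column_kind,
        lengths=m.lengths,
    )
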