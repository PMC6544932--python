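"""Per-module network exports and expression-profile plots.

Module subnetworks are exported as three two-column edge tables (one per
species plus the ortholog pairs restricted to the module) loadable as
source/target edge lists by any network visualization tool. Expression
profiles plot one panel per species with condition index on x; per-gene
z-score standardization is the default because the two species' FPKM
scales differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .expression import ExpressionMatrix
from .orthoclust import CrossSpeciesNetwork, ModuleAssignment

__all__ = ["ModuleExportBundle", "export_module_networks", "plot_module_profiles"]


@dataclass
class ModuleExportBundle:
    """File paths and contents of one module's exported subnetworks."""

    module_id: int
    edges1: list[tuple[str, str]]
    edges2: list[tuple[str, str]]
    ortholog_pairs: list[tuple[str, str]]
    paths: dict[str, Path]


def _module_members(sigma: ModuleAssignment, module_id: int) -> set[str]:
    members = {g for g, label in sigma.sigma.items() if label == module_id}
    if not members:
        raise ValueError(f"unknown module id {module_id}")
    return members


def export_module_networks(
    sigma: ModuleAssignment,
    x: CrossSpeciesNetwork,
    module_id: int,
    out_dir: str | Path,
) -> ModuleExportBundle:
    """Write one module's two species edge lists and ortholog pairs.

    Each file is a two-column TSV restricted to edges/pairs whose both
    endpoints belong to the module. Files:
    ``module<K>_species1_edges.tsv``, ``module<K>_species2_edges.tsv``,
    ``module<K>_orthologs.tsv``.
    """
    members = _module_members(sigma, module_id)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def restrict(pairs) -> list[tuple[str, str]]:
        return sorted((u, v) for u, v in pairs if u in members and v in members)

    edges1 = restrict(x.net1.edges)
    edges2 = restrict(x.net2.edges)
    opairs = restrict(x.orthologs.pairs)

    paths = {}
    for name, rows in (
        (f"module{module_id}_species1_edges.tsv", edges1),
        (f"module{module_id}_species2_edges.tsv", edges2),
        (f"module{module_id}_orthologs.tsv", opairs),
    ):
        path = out_dir / name
        with open(path, "w") as fh:
            for u, v in rows:
                fh.write(f"{u}\t{v}\n")
        paths[name] = path
    return ModuleExportBundle(
        module_id=module_id,
        edges1=edges1,
        edges2=edges2,
        ortholog_pairs=opairs,
        paths=paths,
    )


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1).replace(0.0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def plot_module_profiles(
    fpkm1: ExpressionMatrix,
    fpkm2: ExpressionMatrix,
    sigma: ModuleAssignment,
    module_id: int,
    highlight: list[str] | None = None,
    out: str | Path | None = None,
    standardize: bool = True,
) -> dict:
    """Plot each species' expression profiles for one module.

    One panel per species; x is the condition index, y the (optionally
    per-gene z-scored) expression. Highlighted genes are drawn in color on
    top of the module's grey profiles; a highlighted gene outside the
    module is still drawn (with a warning) if it is present in a matrix.

    Returns the plotted value arrays, keyed ``species1`` / ``species2``
    (DataFrames of plotted rows), for testability; writes ``out`` if given.
    """
    highlight = list(highlight or [])
    members = _module_members(sigma, module_id)
    panels: dict[str, pd.DataFrame] = {}
    for key, m in (("species1", fpkm1), ("species2", fpkm2)):
        genes = [g for g in m.values.index if g in members]
        extra = [g for g in highlight if g in m.values.index and g not in members]
        if extra:
            warnings.warn(
                f"highlight gene(s) not in module {module_id}: {extra}; "
                "drawn from the full matrix",
                stacklevel=2,
            )
        rows = m.values.loc[genes + extra]
        panels[key] = _zscore(rows) if standardize else rows.copy()
    if all(df.empty for df in panels.values()):
        raise ValueError(f"module {module_id} has no genes in either matrix")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=standardize)
    for ax, (key, df) in zip(axes, panels.items()):
        xvals = np.arange(1, df.shape[1] + 1)
        for gene, row in df.iterrows():
            if gene in highlight:
                ax.plot(xvals, row.to_numpy(), lw=2.0, label=gene, zorder=3)
            else:
                ax.plot(xvals, row.to_numpy(), color="0.6", lw=0.8, alpha=0.7)
        ax.set_title(f"{key} (module {module_id}, {df.shape[0]} genes)")
        ax.set_xlabel("condition")
        ax.set_ylabel("z-scored FPKM" if standardize else "FPKM")
        if any(g in highlight for g in df.index):
            ax.legend(fontsize=7)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
    plt.close(fig)
    return panels
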