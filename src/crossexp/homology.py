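"""Orthology inference from tabular protein-alignment output.

Implements the reciprocal-best-hit (RBH) and k-best-hit procedures used to
link genes between two species before cross-species co-expression analysis.
Alignments are produced at the isoform (protein) level against a merged
two-species database, so the raw table contains within-species and self
hits; these are discarded, isoform identifiers are collapsed to gene
identifiers, and best hits are selected per gene with a deterministic
ranking (minimum E-value, then maximum bitscore, then lexicographically
smallest subject gene).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "BLAST_COLUMNS",
    "AlignmentParseError",
    "UnknownSpeciesError",
    "SpeciesIdScheme",
    "BestHit",
    "BestHitTable",
    "OrthologPairSet",
    "parse_alignment_table",
    "filter_by_evalue",
    "collapse_and_best_hit",
    "reciprocal_best_hits",
    "k_best_hits",
]

#: Column names of the standard 12-column tabular alignment output
#: ("-outfmt 6"): query id, subject id, percent identity, alignment length,
#: mismatches, gap opens, query/subject start/end, E-value, bitscore.
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_INT_COLUMNS = ["length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"]
_FLOAT_COLUMNS = ["pident", "evalue", "bitscore"]


class AlignmentParseError(ValueError):
    """Raised for malformed alignment-table lines; names the line number."""


class UnknownSpeciesError(ValueError):
    """Raised when a sequence identifier matches no species pattern."""


def parse_alignment_table(source: str | Path | Iterable[str]) -> pd.DataFrame:
    """Parse 12-column tabular alignment output into a DataFrame.

    Parameters
    ----------
    source
        Path to a file, or an iterable of lines (an open file object works).

    Returns
    -------
    pandas.DataFrame with columns :data:`BLAST_COLUMNS`, one row per hit.
    Empty lines are skipped; self-hits and within-species hits are retained
    (they are filtered later by :func:`collapse_and_best_hit`).

    Raises
    ------
    AlignmentParseError
        If a line has fewer than 12 tab-separated fields, a numeric field
        does not parse, or a value violates a basic invariant (E-value < 0,
        alignment length < 1, coordinate < 1). The message names the line.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_alignment_table(fh)

    records: list[list] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise AlignmentParseError(
                f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
            )
        rec: list = [fields[0], fields[1]]
        try:
            rec.append(float(fields[2]))            # pident
            rec.extend(int(f) for f in fields[3:10])  # length..send
            rec.append(float(fields[10]))           # evalue
            rec.append(float(fields[11]))           # bitscore
        except ValueError as exc:
            raise AlignmentParseError(f"line {lineno}: unparseable number ({exc})") from None
        row = dict(zip(BLAST_COLUMNS, rec))
        if row["evalue"] < 0:
            raise AlignmentParseError(f"line {lineno}: negative E-value {row['evalue']}")
        if row["length"] < 1:
            raise AlignmentParseError(f"line {lineno}: alignment length {row['length']} < 1")
        if min(row["qstart"], row["qend"], row["sstart"], row["send"]) < 1:
            raise AlignmentParseError(f"line {lineno}: coordinates must be >= 1")
        records.append(rec)

    return pd.DataFrame(records, columns=BLAST_COLUMNS).astype(
        {c: int for c in _INT_COLUMNS} | {c: float for c in _FLOAT_COLUMNS}
    )


def filter_by_evalue(hits: pd.DataFrame, threshold: float = 1e-5) -> pd.DataFrame:
    """Keep hits with E-value strictly below ``threshold`` (default 1e-5)."""
    if threshold <= 0:
        raise ValueError(f"E-value threshold must be > 0, got {threshold}")
    return hits.loc[hits["evalue"] < threshold].reset_index(drop=True)


def _default_collapse(identifier: str) -> str:
    # Strip a trailing dot-delimited *numeric* isoform suffix only, so gene
    # ids that legitimately contain dots (Glyma.01G006400) are untouched and
    # the transform is idempotent.
    return re.sub(r"\.\d+$", "", identifier)


@dataclass(frozen=True)
class SpeciesIdScheme:
    """Identifier rules: which species an id belongs to, and isoform collapse.

    Patterns are shell-style globs (``fnmatch``), e.g. ``"AT*"`` for
    Arabidopsis AGI ids and ``"Glyma*"`` for soybean Wm82 ids. The collapse
    rules map an isoform id to its parent gene id; the default strips a
    trailing ``.<digits>`` suffix ("AT1G01090.1" -> "AT1G01090") and is
    idempotent on gene ids.
    """

    species_a_pattern: str = "AT*"
    species_b_pattern: str = "Glyma*"
    collapse_a: Callable[[str], str] = field(default=_default_collapse)
    collapse_b: Callable[[str], str] = field(default=_default_collapse)

    def species_of(self, identifier: str) -> str:
        """Return ``"a"`` or ``"b"``; raise if the id matches neither/both."""
        in_a = fnmatchcase(identifier, self.species_a_pattern)
        in_b = fnmatchcase(identifier, self.species_b_pattern)
        if in_a and in_b:
            raise UnknownSpeciesError(
                f"identifier {identifier!r} matches both species patterns"
            )
        if in_a:
            return "a"
        if in_b:
            return "b"
        raise UnknownSpeciesError(
            f"identifier {identifier!r} matches neither species pattern "
            f"({self.species_a_pattern!r}, {self.species_b_pattern!r})"
        )

    def gene_of(self, identifier: str, species: str | None = None) -> str:
        """Collapse an isoform identifier to its gene identifier."""
        sp = species or self.species_of(identifier)
        collapse = self.collapse_a if sp == "a" else self.collapse_b
        return collapse(identifier)


@dataclass(frozen=True)
class BestHit:
    subject: str
    evalue: float
    bitscore: float


@dataclass
class BestHitTable:
    """Per-gene single best cross-species hit, for one query direction.

    ``direction`` is an ordered species pair such as ``("a", "b")`` meaning
    queries from species a against subjects in species b. Each query gene
    has at most one entry.
    """

    direction: tuple[str, str]
    entries: dict[str, BestHit]

    def __getitem__(self, gene: str) -> BestHit:
        return self.entries[gene]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class OrthologPairSet:
    """Cross-species gene pairs with coupling weights.

    Pairs are oriented ``(gene_species_a, gene_species_b)`` following
    ``direction``. In RBH mode every gene appears in at most one pair and
    all weights are 1; in k-best mode a query gene may pair with up to k
    subject genes and each pair carries weight 1/(number of counterparts of
    the query gene).
    """

    pairs: set[tuple[str, str]]
    weights: dict[tuple[str, str], float]
    mode: str  # "rbh" | "kbest"
    direction: tuple[str, str] = ("a", "b")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def genes(self, side: int) -> set[str]:
        """Genes on side 0 (first member) or 1 (second member) of the pairs."""
        return {p[side] for p in self.pairs}


def _classify_and_collapse(
    hits: pd.DataFrame, scheme: SpeciesIdScheme
) -> pd.DataFrame:
    """Annotate hits with species and collapsed gene ids; validate all ids."""
    unknown: list[str] = []
    qsp, ssp, qg, sg = [], [], [], []
    for q, s in zip(hits["qseqid"], hits["sseqid"]):
        try:
            a = scheme.species_of(q)
        except UnknownSpeciesError:
            unknown.append(q)
            a = None
        try:
            b = scheme.species_of(s)
        except UnknownSpeciesError:
            unknown.append(s)
            b = None
        qsp.append(a)
        ssp.append(b)
        qg.append(scheme.gene_of(q, a) if a else None)
        sg.append(scheme.gene_of(s, b) if b else None)
    if unknown:
        uniq = sorted(set(unknown))
        raise UnknownSpeciesError(
            f"{len(uniq)} identifier(s) match no species pattern: "
            + ", ".join(uniq[:20])
            + ("..." if len(uniq) > 20 else "")
        )
    out = hits.copy()
    out["qspecies"], out["sspecies"] = qsp, ssp
    out["qgene"], out["sgene"] = qg, sg
    return out


def _ranked_cross_hits(
    hits: pd.DataFrame, scheme: SpeciesIdScheme, direction: tuple[str, str]
) -> pd.DataFrame:
    """Cross-species hits for one direction, best row per (qgene, sgene)."""
    if tuple(direction) not in {("a", "b"), ("b", "a")}:
        raise ValueError(f"direction must be ('a','b') or ('b','a'), got {direction}")
    ann = _classify_and_collapse(hits, scheme)
    cross = ann.loc[
        (ann["qspecies"] == direction[0]) & (ann["sspecies"] == direction[1])
    ]
    if cross.empty:
        return cross
    # deterministic ranking: min evalue, max bitscore, then subject gene id
    ranked = cross.sort_values(
        ["qgene", "evalue", "bitscore", "sgene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    # one row per gene pair: the best-scoring isoform-level HSP
    return ranked.drop_duplicates(["qgene", "sgene"], keep="first")


def collapse_and_best_hit(
    hits: pd.DataFrame, scheme: SpeciesIdScheme, direction: tuple[str, str] = ("a", "b")
) -> BestHitTable:
    """Collapse isoforms to genes and select each query gene's best subject.

    Within-species and self hits are discarded first (the alignment is run
    against a merged two-species database, so the raw output contains them).
    Ranking is deterministic: minimum E-value, ties by maximum bitscore,
    remaining ties by smallest subject gene id.
    """
    best = _ranked_cross_hits(hits, scheme, direction).drop_duplicates(
        "qgene", keep="first"
    )
    entries = {
        row.qgene: BestHit(row.sgene, row.evalue, row.bitscore)
        for row in best.itertuples()
    }
    return BestHitTable(direction=tuple(direction), entries=entries)


def reciprocal_best_hits(fwd: BestHitTable, rev: BestHitTable) -> OrthologPairSet:
    """Intersect two best-hit directions into reciprocal best-hit pairs.

    A pair (a, b) is kept iff fwd maps a -> b and rev maps b -> a. Pairs are
    oriented by ``fwd.direction`` and all coupling weights are 1.
    """
    if tuple(fwd.direction) != tuple(reversed(rev.direction)):
        raise ValueError(
            f"direction mismatch: fwd {fwd.direction} vs rev {rev.direction}"
        )
    pairs = {
        (a, hit.subject)
        for a, hit in fwd.entries.items()
        if hit.subject in rev.entries and rev.entries[hit.subject].subject == a
    }
    return OrthologPairSet(
        pairs=pairs,
        weights={p: 1.0 for p in pairs},
        mode="rbh",
        direction=tuple(fwd.direction),
    )


def k_best_hits(
    hits: pd.DataFrame,
    scheme: SpeciesIdScheme,
    direction: tuple[str, str] = ("a", "b"),
    k: int = 5,
) -> OrthologPairSet:
    """Top-k subject genes per query gene, with fractional coupling weights.

    Uses the same ranking as :func:`collapse_and_best_hit`; with k=1 the
    pair set equals the best-hit table. Each pair (q, s) carries weight
    1 / (number of counterparts of the query gene q), so a query with a
    single counterpart gets weight 1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = _ranked_cross_hits(hits, scheme, direction)
    top = ranked.groupby("qgene", sort=False).head(k)
    counts = top.groupby("qgene", sort=False)["sgene"].transform("size")
    oriented = tuple(direction) == ("a", "b")
    pairs: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    for row, n in zip(top.itertuples(), counts):
        pair = (row.qgene, row.sgene) if oriented else (row.sgene, row.qgene)
        pairs.add(pair)
        weights[pair] = 1.0 / int(n)
    return OrthologPairSet(
        pairs=pairs, weights=weights, mode="kbest", direction=("a", "b")
    )
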