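"""Reading, validating, and joining annotator and classifier outputs.

The two inputs consumed here are the standard artifacts of a gene-centric
metagenome workflow:

* a gene -> KO annotation table (GhostKOALA/KofamScan-style TSV), and
* a contig -> taxonomy table (Centrifuge/Kraken-style TSV with a ranked
  lineage string).

``join_community`` links each annotated gene to its contig's lineage and
yields an :class:`AnnotatedCommunity`, the queryable container behind all
screening operations: per-symbol hit counts for the pooled community and
for any taxon at any rank.  A *hit* is one annotated gene record assigned
to a KO (optionally weighted, e.g. by read depth).
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "AnnotationError",
    "TaxonomyError",
    "GeneAnnotation",
    "TaxonAssignment",
    "AnnotatedCommunity",
    "read_ko_table",
    "read_taxonomy_table",
    "write_ko_table",
    "write_taxonomy_table",
    "join_community",
    "parse_lineage",
    "contig_of_gene",
]

#: Fixed rank vocabulary, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Sentinel name for records that carry no assignment at a rank.
UNCLASSIFIED = "unclassified"

_KO_RE = re.compile(r"^K\d{5}$")
_RANK_PREFIX_RE = re.compile(r"^[a-z]__")


class AnnotationError(ValueError):
    pass


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: id, contig, and its (possibly blank) KO."""

    gene_id: str
    ko_id: str = ""
    contig_id: str = ""


@dataclass(frozen=True)
class TaxonAssignment:
    """Taxonomy of one contig as an ordered (rank, name) lineage."""

    contig_id: str
    taxon_id: str
    lineage: tuple[tuple[str, str], ...]

    def name_at(self, rank: str) -> str | None:
        for r, name in self.lineage:
            if r == rank:
                return name
        return None


def contig_of_gene(gene_id: str) -> str:
    """Infer the contig id from a prodigal-style gene id (``contig_12_3``).

    The trailing ``_<number>`` ORF ordinal is stripped; ids without one are
    returned unchanged.
    """
    stem, _, tail = gene_id.rpartition("_")
    if stem and tail.isdigit():
        return stem
    return gene_id


def _iter_lines(source):
    """Yield (line_number, line) from a path, text blob, stream or iterable."""
    if isinstance(source, (str, os.PathLike)):
        if isinstance(source, str) and ("\n" in source or "\t" in source):
            lines = io.StringIO(source)
        else:
            lines = open(source, "r", encoding="utf-8")
        with lines:
            for i, line in enumerate(lines, start=1):
                yield i, line.rstrip("\n")
    else:
        for i, line in enumerate(source, start=1):
            yield i, str(line).rstrip("\n")


def read_ko_table(source, dialect: str = "two-column") -> list[GeneAnnotation]:
    """Read a gene -> KO annotation table.

    Dialects: ``two-column`` (gene_id<TAB>ko, the canonical GhostKOALA
    form; a blank KO field marks an unannotated gene) and
    ``three-column-with-score`` (gene_id<TAB>ko<TAB>score; the score is
    ignored).  An optional ``gene_id`` header line is skipped.
    """
    if dialect not in ("two-column", "three-column-with-score"):
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    n_lines = 0
    for lineno, line in _iter_lines(source):
        n_lines += 1
        if not line.strip():
            continue
        fields = line.split("\t")
        gene_id = fields[0].strip()
        if lineno == 1 and gene_id.lower() in ("gene_id", "gene", "#gene_id"):
            continue
        if not gene_id:
            raise AnnotationError(f"row {lineno}: empty gene id")
        if gene_id in seen:
            raise AnnotationError(f"row {lineno}: duplicated gene id {gene_id!r}")
        seen.add(gene_id)
        ko = fields[1].strip() if len(fields) > 1 else ""
        if ko and not _KO_RE.match(ko):
            raise AnnotationError(f"row {lineno}: malformed KO token {ko!r}")
        out.append(GeneAnnotation(gene_id=gene_id, ko_id=ko, contig_id=contig_of_gene(gene_id)))
    if n_lines == 0:
        raise AnnotationError("empty annotation table")
    if not out:
        raise AnnotationError("annotation table contains no records")
    return out


def parse_lineage(text: str, lineno: int | None = None) -> tuple[tuple[str, str], ...]:
    """Parse a semicolon-delimited lineage into ordered (rank, name) pairs.

    Names are slotted positionally into the fixed rank vocabulary
    (domain ... species); ``d__``-style prefixes and a leading ``root``
    token are tolerated.  Truncated lineages simply yield fewer pairs.
    """
    where = f"row {lineno}: " if lineno is not None else ""
    names = [_RANK_PREFIX_RE.sub("", part.strip()) for part in text.split(";")]
    names = [n for n in names if n and n.lower() != "root"]
    if not names:
        raise TaxonomyError(f"{where}unparseable lineage string {text!r}")
    if len(names) > len(RANKS):
        names = names[: len(RANKS)]  # deeper-than-species tokens are dropped
    return tuple(zip(RANKS[: len(names)], names))


def read_taxonomy_table(source, dialect: str = "centrifuge") -> list[TaxonAssignment]:
    """Read a contig -> taxonomy table.

    Dialects:

    * ``centrifuge`` (canonical): contig_id<TAB>taxon_id<TAB>lineage
    * ``kraken``: C/U flag<TAB>contig_id<TAB>taxon_id<TAB>lineage;
      ``U`` rows are skipped (contig stays unclassified)
    * ``plain-lineage``: contig_id<TAB>lineage
    """
    if dialect not in ("centrifuge", "kraken", "plain-lineage"):
        raise TaxonomyError(f"unknown taxonomy dialect {dialect!r}")
    out: list[TaxonAssignment] = []
    seen: set[str] = set()
    for lineno, line in _iter_lines(source):
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() in ("contig_id", "contig", "#contig_id"):
            continue
        if dialect == "kraken":
            if len(fields) < 3:
                raise TaxonomyError(f"row {lineno}: expected >=3 fields")
            flag = fields[0].strip()
            if flag == "U":
                continue
            contig_id, taxon_id = fields[1].strip(), fields[2].strip()
            lineage_text = fields[3] if len(fields) > 3 else ""
        elif dialect == "plain-lineage":
            if len(fields) < 2:
                raise TaxonomyError(f"row {lineno}: expected 2 fields")
            contig_id, taxon_id = fields[0].strip(), ""
            lineage_text = fields[1]
        else:
            if len(fields) < 3:
                raise TaxonomyError(f"row {lineno}: expected 3 fields")
            contig_id, taxon_id = fields[0].strip(), fields[1].strip()
            lineage_text = fields[2]
        if not contig_id:
            raise TaxonomyError(f"row {lineno}: empty contig id")
        if contig_id in seen:
            raise TaxonomyError(f"row {lineno}: duplicated contig id {contig_id!r}")
        seen.add(contig_id)
        out.append(
            TaxonAssignment(
                contig_id=contig_id,
                taxon_id=taxon_id,
                lineage=parse_lineage(lineage_text, lineno),
            )
        )
    return out


def write_ko_table(annotations: Sequence[GeneAnnotation]) -> str:
    """Serialize annotations in the canonical two-column dialect."""
    return "".join(f"{a.gene_id}\t{a.ko_id}\n" for a in annotations)


def write_taxonomy_table(assignments: Sequence[TaxonAssignment]) -> str:
    """Serialize assignments in the canonical centrifuge-like dialect."""
    return "".join(
        f"{a.contig_id}\t{a.taxon_id}\t{';'.join(name for _, name in a.lineage)}\n"
        for a in assignments
    )


class AnnotatedCommunity:
    """Joined gene/KO/contig/taxon records with queryable hit counts.

    Built by :func:`join_community`.  ``hit_count(symbol)`` is the pooled
    community count; ``hit_count(symbol, taxon, rank)`` restricts to
    records whose lineage at ``rank`` equals ``taxon``.  Records on contigs
    absent from the taxonomy table count toward community totals but never
    toward any taxon.
    """

    def __init__(self, records: pd.DataFrame, symbol_hits: pd.DataFrame, join_stats: dict):
        self._records = records
        self._symbol_hits = symbol_hits  # columns: symbol, weight, + rank columns
        self.join_stats = join_stats
        self._community_counts = (
            symbol_hits.groupby("symbol", sort=True)["weight"].sum()
            if len(symbol_hits)
            else pd.Series(dtype="int64")
        )
        self._rank_counts: dict[str, pd.Series] = {}

    # -- construction helpers -------------------------------------------------

    @property
    def records(self) -> pd.DataFrame:
        """One row per gene record (gene_id, ko_id, contig_id, weight, ranks)."""
        return self._records

    @property
    def n_records(self) -> int:
        return int(self._records["weight"].sum())

    @property
    def n_annotated(self) -> int:
        return int(self._records.loc[self._records["ko_id"] != "", "weight"].sum())

    # -- counts ---------------------------------------------------------------

    def _counts_at(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        if rank not in self._rank_counts:
            hits = self._symbol_hits
            classified = hits[hits[rank].notna()]
            if len(classified):
                self._rank_counts[rank] = classified.groupby(
                    [rank, "symbol"], sort=True
                )["weight"].sum()
            else:
                empty = pd.MultiIndex.from_arrays([[], []], names=[rank, "symbol"])
                self._rank_counts[rank] = pd.Series(dtype="int64", index=empty)
        return self._rank_counts[rank]

    def hit_count(self, symbol: str, taxon: str | None = None, rank: str = "species") -> int:
        if taxon is None:
            return int(self._community_counts.get(symbol, 0))
        return int(self._counts_at(rank).get((taxon, symbol), 0))

    def unclassified_hit_count(self, symbol: str, rank: str = "species") -> int:
        """Hits of a symbol on records unclassified at ``rank``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        hits = self._symbol_hits
        sub = hits[(hits["symbol"] == symbol) & (hits[rank].isna())]
        return int(sub["weight"].sum())

    def community_counts(self) -> dict[str, int]:
        """Pooled per-symbol hit counts (symbols with at least one hit)."""
        return {s: int(c) for s, c in self._community_counts.items()}

    def complement(self, taxon: str | None = None, rank: str = "species") -> frozenset[str]:
        """Symbols with a positive hit count (community or one taxon)."""
        if taxon is None:
            return frozenset(self._community_counts.index[self._community_counts > 0])
        counts = self._counts_at(rank)
        if taxon not in counts.index.get_level_values(0):
            return frozenset()
        sub = counts.loc[taxon]
        return frozenset(sub.index[sub > 0])

    def taxa(self, rank: str = "species") -> list[str]:
        """Taxon names observed at a rank, sorted."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        col = self._records[rank]
        return sorted(col.dropna().unique())

    def lineage_of(self, taxon: str, rank: str = "species") -> tuple[str, ...]:
        """Most frequent ancestral lineage (domain..rank) for a taxon."""
        idx = RANKS.index(rank)
        cols = list(RANKS[: idx + 1])
        sub = self._records.loc[self._records[rank] == taxon, cols]
        if sub.empty:
            raise KeyError(f"taxon {taxon!r} not observed at rank {rank!r}")
        top = sub.fillna(UNCLASSIFIED).value_counts().idxmax()
        return tuple(top)

    def abundance_counts(self, rank: str = "species") -> tuple[pd.Series, int]:
        """(per-taxon record weights at rank, unclassified-at-rank weight)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        rec = self._records
        classified = rec[rec[rank].notna()]
        counts = classified.groupby(rank, sort=True)["weight"].sum()
        unclassified = int(rec["weight"].sum() - counts.sum())
        return counts, unclassified


def join_community(
    annotations: Sequence[GeneAnnotation],
    assignments: Sequence[TaxonAssignment],
    symbol_map: Mapping[str, str | Sequence[str]],
    weights: Mapping[str, float] | None = None,
) -> AnnotatedCommunity:
    """Join annotations to contig lineages under a KO -> symbol(s) map.

    ``symbol_map`` maps a KO id to one gene symbol or a sequence of symbols
    (a KO shared by several catalog genes credits each).  KOs without a map
    entry are carried symbol-less; contigs absent from ``assignments`` are
    treated as unclassified at every rank.  ``weights`` optionally assigns
    a per-gene hit weight (default 1), e.g. to emulate read-depth counts.
    """
    records = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "ko_id": [a.ko_id for a in annotations],
            "contig_id": [a.contig_id or contig_of_gene(a.gene_id) for a in annotations],
        }
    )
    if weights is None:
        records["weight"] = 1
    else:
        records["weight"] = records["gene_id"].map(weights).fillna(1).astype("int64")

    lineage_by_contig: dict[str, dict[str, str]] = {
        a.contig_id: dict(a.lineage) for a in assignments
    }
    for rank in RANKS:
        by_rank = {c: lin.get(rank) for c, lin in lineage_by_contig.items()}
        records[rank] = records["contig_id"].map(by_rank)
        records[rank] = records[rank].where(records[rank].notna(), np.nan)

    # explode KO -> symbols into one row per (record, symbol)
    norm_map: dict[str, tuple[str, ...]] = {}
    for ko, syms in symbol_map.items():
        norm_map[ko] = (syms,) if isinstance(syms, str) else tuple(syms)
    sym_col = records["ko_id"].map(norm_map)
    has_symbol = sym_col.notna()
    hits = records.loc[has_symbol, ["weight", *RANKS]].copy()
    hits["symbol"] = sym_col[has_symbol]
    hits = hits.explode("symbol", ignore_index=True)

    n_unjoined_contigs = len(
        set(records.loc[records["species"].isna(), "contig_id"]) - set(lineage_by_contig)
    )
    join_stats = {
        "n_genes": int(len(records)),
        "n_annotated": int((records["ko_id"] != "").sum()),
        "n_with_symbol": int(has_symbol.sum()),
        "n_contigs_without_taxonomy": n_unjoined_contigs,
    }
    return AnnotatedCommunity(records, hits, join_stats)
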