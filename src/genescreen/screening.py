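"""Gene-centric screening of metabolic production potential.

For every product in a pathway catalog this module decides, from joined
metagenome annotations, whether

* **Case I** (``SINGLE_MICROBE``): at least one taxon at the chosen rank
  carries a complete biosynthesis gene set on its own;
* **Case II** (``MIXED_COMMUNITY``): only the pooled community gene
  complement is complete (synthesis would require syntrophy);
* **Case III** (``NONE``): even the pooled complement is incomplete.

It also quantifies candidate rate-limiting steps: within one product's
gene set, the ratio of the minimum to the maximum per-gene hit number
(e.g. ectA 177 vs. lysC 12,563 gives 0.014) flags the step whose gene is
scarcest relative to the best-covered one.  Taxonomic relative-abundance
summaries at any rank round out the report.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

from .catalog import PathwayCatalog, expr_leaves, pathway_complete
from .community import RANKS, UNCLASSIFIED, AnnotatedCommunity

__all__ = [
    "Classification",
    "SingleProducer",
    "ProductScreen",
    "ScreeningResult",
    "HitProfile",
    "RateLimitingSummary",
    "AbundanceRow",
    "AbundanceTable",
    "screen_community",
    "hit_profile",
    "rate_limiting_ratio",
    "pairwise_ratio",
    "relative_abundance",
    "round_ratio",
]


class Classification(enum.Enum):
    """Producer classes: single taxon (I), pooled community only (II), none (III)."""

    SINGLE_MICROBE = "I"
    MIXED_COMMUNITY = "II"
    NONE = "III"


@dataclass(frozen=True)
class SingleProducer:
    rank: str
    name: str
    lineage: tuple[str, ...]

    @property
    def lineage_string(self) -> str:
        return ";".join(self.lineage)


@dataclass(frozen=True)
class ProductScreen:
    product_name: str
    community_complete: bool
    missing_steps: tuple[str, ...]
    single_producers: tuple[SingleProducer, ...]
    classification: Classification

    def __post_init__(self) -> None:
        # the three classes are mutually exclusive and exhaustive by construction;
        # assert the structural invariants all the same
        if self.classification is Classification.SINGLE_MICROBE:
            assert self.community_complete and self.single_producers
        elif self.classification is Classification.MIXED_COMMUNITY:
            assert self.community_complete and not self.single_producers
        else:
            assert not self.community_complete


@dataclass(frozen=True)
class ScreeningResult:
    rank: str
    products: Mapping[str, ProductScreen]

    def __getitem__(self, product_name: str) -> ProductScreen:
        return self.products[product_name]


def screen_community(
    catalog: PathwayCatalog,
    community: AnnotatedCommunity,
    rank: str = "species",
) -> ScreeningResult:
    """Classify every catalog product as Case I, II, or III.

    The pooled complement is every symbol with a positive community hit
    count (records on contigs without taxonomy included); a taxon's own
    complement is restricted to its records at ``rank``.  Precedence is
    I over II over III.  An empty community yields NONE for every product
    with a warning rather than an error.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    pooled = community.complement()
    if not pooled:
        warnings.warn("community has no annotated genes; every product is Case III")
    taxa = community.taxa(rank)
    complements = {t: community.complement(t, rank) for t in taxa}

    known = frozenset(catalog.gene_index)
    results: dict[str, ProductScreen] = {}
    for pathway in catalog.products:
        complete, missing = pathway_complete(pathway, pooled & known, known)
        producers: list[SingleProducer] = []
        if complete:
            for taxon in taxa:
                ok, _ = pathway_complete(pathway, complements[taxon] & known, known)
                if ok:
                    producers.append(
                        SingleProducer(rank, taxon, community.lineage_of(taxon, rank))
                    )
        if complete and producers:
            cls = Classification.SINGLE_MICROBE
        elif complete:
            cls = Classification.MIXED_COMMUNITY
        else:
            cls = Classification.NONE
        results[pathway.product_name] = ProductScreen(
            product_name=pathway.product_name,
            community_complete=complete,
            missing_steps=tuple(missing),
            single_producers=tuple(producers),
            classification=cls,
        )
    return ScreeningResult(rank=rank, products=results)


@dataclass(frozen=True)
class HitProfile:
    """Per-gene and per-step community hit counts for one product.

    ``per_gene`` covers every distinct leaf symbol of the product's
    expression (zero-count genes included); ``per_step`` sums the per-gene
    counts over each step's leaves.  The extremes ``min_gene``/``max_gene``
    are taken over genes with positive counts (ties broken by lexicographic
    symbol order) — genes of an unused alternative route carry zero hits
    without being rate information.  ``satisfied`` records whether the
    positive-count complement completes the pathway; when it does not, a
    required gene is absent and the min/max ratio is not meaningful.
    """

    product_name: str
    per_gene: Mapping[str, int]
    per_step: Mapping[str, int]
    min_gene: str | None
    max_gene: str | None
    satisfied: bool

    @property
    def min_count(self) -> int:
        return self.per_gene[self.min_gene] if self.min_gene else 0

    @property
    def max_count(self) -> int:
        return self.per_gene[self.max_gene] if self.max_gene else 0


def hit_profile(
    catalog: PathwayCatalog, community: AnnotatedCommunity, product_name: str
) -> HitProfile:
    """Community hit-count profile for one catalog product."""
    pathway = catalog.product(product_name)  # raises KeyError on unknown product
    per_gene = {sym: community.hit_count(sym) for sym in pathway.leaf_symbols}
    per_step = {}
    for step in pathway.steps:
        step_syms = dict.fromkeys(expr_leaves(step.expr))
        per_step[step.step_id] = sum(per_gene[s] for s in step_syms)
    positive = sorted(s for s, c in per_gene.items() if c > 0)
    if positive:
        # min()/max() keep the first of tied keys, so iterating the sorted
        # symbol list breaks ties lexicographically for both extremes
        min_gene = min(positive, key=per_gene.__getitem__)
        max_gene = max(positive, key=per_gene.__getitem__)
    else:
        min_gene = max_gene = None
    satisfied, _ = pathway_complete(pathway, set(positive))
    return HitProfile(
        product_name=product_name,
        per_gene=per_gene,
        per_step=per_step,
        min_gene=min_gene,
        max_gene=max_gene,
        satisfied=satisfied,
    )


def round_ratio(numerator: int, denominator: int, places: int = 3) -> float:
    """Exact quotient rounded half-away-from-zero to ``places`` decimals."""
    if places < 1:
        raise ValueError("rounding places must be >= 1")
    if denominator == 0:
        raise ZeroDivisionError("zero denominator")
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateLimitingSummary:
    """Min/max per-gene hit ratio for one product (candidate bottleneck)."""

    product_name: str
    ratio: float | None
    min_gene: str | None
    max_gene: str | None
    defined: bool


def rate_limiting_ratio(profile: HitProfile, rounding: int = 3) -> RateLimitingSummary:
    """Ratio of the lowest to the highest per-gene hit count of a product.

    Undefined (ratio ``None``) when the profile's positive-count genes do
    not complete the pathway — absence of a required gene is a completeness
    question, not a rate question — or when no gene has any hits.
    """
    if len(profile.per_gene) < 2:
        raise ValueError("profile needs at least two genes")
    if not profile.satisfied or profile.min_gene is None or profile.max_count == 0:
        return RateLimitingSummary(profile.product_name, None, profile.min_gene,
                                   profile.max_gene, defined=False)
    ratio = round_ratio(profile.min_count, profile.max_count, rounding)
    return RateLimitingSummary(profile.product_name, ratio, profile.min_gene,
                               profile.max_gene, defined=True)


def pairwise_ratio(
    profile: HitProfile, numerator_gene: str, denominator_gene: str, rounding: int = 3
) -> float:
    """Hit-count ratio of two named genes of one product's profile."""
    for gene in (numerator_gene, denominator_gene):
        if gene not in profile.per_gene:
            raise KeyError(f"gene {gene!r} not in profile of {profile.product_name!r}")
    den = profile.per_gene[denominator_gene]
    if den == 0:
        raise ZeroDivisionError(f"gene {denominator_gene!r} has zero hits")
    return round_ratio(profile.per_gene[numerator_gene], den, rounding)


@dataclass(frozen=True)
class AbundanceRow:
    name: str
    count: int
    fraction: float
    kind: str  # "taxon", "other", or "unclassified"


@dataclass(frozen=True)
class AbundanceTable:
    rank: str
    rows: tuple[AbundanceRow, ...]
    truncated: bool

    def fractions(self) -> dict[str, float]:
        return {r.name: r.fraction for r in self.rows}


def relative_abundance(
    community: AnnotatedCommunity, rank: str = "species", top_n: int = 50
) -> AbundanceTable:
    """Top-N taxon relative abundances at a rank, by gene-record weight.

    Fractions are taxon records over *all* records (classified at the rank
    or not), so the listed rows plus the ``other`` remainder and the
    ``unclassified`` row sum to one.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts, unclassified = community.abundance_counts(rank)
    total = int(counts.sum()) + unclassified
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        AbundanceRow(name, int(c), (int(c) / total) if total else 0.0, "taxon")
        for name, c in ordered[:top_n]
    ]
    truncated = len(ordered) > top_n
    if truncated:
        rest = int(sum(c for _, c in ordered[top_n:]))
        rows.append(AbundanceRow("other", rest, rest / total, "other"))
    if unclassified or not rows:
        frac = (unclassified / total) if total else 0.0
        rows.append(AbundanceRow(UNCLASSIFIED, unclassified, frac, "unclassified"))
    return AbundanceTable(rank=rank, rows=tuple(rows), truncated=truncated)
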