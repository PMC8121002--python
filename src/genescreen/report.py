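"""Plain-TSV report assembly for screening runs.

Four tables: the classification matrix (product x mixed culture / producer
lineage / producer species), the per-product hit profiles, the
rate-limiting ratio summary, and the taxonomic abundance table.  All
writers are deterministic: rows follow catalog order or sorted taxon
order, so reruns and input row permutations yield identical bytes.
"""

from __future__ import annotations

from typing import Sequence

from .catalog import PathwayCatalog
from .screening import (
    AbundanceTable,
    Classification,
    HitProfile,
    RateLimitingSummary,
    ScreeningResult,
)

__all__ = [
    "classification_table",
    "hit_profiles_table",
    "ratios_table",
    "abundance_table_tsv",
]

_PRESENT = "+"
_ABSENT = "-"


def classification_table(result: ScreeningResult) -> str:
    """Product-by-producer matrix, one row per product.

    ``lineage`` lists each single producer's ancestral lineage (ranks above
    the screening rank); multiple producers are separated by `` | ``.
    """
    lines = ["product\tmixed_culture\tcase\tlineage\tspecies"]
    for name, screen in result.products.items():
        mixed = _PRESENT if screen.community_complete else _ABSENT
        if screen.single_producers:
            lineages = " | ".join(
                ";".join(p.lineage[:-1]) if len(p.lineage) > 1 else p.lineage[0]
                for p in screen.single_producers
            )
            names = " | ".join(p.name for p in screen.single_producers)
        else:
            lineages = names = _ABSENT
        lines.append(f"{name}\t{mixed}\t{screen.classification.value}\t{lineages}\t{names}")
    return "\n".join(lines) + "\n"


def hit_profiles_table(catalog: PathwayCatalog, profiles: Sequence[HitProfile]) -> str:
    """Long-format per-step, per-gene hit counts (catalog order)."""
    from .catalog import expr_leaves

    lines = ["product\tstep\tgene\tcount"]
    by_name = {p.product_name: p for p in profiles}
    for pathway in catalog.products:
        profile = by_name.get(pathway.product_name)
        if profile is None:
            continue
        for step in pathway.steps:
            for sym in dict.fromkeys(expr_leaves(step.expr)):
                lines.append(
                    f"{pathway.product_name}\t{step.step_id}\t{sym}\t{profile.per_gene[sym]}"
                )
    return "\n".join(lines) + "\n"


def ratios_table(summaries: Sequence[RateLimitingSummary]) -> str:
    lines = ["product\tmin_gene\tmax_gene\tratio\tdefined"]
    for s in summaries:
        ratio = f"{s.ratio}" if s.defined else "NA"
        lines.append(
            f"{s.product_name}\t{s.min_gene or 'NA'}\t{s.max_gene or 'NA'}\t{ratio}\t"
            f"{'yes' if s.defined else 'no'}"
        )
    return "\n".join(lines) + "\n"


def abundance_table_tsv(table: AbundanceTable) -> str:
    lines = ["rank\ttaxon\tcount\tfraction"]
    for row in table.rows:
        lines.append(f"{table.rank}\t{row.name}\t{row.count}\t{row.fraction:.6f}")
    return "\n".join(lines) + "\n"
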