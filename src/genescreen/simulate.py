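"""Synthetic metagenome annotation generator with ground-truth manifests.

Emits the two canonical input tables (gene -> KO annotations, contig ->
taxonomy) for communities whose composition and gene complements are
designed, together with a manifest recording the realized truth: per-taxon
and community hit counts, the expected Case I/II/III classification of
every catalog product, and relative-abundance fractions.  Because the
tables and the manifest are written from the same draw, the manifest is an
exact oracle for the whole screening pipeline.

Counts are drawn at KO resolution (one annotated gene record per hit), so
symbols that share a KO — indistinguishable to a KO-based annotator — are
credited together, exactly as the join does.  A taxon designed to lack a
symbol never emits any record whose KO maps to that symbol.

:func:`paper_like_fixture` builds one fixed community whose pooled per-gene
hit numbers embed published worked-example values (ectA 177, lysC 12,563,
phaA 2,532, phaB 2,476, phaC 14,491, alsD 115) and whose presence/absence
pattern has six products community-complete and lutein incomplete.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import PathwayCatalog, load_default_catalog, pathway_complete
from .community import RANKS

__all__ = [
    "DesignError",
    "CountModel",
    "TaxonSpec",
    "SyntheticDesign",
    "SyntheticBundle",
    "generate",
    "random_design",
    "parse_design",
    "load_demo_design",
    "paper_like_fixture",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class CountModel:
    """Distribution of per-gene (per-KO) hit counts.

    ``log-uniform`` over [50, 15000] by default, spanning the dynamic range
    typical of deeply sequenced communities (roughly 1e2..1.5e4 hits per
    gene); ``uniform`` draws integers on [low, high].
    """

    family: str = "log-uniform"
    low: int = 50
    high: int = 15000

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "log-uniform"):
            raise DesignError(f"unknown count model family {self.family!r}")
        if not (1 <= self.low <= self.high):
            raise DesignError("count model needs 1 <= low <= high")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "uniform":
            return rng.integers(self.low, self.high + 1, size=size)
        raw = np.exp(rng.uniform(math.log(self.low), math.log(self.high), size=size))
        return np.maximum(np.rint(raw).astype(int), 1)


@dataclass(frozen=True)
class TaxonSpec:
    """One designed taxon: lineage, abundance weight, per-product complement.

    ``products`` maps a catalog product name to the tuple of symbols the
    taxon is *missing* from that product's gene set; an empty tuple means
    the complete set.  Products not listed contribute no genes.
    """

    name: str
    lineage: tuple[str, ...]
    weight: float = 1.0
    products: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def species(self) -> str | None:
        return self.lineage[6] if len(self.lineage) >= 7 else None


@dataclass(frozen=True)
class SyntheticDesign:
    taxa: tuple[TaxonSpec, ...]
    count_model: CountModel = CountModel()
    unclassified_fraction: float = 0.0
    seed: int = 0
    background_per_weight: int = 50
    contigs_per_taxon: int = 3


@dataclass(frozen=True)
class SyntheticBundle:
    annotation_tsv: str
    taxonomy_tsv: str
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, sort_keys=True, indent=2) + "\n"


def _validate_design(design: SyntheticDesign, catalog: PathwayCatalog) -> None:
    if not design.taxa:
        raise DesignError("design has no taxa")
    if not (0.0 <= design.unclassified_fraction < 1.0):
        raise DesignError("unclassified_fraction must be in [0, 1)")
    if design.contigs_per_taxon < 1:
        raise DesignError("contigs_per_taxon must be >= 1")
    names = [t.name for t in design.taxa]
    if len(set(names)) != len(names):
        raise DesignError("taxon names must be unique")
    for taxon in design.taxa:
        if taxon.weight <= 0:
            raise DesignError(f"taxon {taxon.name!r}: weight must be positive")
        if not (1 <= len(taxon.lineage) <= len(RANKS)):
            raise DesignError(f"taxon {taxon.name!r}: lineage must have 1..{len(RANKS)} ranks")
        for product, missing in taxon.products.items():
            try:
                leaves = set(catalog.product(product).leaf_symbols)
            except KeyError:
                raise DesignError(f"taxon {taxon.name!r}: unknown product {product!r}")
            unknown = set(missing) - leaves
            if unknown:
                raise DesignError(
                    f"taxon {taxon.name!r}, product {product!r}: "
                    f"missing symbols not in gene set: {sorted(unknown)}"
                )


def _taxon_kos(taxon: TaxonSpec, catalog: PathwayCatalog) -> list[str]:
    """KOs a taxon emits: its designed complement, minus any KO that would
    credit a symbol the taxon is designed to lack."""
    sym2ko = catalog.symbol_to_ko()
    ko2sym = catalog.ko_to_symbols()
    carried: set[str] = set()
    missing: set[str] = set()
    for product, miss in taxon.products.items():
        leaves = set(catalog.product(product).leaf_symbols)
        carried |= leaves - set(miss)
        missing |= set(miss)
    kos = set()
    for sym in carried:
        ko = sym2ko.get(sym)
        if ko is None:
            raise DesignError(f"symbol {sym!r} has no KO id; cannot be emitted")
        if not (set(ko2sym[ko]) & missing):
            kos.add(ko)
    return sorted(kos)


def _build_manifest(
    catalog: PathwayCatalog,
    rec: pd.DataFrame,
    contig_lineage: Mapping[str, tuple[str, ...]],
    seed: int,
) -> dict:
    """Ground truth for a record table given the *kept* contig lineages."""
    ko2sym = catalog.ko_to_symbols()

    def _expand(ko_counts: Mapping[str, int]) -> dict[str, int]:
        out: dict[str, int] = {}
        for ko, n in ko_counts.items():
            for sym in ko2sym.get(ko, ()):
                out[sym] = out.get(sym, 0) + int(n)
        return out

    annotated = rec[rec["ko"] != ""]
    community = _expand(annotated.groupby("ko").size().to_dict())

    species_of = {
        c: lin[6] for c, lin in contig_lineage.items() if len(lin) >= 7
    }
    rec_species = rec["contig"].map(species_of)
    classified = rec[rec_species.notna()].assign(species=rec_species.dropna())

    by_species: dict[str, dict[str, int]] = {}
    ann_classified = classified[classified["ko"] != ""]
    if len(ann_classified):
        for (sp, ko), n in ann_classified.groupby(["species", "ko"]).size().items():
            for sym in ko2sym.get(ko, ()):
                d = by_species.setdefault(sp, {})
                d[sym] = d.get(sym, 0) + int(n)

    community_syms = frozenset(community)
    classification: dict[str, str] = {}
    producers: dict[str, list[str]] = {}
    for pathway in catalog.products:
        complete, _ = pathway_complete(pathway, community_syms)
        who = [
            sp
            for sp in sorted(by_species)
            if complete and pathway_complete(pathway, frozenset(by_species[sp]))[0]
        ]
        if complete and who:
            classification[pathway.product_name] = "SINGLE_MICROBE"
        elif complete:
            classification[pathway.product_name] = "MIXED_COMMUNITY"
        else:
            classification[pathway.product_name] = "NONE"
        producers[pathway.product_name] = who

    n_total = len(rec)
    sp_counts = classified.groupby("species").size() if len(classified) else pd.Series(dtype=int)
    abundance = {sp: int(n) / n_total for sp, n in sp_counts.items()}
    unclassified_frac = (n_total - int(sp_counts.sum())) / n_total if n_total else 0.0

    return {
        "seed": seed,
        "n_records": int(n_total),
        "n_annotated": int(len(annotated)),
        "hit_counts": {
            "community": dict(sorted(community.items())),
            "by_species": {sp: dict(sorted(d.items())) for sp, d in sorted(by_species.items())},
        },
        "classification": classification,
        "single_producers": producers,
        "abundance": {"species": dict(sorted(abundance.items())),
                      "unclassified": unclassified_frac},
    }


def _records_to_tsvs(
    rec: pd.DataFrame, taxonomy_entries: Sequence[tuple[str, str, tuple[str, ...]]]
) -> tuple[str, str]:
    ann = rec["gene_id"].str.cat(rec["ko"], sep="\t")
    annotation_tsv = "\n".join(ann) + "\n" if len(ann) else ""
    tax_lines = [
        f"{contig}\t{taxon_id}\t{';'.join(lineage)}" for contig, taxon_id, lineage in taxonomy_entries
    ]
    taxonomy_tsv = "\n".join(tax_lines) + "\n" if tax_lines else ""
    return annotation_tsv, taxonomy_tsv


def _emit_taxon_records(
    kos_per_record: np.ndarray, contigs: Sequence[str]
) -> pd.DataFrame:
    """Distribute a taxon's records round-robin over its contigs."""
    n = len(kos_per_record)
    idx = np.arange(n)
    contig_arr = np.asarray(contigs, dtype=object)[idx % len(contigs)]
    ordinal = idx // len(contigs) + 1
    gene_ids = [f"{c}_{o}" for c, o in zip(contig_arr, ordinal)]
    return pd.DataFrame({"gene_id": gene_ids, "ko": kos_per_record, "contig": contig_arr})


def generate(design: SyntheticDesign, catalog: PathwayCatalog | None = None) -> SyntheticBundle:
    """Realize a design into annotation + taxonomy TSVs and a manifest.

    Deterministic for a fixed design (the seed lives in the design): the
    same design yields byte-identical tables.  Per-KO hit counts are drawn
    from the design's count model; each taxon additionally receives
    ``round(weight * background_per_weight)`` unannotated background genes,
    which carry its relative abundance.  Unclassified contigs are selected
    last and removed from the taxonomy table only.
    """
    catalog = catalog if catalog is not None else load_default_catalog()
    _validate_design(design, catalog)
    rng = np.random.default_rng(design.seed)

    frames = []
    contig_lineage_all: dict[str, tuple[str, ...]] = {}
    taxon_id_of_contig: dict[str, str] = {}
    for i, taxon in enumerate(design.taxa):
        kos = _taxon_kos(taxon, catalog)
        counts = design.count_model.draw(rng, len(kos)) if kos else np.array([], dtype=int)
        n_background = int(round(taxon.weight * design.background_per_weight))
        ko_col = np.repeat(np.array(kos + [""], dtype=object),
                           np.append(counts, n_background))
        if len(ko_col) == 0:
            continue
        contigs = [f"t{i:03d}c{j + 1}" for j in range(design.contigs_per_taxon)]
        frames.append(_emit_taxon_records(ko_col, contigs))
        for c in contigs:
            contig_lineage_all[c] = taxon.lineage
            taxon_id_of_contig[c] = f"T{i:03d}"
    rec = pd.concat(frames, ignore_index=True)

    # unclassified contigs: drawn last, stripped from the taxonomy table only
    all_contigs = sorted(contig_lineage_all)
    n_strip = int(math.floor(design.unclassified_fraction * len(all_contigs)))
    stripped = set(rng.choice(all_contigs, size=n_strip, replace=False)) if n_strip else set()

    kept = {c: lin for c, lin in contig_lineage_all.items() if c not in stripped}
    taxonomy_entries = [(c, taxon_id_of_contig[c], kept[c]) for c in sorted(kept)]
    annotation_tsv, taxonomy_tsv = _records_to_tsvs(rec, taxonomy_entries)
    manifest = _build_manifest(catalog, rec, kept, design.seed)
    return SyntheticBundle(annotation_tsv, taxonomy_tsv, manifest)


def random_design(
    seed: int,
    catalog: PathwayCatalog | None = None,
    max_taxa: int = 5,
    count_low: int = 1,
    count_high: int = 30,
) -> SyntheticDesign:
    """Draw a small random design (for property and recovery testing).

    Every taxon gets, per product, one of: no genes, the complete set, or
    the set minus one or two symbols; about half the designs strip a fifth
    of the contigs from the taxonomy table.
    """
    catalog = catalog if catalog is not None else load_default_catalog()
    rng = np.random.default_rng(seed)
    n_taxa = int(rng.integers(2, max_taxa + 1))
    taxa = []
    for i in range(n_taxa):
        products: dict[str, tuple[str, ...]] = {}
        for pathway in catalog.products:
            u = rng.random()
            if u < 0.45:
                continue  # taxon carries nothing of this product
            leaves = list(pathway.leaf_symbols)
            if u < 0.75:
                products[pathway.product_name] = ()
            else:
                k = int(rng.integers(1, min(2, len(leaves)) + 1))
                drop = rng.choice(len(leaves), size=k, replace=False)
                products[pathway.product_name] = tuple(sorted(leaves[j] for j in drop))
        lineage = (
            f"dom{i % 2}", f"phylum{i}", f"class{i}", f"order{i}",
            f"family{i}", f"genus{i}", f"Species {i}",
        )
        taxa.append(
            TaxonSpec(
                name=f"Species {i}",
                lineage=lineage,
                weight=float(rng.uniform(0.5, 3.0)),
                products=products,
            )
        )
    return SyntheticDesign(
        taxa=tuple(taxa),
        count_model=CountModel("uniform", count_low, count_high),
        unclassified_fraction=float(rng.choice([0.0, 0.2])),
        seed=int(rng.integers(0, 2**31 - 1)),
        background_per_weight=20,
    )


# ---------------------------------------------------------------------------
# design documents


def parse_design(text: str) -> SyntheticDesign:
    """Parse a design document (YAML).

    Schema::

        seed: 7
        unclassified_fraction: 0.1
        count_model: {family: log-uniform, low: 50, high: 15000}
        background_per_weight: 50
        contigs_per_taxon: 3
        taxa:
          - name: Species one
            lineage: [Bacteria, ..., Species one]      # domain..species
            weight: 2.0
            products:
              PHB: complete
              ectoine: {missing: [ectA]}
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise DesignError(f"design syntax error: {exc}") from exc
    if not isinstance(doc, dict) or "taxa" not in doc:
        raise DesignError("design document must be a mapping with a 'taxa' list")
    cm = doc.get("count_model", {}) or {}
    taxa = []
    for entry in doc["taxa"]:
        products: dict[str, tuple[str, ...]] = {}
        for pname, spec in (entry.get("products", {}) or {}).items():
            if spec == "complete":
                products[pname] = ()
            elif isinstance(spec, dict) and "missing" in spec:
                products[pname] = tuple(spec["missing"])
            else:
                raise DesignError(
                    f"taxon {entry.get('name')!r}, product {pname!r}: "
                    "expected 'complete' or {missing: [...]}"
                )
        taxa.append(
            TaxonSpec(
                name=str(entry["name"]),
                lineage=tuple(str(x) for x in entry["lineage"]),
                weight=float(entry.get("weight", 1.0)),
                products=products,
            )
        )
    return SyntheticDesign(
        taxa=tuple(taxa),
        count_model=CountModel(
            family=str(cm.get("family", "log-uniform")),
            low=int(cm.get("low", 50)),
            high=int(cm.get("high", 15000)),
        ),
        unclassified_fraction=float(doc.get("unclassified_fraction", 0.0)),
        seed=int(doc.get("seed", 0)),
        background_per_weight=int(doc.get("background_per_weight", 50)),
        contigs_per_taxon=int(doc.get("contigs_per_taxon", 3)),
    )


def load_demo_design() -> SyntheticDesign:
    from importlib import resources

    text = resources.files("genescreen.data").joinpath("demo_design.yaml").read_text("utf-8")
    return parse_design(text)


# ---------------------------------------------------------------------------
# fixed worked-example community
#
# Pooled per-KO totals.  Values for ectA, lysC, phaA, phaB, phaC and alsD
# are published worked-example hit numbers; the remaining totals are fixed
# choices within the same dynamic range, consistent with the published
# min/max ratios of their products (E2.2.1.6L from 115/0.0045; crtZ and
# crtW placed so both carotenoid ratios round to 0.11).  Symbols sharing a
# KO (phaA/atoB, butA/budC) are keyed by one representative.

_FX_TOTALS = {
    "lysC": 12563, "asd": 9835, "ectB": 3412, "ectA": 177, "ectC": 2954,
    "phaA": 2532, "phaB": 2476, "phaC": 14491,
    "E2.2.1.6L": 25556, "E2.2.1.6S": 1892, "ilvM": 754, "alsD": 115,
    "BDH": 2103, "butA": 3377,
    "dxs": 4100, "dxr": 2250, "ispD": 1820, "ispE": 2540, "ispF": 1933,
    "ispG": 5210, "ispH": 4876,
    "ispA": 7231, "crtE": 1406, "crtB": 980, "crtI": 1510,
    "crtY": 830, "crtZ": 798, "crtW": 795,
}

#: (name, lineage domain..species, total gene records, per-symbol counts)
_FX_TAXA = [
    ("Methyloceanibacter caenitepidi",
     ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales",
      "Methyloligellaceae", "Methyloceanibacter", "Methyloceanibacter caenitepidi"),
     2400, {"phaA": 220, "phaB": 215, "phaC": 930}),
    ("Rhodopseudomonas palustris",
     ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales",
      "Nitrobacteraceae", "Rhodopseudomonas", "Rhodopseudomonas palustris"),
     1800, {"lysC": 160, "asd": 140, "dxs": 52, "dxr": 48, "ispD": 40, "ispE": 45,
            "ispF": 41, "ispG": 60, "ispH": 58, "ispA": 75, "crtE": 38,
            "crtB": 35, "crtI": 44}),
    ("Candidatus Filomicrobium marinum W",
     ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales",
      "Hyphomicrobiaceae", "Filomicrobium", "Candidatus Filomicrobium marinum W"),
     1200, {"phaA": 105, "phaB": 98, "phaC": 410}),
    ("Janthinobacterium sp. Marseille",
     ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales",
      "Oxalobacteraceae", "Janthinobacterium", "Janthinobacterium sp. Marseille"),
     900, {"phaA": 88, "phaB": 80, "phaC": 350}),
    ("Candidatus Promineofilum breve",
     ("Bacteria", "Chloroflexi", "Ardenticatenia", "Ardenticatenales",
      "Ardenticatenaceae", "Candidatus Promineofilum", "Candidatus Promineofilum breve"),
     800, {"E2.2.1.6L": 120, "ilvM": 35, "alsD": 28}),
    ("Caldilinea aerophila",
     ("Bacteria", "Chloroflexi", "Caldilineae", "Caldilineales",
      "Caldilineaceae", "Caldilinea", "Caldilinea aerophila"),
     700, {"E2.2.1.6L": 95, "ilvM": 30, "alsD": 22, "butA": 60, "BDH": 45}),
    ("Lonsdalea britannica",
     ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
      "Pectobacteriaceae", "Lonsdalea", "Lonsdalea britannica"),
     600, {"E2.2.1.6L": 80, "E2.2.1.6S": 40, "alsD": 18, "butA": 50, "BDH": 38}),
    ("Orrella dioscoreae",
     ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales",
      "Alcaligenaceae", "Orrella", "Orrella dioscoreae"),
     600, {"E2.2.1.6L": 75, "ilvM": 28, "alsD": 15, "butA": 45, "BDH": 35}),
    ("Sphingomonas paucimobilis",
     ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales",
      "Sphingomonadaceae", "Sphingomonas", "Sphingomonas paucimobilis"),
     500, {"crtY": 70, "crtZ": 66}),
    ("Brevundimonas vesicularis",
     ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Caulobacterales",
      "Caulobacteraceae", "Brevundimonas", "Brevundimonas vesicularis"),
     500, {"crtW": 72, "crtZ": 64}),
    ("Methylophaga nitratireducenticrescens",
     ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Nitrosococcales",
      "Methylophagaceae", "Methylophaga", "Methylophaga nitratireducenticrescens"),
     700, {"ectB": 90, "ectA": 25}),
    ("Nitrosopumilus maritimus",
     ("Archaea", "Thaumarchaeota", "Nitrososphaeria", "Nitrosopumilales",
      "Nitrosopumilaceae", "Nitrosopumilus", "Nitrosopumilus maritimus"),
     400, {"ectC": 55}),
]

FIXTURE_TOTAL_RECORDS = 200_000
_FX_CONTIGS_PER_TAXON = 5
_FX_UNCLASSIFIED_CONTIGS = 400


@lru_cache(maxsize=1)
def paper_like_fixture() -> SyntheticBundle:
    """Fixed synthetic community mirroring the published worked example.

    Wholly synthetic (no sequencing data involved): twelve named species
    carry designed slices of the pathway gene sets, the balance of every
    gene's hits sits on contigs absent from the taxonomy table, and
    unannotated background genes pad each species to a fixed record total
    (200,000 records overall, giving the most abundant species 1.2% and
    the runner-up 0.9%).  Deterministic: repeated calls are byte-identical.
    """
    catalog = load_default_catalog()
    sym2ko = catalog.symbol_to_ko()

    allocated: dict[str, int] = {s: 0 for s in _FX_TOTALS}
    frames = []
    contig_lineage: dict[str, tuple[str, ...]] = {}
    taxon_id_of_contig: dict[str, str] = {}
    for i, (name, lineage, total, symbol_counts) in enumerate(_FX_TAXA):
        kos, reps = [], []
        for sym in sorted(symbol_counts):
            allocated[sym] += symbol_counts[sym]
            kos.append(sym2ko[sym])
            reps.append(symbol_counts[sym])
        n_annotated = sum(reps)
        assert n_annotated <= total, name
        ko_col = np.repeat(np.array(kos + [""], dtype=object),
                           np.array(reps + [total - n_annotated]))
        contigs = [f"t{i:02d}c{j + 1}" for j in range(_FX_CONTIGS_PER_TAXON)]
        frames.append(_emit_taxon_records(ko_col, contigs))
        for c in contigs:
            contig_lineage[c] = lineage
            taxon_id_of_contig[c] = f"T{i:03d}"

    # community remainders + padding land on contigs with no taxonomy
    rem_kos, rem_reps = [], []
    for sym in sorted(_FX_TOTALS):
        remainder = _FX_TOTALS[sym] - allocated[sym]
        assert remainder >= 0, sym
        rem_kos.append(sym2ko[sym])
        rem_reps.append(remainder)
    n_classified = sum(t for _, _, t, _ in _FX_TAXA)
    n_background = FIXTURE_TOTAL_RECORDS - n_classified - sum(rem_reps)
    assert n_background >= 0
    ko_col = np.repeat(np.array(rem_kos + [""], dtype=object),
                       np.array(rem_reps + [n_background]))
    contigs = [f"u{j:04d}" for j in range(_FX_UNCLASSIFIED_CONTIGS)]
    frames.append(_emit_taxon_records(ko_col, contigs))

    rec = pd.concat(frames, ignore_index=True)
    taxonomy_entries = [
        (c, taxon_id_of_contig[c], contig_lineage[c]) for c in sorted(contig_lineage)
    ]
    annotation_tsv, taxonomy_tsv = _records_to_tsvs(rec, taxonomy_entries)
    manifest = _build_manifest(catalog, rec, contig_lineage, seed=0)
    return SyntheticBundle(annotation_tsv, taxonomy_tsv, manifest)
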