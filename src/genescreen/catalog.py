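"""Biosynthesis pathway catalog: boolean gene-requirement expressions.

A :class:`PathwayCatalog` describes, for each target product, the ordered
reaction steps from an entry metabolite (assumed supplied by central
metabolism) to the product, where each step carries a boolean requirement
expression over gene symbols.  A pathway is *complete* for a given gene
complement when every step's expression is satisfied.  Expressions support
conjunction (``all``), disjunction (``any``, used for alternative routes
such as the mevalonate vs. methylerythritol-phosphate terpenoid backbone),
and gene-symbol leaves.

The packaged default catalog covers seven products relevant to C1-fed
mixed-culture bioprocesses: ectoine, PHB, lutein, zeaxanthin, astaxanthin,
acetoin, and 2,3-butanediol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Union

import yaml

__all__ = [
    "CatalogError",
    "CatalogSyntaxError",
    "UnknownSymbolError",
    "DuplicateProductError",
    "GeneRequirement",
    "Leaf",
    "AllOf",
    "AnyOf",
    "RequirementExpr",
    "ReactionStep",
    "ProductPathway",
    "PathwayCatalog",
    "evaluate_expr",
    "expr_leaves",
    "pathway_complete",
    "parse_catalog",
    "serialize_catalog",
    "load_catalog",
    "load_default_catalog",
    "DEFAULT_PRODUCTS",
]

KO_PATTERN = re.compile(r"^K\d{5}$")

#: Product names of the packaged default catalog.
DEFAULT_PRODUCTS = (
    "ectoine",
    "PHB",
    "lutein",
    "zeaxanthin",
    "astaxanthin",
    "acetoin",
    "2,3-butanediol",
)

#: Step id of the acetolactate-synthase step (subject to the subunit relaxation).
ALS_STEP_ID = "acetolactate-synthase"
ALS_LARGE_SUBUNIT = "E2.2.1.6L"


class CatalogError(ValueError):
    """Base class for catalog validation failures."""


class CatalogSyntaxError(CatalogError):
    """Document could not be parsed (carries the underlying position info)."""


class UnknownSymbolError(CatalogError):
    """A requirement leaf references a symbol absent from the gene table."""

    def __init__(self, symbol: str, context: str = ""):
        self.symbol = symbol
        where = f" in {context}" if context else ""
        super().__init__(f"unresolved gene symbol {symbol!r}{where}")


class DuplicateProductError(CatalogError):
    pass


@dataclass(frozen=True)
class GeneRequirement:
    """One functional gene: symbol, optional KO id, EC numbers, enzyme name."""

    symbol: str
    ko_id: str = ""
    ec_numbers: tuple[str, ...] = ()
    enzyme_name: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogError("gene symbol must be non-empty")
        if self.ko_id and not KO_PATTERN.match(self.ko_id):
            raise CatalogError(
                f"gene {self.symbol!r}: KO id {self.ko_id!r} does not match K#####"
            )


@dataclass(frozen=True)
class Leaf:
    symbol: str


@dataclass(frozen=True)
class AllOf:
    children: tuple["RequirementExpr", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise CatalogError("'all' node needs at least one child")


@dataclass(frozen=True)
class AnyOf:
    children: tuple["RequirementExpr", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise CatalogError("'any' node needs at least one child")


RequirementExpr = Union[Leaf, AllOf, AnyOf]


def expr_leaves(expr: RequirementExpr) -> Iterator[str]:
    """Yield leaf symbols in document order (duplicates preserved)."""
    if isinstance(expr, Leaf):
        yield expr.symbol
    else:
        for child in expr.children:
            yield from expr_leaves(child)


def evaluate_expr(
    expr: RequirementExpr,
    present: Iterable[str],
    known_symbols: Iterable[str] | None = None,
) -> bool:
    """Evaluate a requirement expression against a set of present symbols.

    A leaf is true iff its symbol is in ``present``; ``all`` nodes are
    conjunctions and ``any`` nodes disjunctions.  When ``known_symbols`` is
    given, a leaf outside it raises :class:`UnknownSymbolError`.
    """
    present = frozenset(present)
    known = None if known_symbols is None else frozenset(known_symbols)

    def _eval(node: RequirementExpr) -> bool:
        if isinstance(node, Leaf):
            if known is not None and node.symbol not in known:
                raise UnknownSymbolError(node.symbol)
            return node.symbol in present
        if isinstance(node, AllOf):
            return all(_eval(c) for c in node.children)
        if isinstance(node, AnyOf):
            return any(_eval(c) for c in node.children)
        raise TypeError(f"not a requirement expression node: {node!r}")

    return _eval(expr)


@dataclass(frozen=True)
class ReactionStep:
    """One enzymatic conversion with its gene requirement expression."""

    step_id: str
    substrate: str
    product: str
    expr: RequirementExpr

    def __post_init__(self) -> None:
        if not self.step_id:
            raise CatalogError("step id must be non-empty")
        if not self.substrate or not self.product:
            raise CatalogError(f"step {self.step_id!r}: substrate/product must be non-empty")


@dataclass(frozen=True)
class ProductPathway:
    """Ordered reaction steps from an entry metabolite to one product."""

    product_name: str
    steps: tuple[ReactionStep, ...]
    entry_metabolite: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise CatalogError(f"product {self.product_name!r} has no steps")
        ids = [s.step_id for s in self.steps]
        if len(set(ids)) != len(ids):
            raise CatalogError(f"product {self.product_name!r} has duplicate step ids")

    @property
    def leaf_symbols(self) -> tuple[str, ...]:
        """All distinct gene symbols referenced by this pathway, in order."""
        seen: dict[str, None] = {}
        for step in self.steps:
            for sym in expr_leaves(step.expr):
                seen.setdefault(sym)
        return tuple(seen)


@dataclass(frozen=True)
class PathwayCatalog:
    products: tuple[ProductPathway, ...]
    gene_index: Mapping[str, GeneRequirement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.product_name for p in self.products]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateProductError(f"duplicate product names: {sorted(dupes)}")
        for pathway in self.products:
            for step in pathway.steps:
                for sym in expr_leaves(step.expr):
                    if sym not in self.gene_index:
                        raise UnknownSymbolError(
                            sym, f"product {pathway.product_name!r}, step {step.step_id!r}"
                        )

    @property
    def product_names(self) -> tuple[str, ...]:
        return tuple(p.product_name for p in self.products)

    def product(self, name: str) -> ProductPathway:
        for p in self.products:
            if p.product_name == name:
                return p
        raise KeyError(f"product {name!r} not in catalog")

    def symbol_to_ko(self) -> dict[str, str]:
        """Gene symbol -> KO id, for genes that have one."""
        return {s: g.ko_id for s, g in self.gene_index.items() if g.ko_id}

    def ko_to_symbols(self) -> dict[str, tuple[str, ...]]:
        """KO id -> gene symbols sharing it.

        Distinct symbols may legitimately share a KO (e.g. the PHB thiolase
        phaA and the mevalonate-route thiolase atoB are the same orthologous
        group), so annotation hits to such a KO credit every mapped symbol.
        """
        rev: dict[str, list[str]] = {}
        for sym in sorted(self.gene_index):
            ko = self.gene_index[sym].ko_id
            if ko:
                rev.setdefault(ko, []).append(sym)
        return {ko: tuple(syms) for ko, syms in rev.items()}

    def with_relaxed_als(self) -> "PathwayCatalog":
        """Relax the acetolactate-synthase step to the large subunit only.

        Catabolic ALS enzymes can be single-subunit; this drops the small
        subunit requirement wherever the ALS step appears.
        """
        new_products = []
        for pathway in self.products:
            steps = tuple(
                replace(s, expr=Leaf(ALS_LARGE_SUBUNIT)) if s.step_id == ALS_STEP_ID else s
                for s in pathway.steps
            )
            new_products.append(replace(pathway, steps=steps))
        return PathwayCatalog(tuple(new_products), dict(self.gene_index))


def pathway_complete(
    pathway: ProductPathway,
    present: Iterable[str],
    known_symbols: Iterable[str] | None = None,
) -> tuple[bool, list[str]]:
    """Return (complete, missing step ids) for a gene complement.

    The pathway is complete iff every step's requirement expression is
    satisfied; ``missing`` lists every step whose expression is false.
    """
    present = frozenset(present)
    missing = [
        step.step_id
        for step in pathway.steps
        if not evaluate_expr(step.expr, present, known_symbols)
    ]
    return (not missing, missing)


# ---------------------------------------------------------------------------
# parsing / serialization


def _parse_requires(node, context: str) -> RequirementExpr:
    if isinstance(node, str):
        if not node:
            raise CatalogError(f"{context}: empty symbol in requirement")
        return Leaf(node)
    if isinstance(node, dict):
        if len(node) != 1:
            raise CatalogError(f"{context}: requirement node must have exactly one key")
        key, children = next(iter(node.items()))
        if key not in ("all", "any"):
            raise CatalogError(f"{context}: unknown requirement operator {key!r}")
        if not isinstance(children, list) or not children:
            raise CatalogError(f"{context}: {key!r} needs a non-empty list")
        parsed = tuple(_parse_requires(c, context) for c in children)
        return AllOf(parsed) if key == "all" else AnyOf(parsed)
    raise CatalogError(f"{context}: requirement must be a symbol or all/any mapping")


def parse_catalog(text: str) -> PathwayCatalog:
    """Parse a catalog document (YAML schema) into a validated catalog.

    Schema::

        genes:
          - {symbol: lysC, ko: K00928, ec: ["2.7.2.4"], name: aspartate kinase}
        products:
          - name: ectoine
            entry_metabolite: L-aspartate
            steps:
              - {id: s1, substrate: A, product: B, requires: lysC}
              - {id: s2, substrate: B, product: C,
                 requires: {all: [x, {any: [y, z]}]}}
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # YAML errors carry line/column marks
        raise CatalogSyntaxError(f"catalog syntax error: {exc}") from exc
    if not isinstance(doc, dict):
        raise CatalogSyntaxError("catalog document must be a mapping")

    gene_index: dict[str, GeneRequirement] = {}
    for entry in doc.get("genes", []) or []:
        if not isinstance(entry, dict) or "symbol" not in entry:
            raise CatalogError(f"gene entry must be a mapping with 'symbol': {entry!r}")
        gene = GeneRequirement(
            symbol=str(entry["symbol"]),
            ko_id=str(entry.get("ko", "") or ""),
            ec_numbers=tuple(str(e) for e in entry.get("ec", []) or []),
            enzyme_name=str(entry.get("name", "") or ""),
        )
        if gene.symbol in gene_index:
            raise CatalogError(f"duplicate gene symbol {gene.symbol!r}")
        gene_index[gene.symbol] = gene

    products = []
    for pentry in doc.get("products", []) or []:
        if not isinstance(pentry, dict) or "name" not in pentry:
            raise CatalogError(f"product entry must be a mapping with 'name': {pentry!r}")
        name = str(pentry["name"])
        steps = []
        for sentry in pentry.get("steps", []) or []:
            context = f"product {name!r}, step {sentry.get('id')!r}"
            steps.append(
                ReactionStep(
                    step_id=str(sentry.get("id", "")),
                    substrate=str(sentry.get("substrate", "")),
                    product=str(sentry.get("product", "")),
                    expr=_parse_requires(sentry.get("requires"), context),
                )
            )
        products.append(
            ProductPathway(
                product_name=name,
                steps=tuple(steps),
                entry_metabolite=str(pentry.get("entry_metabolite", "")),
                notes=str(pentry.get("notes", "") or ""),
            )
        )

    return PathwayCatalog(tuple(products), gene_index)


def _requires_to_obj(expr: RequirementExpr):
    if isinstance(expr, Leaf):
        return expr.symbol
    key = "all" if isinstance(expr, AllOf) else "any"
    return {key: [_requires_to_obj(c) for c in expr.children]}


def serialize_catalog(catalog: PathwayCatalog) -> str:
    """Serialize a catalog to its document form (inverse of parse_catalog)."""
    doc = {
        "genes": [
            {
                "symbol": g.symbol,
                "ko": g.ko_id,
                "ec": list(g.ec_numbers),
                "name": g.enzyme_name,
            }
            for g in catalog.gene_index.values()
        ],
        "products": [
            {
                "name": p.product_name,
                "entry_metabolite": p.entry_metabolite,
                "notes": p.notes,
                "steps": [
                    {
                        "id": s.step_id,
                        "substrate": s.substrate,
                        "product": s.product,
                        "requires": _requires_to_obj(s.expr),
                    }
                    for s in p.steps
                ],
            }
            for p in catalog.products
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def load_catalog(path) -> PathwayCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_catalog(fh.read())


def load_default_catalog(als_large_subunit_only: bool = False) -> PathwayCatalog:
    """Load the packaged seven-product catalog.

    ``als_large_subunit_only=True`` relaxes the acetolactate-synthase step
    (acetoin / 2,3-butanediol) to require only the large subunit.
    """
    text = resources.files("genescreen.data").joinpath("catalog.yaml").read_text("utf-8")
    catalog = parse_catalog(text)
    return catalog.with_relaxed_als() if als_large_subunit_only else catalog
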