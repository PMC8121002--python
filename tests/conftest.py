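import pytest
from hypothesis import HealthCheck, settings

from genescreen.catalog import load_default_catalog
from genescreen.community import join_community, read_ko_table, read_taxonomy_table
from genescreen.simulate import paper_like_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def fixture_bundle():
    return paper_like_fixture()


@pytest.fixture(scope="session")
def fixture_community(catalog, fixture_bundle):
    anns = read_ko_table(fixture_bundle.annotation_tsv)
    assigns = read_taxonomy_table(fixture_bundle.taxonomy_tsv)
    return join_community(anns, assigns, catalog.ko_to_symbols())


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_bundle):
    """The worked-example community written out as input files."""
    d = tmp_path_factory.mktemp("fixture")
    (d / "annotations.tsv").write_text(fixture_bundle.annotation_tsv)
    (d / "taxonomy.tsv").write_text(fixture_bundle.taxonomy_tsv)
    return d


@pytest.fixture(scope="session")
def make_community(catalog):
    """Build a small AnnotatedCommunity from per-taxon symbol counts.

    ``taxa`` maps a taxon name to (lineage tuple, {symbol: count});
    ``unclassified`` gives symbol counts on contigs without taxonomy.
    """
    sym2ko = catalog.symbol_to_ko()

    def _build(taxa=None, unclassified=None, ko_to_symbols=None):
        ann_lines, tax_lines, weights = [], [], {}
        for t, (_, (lineage, counts)) in enumerate((taxa or {}).items()):
            contig = f"c{t}"
            tax_lines.append(f"{contig}\tT{t}\t{';'.join(lineage)}")
            for g, sym in enumerate(sorted(counts), start=1):
                gene_id = f"{contig}_{g}"
                ann_lines.append(f"{gene_id}\t{sym2ko[sym]}")
                weights[gene_id] = counts[sym]
            if not counts:  # keep the taxon visible via one unannotated gene
                ann_lines.append(f"{contig}_1\t")
        for g, sym in enumerate(sorted(unclassified or {}), start=1):
            gene_id = f"u0_{g}"
            ann_lines.append(f"{gene_id}\t{sym2ko[sym]}")
            weights[gene_id] = unclassified[sym]
        anns = read_ko_table("\n".join(ann_lines) + "\n")
        assigns = read_taxonomy_table("\n".join(tax_lines) + "\n" if tax_lines else "c9\tT9\tBacteria")
        return join_community(
            anns,
            assigns,
            ko_to_symbols if ko_to_symbols is not None else catalog.ko_to_symbols(),
            weights=weights,
        )

    return _build
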