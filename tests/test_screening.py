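"""Producer classification, hit profiles, ratios, and abundances."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from genescreen.community import join_community, read_ko_table, read_taxonomy_table
from genescreen.screening import (
    Classification,
    hit_profile,
    pairwise_ratio,
    rate_limiting_ratio,
    relative_abundance,
    round_ratio,
    screen_community,
)
from genescreen.simulate import generate, random_design

LINEAGE = ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales",
           "Methyloligellaceae", "Methyloceanibacter", "Methyloceanibacter caenitepidi")


class TestClassification:
    def test_species_with_full_phb_set_is_case_one(self, make_community):
        com = make_community({"m": (LINEAGE, {"phaA": 2, "phaB": 1, "phaC": 3})})
        screen = screen_community_by(com)["PHB"]
        assert screen.classification is Classification.SINGLE_MICROBE
        assert [p.name for p in screen.single_producers] == [LINEAGE[-1]]
        assert screen.single_producers[0].lineage == LINEAGE

    def test_ectoine_split_across_taxa_is_case_two(self, make_community):
        lin2 = ("Bacteria",) * 6 + ("Other sp.",)
        com = make_community({
            "a": (LINEAGE, {"lysC": 5, "asd": 2, "ectB": 1}),
            "b": (lin2, {"ectA": 1, "ectC": 2}),
        })
        screen = screen_community_by(com)["ectoine"]
        assert screen.classification is Classification.MIXED_COMMUNITY
        assert screen.community_complete and not screen.single_producers

    def test_absent_pathway_is_case_three(self, make_community):
        com = make_community({"m": (LINEAGE, {"phaA": 1})})
        screen = screen_community_by(com)["lutein"]
        assert screen.classification is Classification.NONE
        assert screen.missing_steps

    def test_unclassified_genes_complete_community_but_no_taxon(self, make_community):
        com = make_community(
            {"m": (LINEAGE, {"phaA": 1, "phaB": 1})}, unclassified={"phaC": 4}
        )
        screen = screen_community_by(com)["PHB"]
        assert screen.classification is Classification.MIXED_COMMUNITY

    def test_removing_a_required_gene_demotes_the_producer(self, make_community):
        with_c = make_community({"m": (LINEAGE, {"phaA": 1, "phaB": 1, "phaC": 1})})
        without_c = make_community({"m": (LINEAGE, {"phaA": 1, "phaB": 1})})
        assert screen_community_by(with_c)["PHB"].classification is Classification.SINGLE_MICROBE
        assert screen_community_by(without_c)["PHB"].classification is Classification.NONE

    def test_empty_community_warns_and_reports_all_none(self, catalog, make_community):
        com = make_community({"m": (LINEAGE, {})}, ko_to_symbols={})
        with pytest.warns(UserWarning, match="no annotated genes"):
            result = screen_community(catalog, com)
        assert all(
            s.classification is Classification.NONE for s in result.products.values()
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_invariants_on_random_communities(self, catalog, seed):
        """Exactly one case per product; Case I implies community-complete;
        every listed producer's own complement completes the pathway."""
        bundle = generate(random_design(seed, catalog), catalog)
        com = join_community(
            read_ko_table(bundle.annotation_tsv),
            read_taxonomy_table(bundle.taxonomy_tsv),
            catalog.ko_to_symbols(),
        )
        result = screen_community(catalog, com)
        for name, screen in result.products.items():
            if screen.classification is Classification.SINGLE_MICROBE:
                assert screen.community_complete and screen.single_producers
            elif screen.classification is Classification.MIXED_COMMUNITY:
                assert screen.community_complete and not screen.single_producers
            else:
                assert not screen.community_complete and screen.missing_steps
            # union property: any single producer's complement is a subset of
            # the pooled complement, so Case I forces community completeness
            for producer in screen.single_producers:
                assert com.complement(producer.name, "species") <= com.complement()


def screen_community_by(com):
    from genescreen.catalog import load_default_catalog

    return screen_community(load_default_catalog(), com).products


class TestHitProfile:
    def test_ectoine_extremes_from_worked_example(self, catalog, fixture_community):
        profile = hit_profile(catalog, fixture_community, "ectoine")
        assert (profile.min_gene, profile.min_count) == ("ectA", 177)
        assert (profile.max_gene, profile.max_count) == ("lysC", 12563)

    def test_per_step_counts_sum_gene_counts(self, catalog, make_community):
        com = make_community({"m": (LINEAGE, {"E2.2.1.6L": 3, "ilvM": 2, "alsD": 4})})
        profile = hit_profile(catalog, com, "acetoin")
        assert profile.per_step["acetolactate-synthase"] == 5  # large + small subunits
        assert profile.per_step["acetoin-formation"] == 4

    def test_uniform_counts_tie_break_lexicographically(self, catalog, make_community):
        com = make_community({"m": (LINEAGE, {"phaA": 5, "phaB": 5, "phaC": 5})})
        profile = hit_profile(catalog, com, "PHB")
        assert profile.min_gene == profile.max_gene == "phaA"
        assert profile.min_count == profile.max_count == 5

    def test_unknown_product_raises(self, catalog, fixture_community):
        with pytest.raises(KeyError):
            hit_profile(catalog, fixture_community, "unobtainium")

    @given(st.lists(st.integers(1, 10_000), min_size=3, max_size=3))
    def test_extremes_match_exhaustive_scan(self, catalog, make_community, counts):
        genes = ["phaA", "phaB", "phaC"]
        table = dict(zip(genes, counts))
        profile = hit_profile(catalog, make_community({"m": (LINEAGE, table)}), "PHB")
        assert profile.min_count == min(table.values())
        assert profile.max_count == max(table.values())


class TestRatios:
    def test_printed_rate_limiting_ratio(self, catalog, fixture_community):
        summary = rate_limiting_ratio(hit_profile(catalog, fixture_community, "ectoine"))
        assert summary.defined
        assert summary.ratio == 0.014  # 177 / 12,563
        assert (summary.min_gene, summary.max_gene) == ("ectA", "lysC")

    def test_printed_pairwise_ratios(self, catalog, fixture_community):
        profile = hit_profile(catalog, fixture_community, "PHB")
        assert pairwise_ratio(profile, "phaA", "phaC") == 0.175
        assert pairwise_ratio(profile, "phaB", "phaC") == 0.171

    def test_self_ratio_is_one(self, catalog, fixture_community):
        profile = hit_profile(catalog, fixture_community, "PHB")
        assert pairwise_ratio(profile, "phaC", "phaC") == 1.0

    def test_equal_counts_give_ratio_one(self, catalog, make_community):
        com = make_community({"m": (LINEAGE, {"phaA": 6, "phaB": 6, "phaC": 6})})
        assert rate_limiting_ratio(hit_profile(catalog, com, "PHB")).ratio == 1.0

    def test_missing_required_gene_makes_ratio_undefined(self, catalog, fixture_community):
        summary = rate_limiting_ratio(hit_profile(catalog, fixture_community, "lutein"))
        assert not summary.defined and summary.ratio is None

    def test_zero_hit_alternative_route_does_not_undefine(self, catalog, fixture_community):
        # the mevalonate-route genes have zero hits, but the MEP route covers
        # the backbone, so the zeaxanthin ratio is a rate statement, not absence
        summary = rate_limiting_ratio(hit_profile(catalog, fixture_community, "zeaxanthin"))
        assert summary.defined

    @given(st.lists(st.integers(1, 5000), min_size=3, max_size=3),
           st.integers(2, 50))
    def test_scale_invariance_and_bounds(self, catalog, make_community, counts, factor):
        genes = ["phaA", "phaB", "phaC"]
        base = make_community({"m": (LINEAGE, dict(zip(genes, counts)))})
        scaled = make_community({"m": (LINEAGE, dict(zip(genes, [c * factor for c in counts])))})
        r1 = rate_limiting_ratio(hit_profile(catalog, base, "PHB"), rounding=9)
        r2 = rate_limiting_ratio(hit_profile(catalog, scaled, "PHB"), rounding=9)
        assert r1.ratio == r2.ratio
        assert 0 < r1.ratio <= 1
        assert (r1.ratio == 1.0) == (len(set(counts)) == 1)

    @given(st.integers(1, 10**6), st.integers(1, 10**6))
    def test_rounding_matches_exact_rational_arithmetic(self, a, b):
        num, den = min(a, b), max(a, b)
        got = round_ratio(num, den, places=12)
        assert abs(got - float(Fraction(num, den))) < 1e-12


class TestAbundance:
    def test_printed_abundance_ratio(self, make_community):
        # two species at 1.2% and 0.9% of 1,000 records: ratio 1.3 at one decimal
        lin2 = ("Bacteria",) * 6 + ("Rhodopseudomonas palustris",)
        com = make_community(
            {"a": (LINEAGE, {"phaA": 12}), "b": (lin2, {"phaA": 9})},
            unclassified={"lysC": 979},
        )
        table = relative_abundance(com, "species", top_n=5)
        fr = table.fractions()
        assert fr[LINEAGE[-1]] == pytest.approx(0.012)
        assert fr["Rhodopseudomonas palustris"] == pytest.approx(0.009)
        assert round_ratio(12, 9, 1) == 1.3

    def test_single_taxon_community(self, make_community):
        com = make_community({"a": (LINEAGE, {"phaA": 4})})
        (row,) = relative_abundance(com, "species", top_n=5).rows
        assert row.name == LINEAGE[-1] and row.fraction == 1.0

    def test_fractions_sum_to_one_with_truncation(self, catalog):
        bundle = generate(random_design(11, catalog), catalog)
        com = join_community(
            read_ko_table(bundle.annotation_tsv),
            read_taxonomy_table(bundle.taxonomy_tsv),
            catalog.ko_to_symbols(),
        )
        table = relative_abundance(com, "species", top_n=2)
        assert sum(r.fraction for r in table.rows) == pytest.approx(1.0, abs=1e-9)

    def test_fixture_fractions_match_manifest(self, fixture_community, fixture_bundle):
        table = relative_abundance(fixture_community, "species", top_n=50)
        expected = fixture_bundle.manifest["abundance"]["species"]
        got = {r.name: r.fraction for r in table.rows if r.kind == "taxon"}
        assert got == pytest.approx(expected)
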