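"""The three-filter cascade and the combination of the two approaches."""

import pandas as pd
import pytest

from testisscreen.expression import AbsoluteLevel, ClassificationRule
from testisscreen.filters import (
    combine_approaches,
    filter_by_absolute,
    filter_by_phenotype,
    filter_by_relative,
    run_approach1,
    run_approach2,
)
from testisscreen.gene_sets import gene_set
from testisscreen.tables import (
    ExpressionTable,
    OrthologTable,
    PhenotypeTable,
)


@pytest.fixture
def tiny_expression():
    # levels: g1 exclusive (testis only), g2 ubiquitous (head higher),
    # g3 predominant at moderately_high, g4 predominant but below cutoff
    df = pd.DataFrame(
        {
            "testis": [5, 3, 4, 3],
            "accessory_gland": [2, 0, 0, 0],
            "imaginal_disc": [0, 0, 0, 0],
            "head": [0, 5, 2, 1],
            "gut": [0, 1, 1, 1],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionTable(species="fly", values=df, dialect="ordinal")


@pytest.fixture
def tiny_phenotypes():
    return PhenotypeTable(
        outcomes={"g1": "sterile", "g2": "fertile", "g4": "sterile"}
    )


class TestPhenotypeFilter:
    def test_example(self, tiny_phenotypes):
        genes = gene_set({"g1", "g2", "g3"}, "fly")
        out = filter_by_phenotype(genes, tiny_phenotypes)
        assert out.members == {"g1"}
        assert out.provenance[-1].params["n_unknown"] == 1

    def test_empty_keep_set(self, tiny_phenotypes):
        genes = gene_set({"g1", "g2"}, "fly")
        assert len(filter_by_phenotype(genes, tiny_phenotypes, keep=set())) == 0


class TestRelativeFilter:
    def test_keeps_exclusive_and_predominant(self, tiny_expression, rule):
        genes = gene_set({"g1", "g2", "g3", "g4"}, "fly")
        out = filter_by_relative(genes, tiny_expression, rule)
        assert out.members == {"g1", "g3", "g4"}

    def test_keep_sets_partition(self, tiny_expression, rule):
        from testisscreen.expression import RelativeCategory

        genes = gene_set({"g1", "g2", "g3", "g4"}, "fly")
        both = filter_by_relative(genes, tiny_expression, rule)
        excl = filter_by_relative(
            genes, tiny_expression, rule, keep=[RelativeCategory.EXCLUSIVE]
        )
        pred = filter_by_relative(
            genes, tiny_expression, rule, keep=[RelativeCategory.PREDOMINANT]
        )
        assert excl.members | pred.members == both.members
        assert not excl.members & pred.members

    def test_missing_gene_excluded_not_fatal(self, tiny_expression, rule):
        genes = gene_set({"g1", "ghost"}, "fly")
        out = filter_by_relative(genes, tiny_expression, rule)
        assert out.members == {"g1"}
        assert out.provenance[-1].params["n_missing"] == 1


class TestAbsoluteFilter:
    def test_cutoff(self, tiny_expression):
        genes = gene_set({"g1", "g3", "g4"}, "fly")
        out = filter_by_absolute(genes, tiny_expression)
        assert out.members == {"g1", "g3"}  # g4 is moderate

    def test_min_level_none_is_identity(self, tiny_expression):
        genes = gene_set({"g1", "g2", "g3", "g4"}, "fly")
        out = filter_by_absolute(
            genes, tiny_expression, min_level=AbsoluteLevel.NONE
        )
        assert out.members == genes.members

    def test_numeric_table_rejected(self, small_bundle):
        genes = gene_set({"Mm00000"}, "mouse")
        with pytest.raises(ValueError, match="ordinal"):
            filter_by_absolute(genes, small_bundle.source_expression)


class TestFilterAlgebra:
    def test_contractive_and_idempotent(
        self, tiny_expression, tiny_phenotypes, rule
    ):
        genes = gene_set({"g1", "g2", "g3", "g4"}, "fly")
        for apply_filter in (
            lambda gs: filter_by_phenotype(gs, tiny_phenotypes),
            lambda gs: filter_by_relative(gs, tiny_expression, rule),
            lambda gs: filter_by_absolute(gs, tiny_expression),
        ):
            once = apply_filter(genes)
            assert once.members <= genes.members
            assert apply_filter(once).members == once.members

    def test_filters_2_and_3_commute(self, tiny_expression, rule):
        genes = gene_set({"g1", "g2", "g3", "g4"}, "fly")
        f23 = filter_by_absolute(
            filter_by_relative(genes, tiny_expression, rule), tiny_expression
        )
        f32 = filter_by_relative(
            filter_by_absolute(genes, tiny_expression), tiny_expression, rule
        )
        assert f23.members == f32.members


class TestCombination:
    def test_inclusion_exclusion(self):
        a = gene_set({"n1", "n2", "n3"}, "nasonia", label="a")
        b = gene_set({"n3", "n4"}, "nasonia", label="b")
        combo = combine_approaches(a, b)
        assert combo.overlap.members == {"n3"}
        assert len(combo.union) == len(a) + len(b) - len(combo.overlap)

    def test_disjoint_sets(self):
        a = gene_set({"n1"}, "nasonia")
        b = gene_set({"n2"}, "nasonia")
        combo = combine_approaches(a, b)
        assert len(combo.union) == 2 and len(combo.overlap) == 0

    def test_subset_gives_superset_union(self):
        a = gene_set({"n1"}, "nasonia")
        b = gene_set({"n1", "n2"}, "nasonia")
        assert combine_approaches(a, b).union.members == b.members

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="species"):
            combine_approaches(
                gene_set({"n1"}, "nasonia"), gene_set({"f1"}, "fly")
            )


class TestApproaches:
    def test_cascade_matches_manifest(self, small_bundle):
        m = small_bundle.manifest
        cascade = run_approach1(
            small_bundle.source_expression,
            small_bundle.source_to_intermediate,
            small_bundle.intermediate_expression,
            small_bundle.phenotypes,
            small_bundle.target_tables,
        )
        assert cascade.source_screened.members == set(
            m.expected_sets["source_screen"]
        )
        assert cascade.initial.members == set(m.expected_sets["initial"])
        assert cascade.after_phenotype.members == set(
            m.expected_sets["filter1"]
        )
        assert cascade.after_relative.members == set(
            m.expected_sets["filter2"]
        )
        assert cascade.after_relative_and_absolute.members == set(
            m.expected_sets["filter23"]
        )
        summary = cascade.summary()
        for key in (
            "n_source_screened", "n_sources_with_ortholog", "n_initial",
            "n_filter1", "n_filter2", "n_filter23",
            "presence_initial_in_all", "presence_initial_in_none",
        ):
            assert summary[key] == m.expected_counts[key], key

    def test_phenotype_branch_is_parallel(self, small_bundle):
        cascade = run_approach1(
            small_bundle.source_expression,
            small_bundle.source_to_intermediate,
            small_bundle.intermediate_expression,
            small_bundle.phenotypes,
            small_bundle.target_tables,
        )
        # filter 1 descends from the initial ortholog set, not from filter 2:
        # it equals sterile ∩ initial even for genes failing filter 2
        sterile = {
            g
            for g in cascade.initial.members
            if small_bundle.phenotypes.outcome(g) == "sterile"
        }
        assert cascade.after_phenotype.members == sterile

    def test_empty_source_list_gives_empty_cascade(self, small_bundle):
        empty = ExpressionTable(
            species="mouse",
            values=small_bundle.source_expression.values.iloc[:0],
            dialect="numeric",
        )
        cascade = run_approach1(
            empty,
            small_bundle.source_to_intermediate,
            small_bundle.intermediate_expression,
            small_bundle.phenotypes,
            small_bundle.target_tables,
        )
        assert len(cascade.initial) == 0
        assert len(cascade.after_relative_and_absolute) == 0
        assert cascade.presence_initial.total == 0

    def test_approach2_matches_manifest(self, small_bundle):
        m = small_bundle.manifest
        result = run_approach2(
            small_bundle.curated, small_bundle.target_tables
        )
        assert result.presence.in_all == m.expected_counts["approach2_in_all"]
        assert (
            result.presence.in_none == m.expected_counts["approach2_in_none"]
        )
        focal = small_bundle.config.focal_target
        assert result.per_species_orthologs[focal].members == set(
            m.expected_sets["set_b"]
        )

    def test_single_species_degenerates_to_sources_with_ortholog(
        self, small_bundle
    ):
        from testisscreen.orthology import sources_with_ortholog

        focal = small_bundle.config.focal_target
        table = small_bundle.target_tables[focal]
        result = run_approach2(small_bundle.curated, {focal: table})
        direct = sources_with_ortholog(small_bundle.curated, table)
        assert result.presence.in_all == len(direct)
        assert result.presence.in_none == len(small_bundle.curated) - len(
            direct
        )
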