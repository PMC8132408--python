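"""Absolute-level binning and relative-category classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from testisscreen.expression import (
    AbsoluteLevel,
    ClassificationRule,
    RelativeCategory,
    bin_absolute,
    classify_relative,
    classify_relative_numeric,
    classify_table,
    meets_absolute_cutoff,
    octile_cutpoints,
    parse_level,
    screen_source_species,
)
from testisscreen.tables import ExpressionTable

THRESHOLDS = [1, 5, 20, 50, 100, 200, 400]


class TestBinAbsolute:
    def test_zero_is_none(self):
        assert bin_absolute(0, THRESHOLDS) == AbsoluteLevel.NONE

    def test_above_top_is_extremely_high(self):
        assert bin_absolute(1e6, THRESHOLDS) == AbsoluteLevel.EXTREMELY_HIGH

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bin_absolute(-1, THRESHOLDS)

    @pytest.mark.parametrize("bad", [[1, 2], [1, 2, 3, 4, 5, 6, 6]])
    def test_bad_cutpoints_rejected(self, bad):
        with pytest.raises(ValueError):
            bin_absolute(1, bad)

    @settings(deadline=None, max_examples=200)
    @given(
        a=st.floats(min_value=0, max_value=500),
        b=st.floats(min_value=0, max_value=500),
    )
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert bin_absolute(lo, THRESHOLDS) <= bin_absolute(hi, THRESHOLDS)


def _oracle_two_tissue(testis: int, head: int) -> RelativeCategory:
    """Independent restatement of the rule for a {testis, head} profile."""
    if testis == 0:
        return RelativeCategory.NOT_EXPRESSED
    # head is the single non-tolerated other tissue
    if head < int(AbsoluteLevel.MODERATELY_HIGH):  # none or below the bound
        return RelativeCategory.EXCLUSIVE
    if testis > head:
        return RelativeCategory.PREDOMINANT
    return RelativeCategory.UBIQUITOUS


class TestClassifyRelative:
    def test_all_two_tissue_level_pairs(self, rule):
        for t in range(8):
            for h in range(8):
                profile = {
                    "testis": AbsoluteLevel(t),
                    "head": AbsoluteLevel(h),
                }
                assert classify_relative(profile, rule) == _oracle_two_tissue(
                    t, h
                ), (t, h)

    def test_exclusive_when_silent_elsewhere(self, rule):
        profile = {
            "testis": AbsoluteLevel.HIGH,
            "head": AbsoluteLevel.NONE,
            "gut": AbsoluteLevel.NONE,
        }
        assert classify_relative(profile, rule) == RelativeCategory.EXCLUSIVE

    def test_tie_is_ubiquitous(self, rule):
        profile = {
            "testis": AbsoluteLevel.HIGH,
            "head": AbsoluteLevel.HIGH,
            "gut": AbsoluteLevel.LOW,
        }
        assert classify_relative(profile, rule) == RelativeCategory.UBIQUITOUS

    def test_focal_below_other_is_ubiquitous(self, rule):
        profile = {
            "testis": AbsoluteLevel.MODERATE,
            "head": AbsoluteLevel.HIGH,
            "gut": AbsoluteLevel.LOW,
        }
        assert classify_relative(profile, rule) == RelativeCategory.UBIQUITOUS

    def test_tolerated_tissues_ignored_for_exclusivity(self, rule):
        profile = {
            "testis": AbsoluteLevel.LOW,
            "accessory_gland": AbsoluteLevel.EXTREMELY_HIGH,
            "imaginal_disc": AbsoluteLevel.HIGH,
            "head": AbsoluteLevel.NONE,
        }
        assert classify_relative(profile, rule) == RelativeCategory.EXCLUSIVE

    def test_two_expressed_side_tissues_break_exclusivity(self, rule):
        profile = {
            "testis": AbsoluteLevel.HIGH,
            "head": AbsoluteLevel.LOW,
            "gut": AbsoluteLevel.VERY_LOW,
        }
        assert classify_relative(profile, rule) == RelativeCategory.PREDOMINANT

    def test_missing_focal_tissue_errors(self, rule):
        with pytest.raises(ValueError, match="testis"):
            classify_relative({"head": AbsoluteLevel.LOW}, rule)

    def test_focal_in_tolerated_rejected(self):
        with pytest.raises(ValueError):
            ClassificationRule(
                focal_tissue="testis", tolerated_tissues=frozenset({"testis"})
            )

    @settings(deadline=None, max_examples=300)
    @given(
        levels=st.lists(
            st.integers(min_value=0, max_value=7), min_size=4, max_size=4
        )
    )
    def test_categories_exhaustive_and_exclusive(self, rule, levels):
        tissues = ["testis", "accessory_gland", "head", "gut"]
        profile = {
            t: AbsoluteLevel(l) for t, l in zip(tissues, levels)
        }
        cat = classify_relative(profile, rule)
        assert cat in RelativeCategory
        if cat == RelativeCategory.PREDOMINANT:
            others = [v for t, v in profile.items() if t != "testis"]
            assert all(profile["testis"] > v for v in others)
        if cat == RelativeCategory.NOT_EXPRESSED:
            assert profile["testis"] == AbsoluteLevel.NONE


class TestNumericClassification:
    def test_examples(self, rule):
        src_rule = ClassificationRule(tolerated_tissues=frozenset())
        f = lambda p: classify_relative_numeric(p, src_rule, side_threshold=50)
        assert (
            f({"testis": 10, "liver": 0, "brain": 0})
            == RelativeCategory.EXCLUSIVE
        )
        assert (
            f({"testis": 5, "liver": 9, "brain": 2})
            == RelativeCategory.UBIQUITOUS
        )
        assert (
            f({"testis": 50, "liver": 9, "brain": 2})
            == RelativeCategory.PREDOMINANT
        )
        assert (
            f({"testis": 0, "liver": 9, "brain": 2})
            == RelativeCategory.NOT_EXPRESSED
        )

    def test_octile_cutpoints_strictly_increasing(self):
        rng = np.random.default_rng(0)
        cut = octile_cutpoints(rng.integers(0, 100, size=1000).astype(float))
        assert np.all(np.diff(cut) > 0)
        cut_tied = octile_cutpoints(np.array([5.0] * 50))
        assert np.all(np.diff(cut_tied) > 0)


class TestScreenSourceSpecies:
    def test_recovers_planted_testis_genes_exactly(self, small_bundle):
        rule = ClassificationRule(tolerated_tissues=frozenset())
        screened = screen_source_species(
            small_bundle.source_expression, rule
        )
        assert screened.members == frozenset(
            small_bundle.manifest.planted_testis_specific
        )

    def test_partition_totals(self, small_bundle):
        rule = ClassificationRule(tolerated_tissues=frozenset())
        cats = classify_table(small_bundle.source_expression, rule)
        assert len(cats) == len(small_bundle.source_expression.values)
        assert set(cats.unique()) <= {c.value for c in RelativeCategory}

    def test_empty_table_returns_empty_set(self):
        table = ExpressionTable(
            species="mouse",
            values=pd.DataFrame(columns=["testis", "liver"], dtype=float),
            dialect="numeric",
        )
        rule = ClassificationRule(tolerated_tissues=frozenset())
        assert len(screen_source_species(table, rule)) == 0

    def test_ordinal_table_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="numeric"):
            screen_source_species(
                small_bundle.intermediate_expression, ClassificationRule()
            )


class TestAbsoluteCutoff:
    def test_boundary_inclusive(self):
        profile = {"testis": AbsoluteLevel.MODERATELY_HIGH}
        assert meets_absolute_cutoff(profile, AbsoluteLevel.MODERATELY_HIGH)
        profile = {"testis": AbsoluteLevel.MODERATE}
        assert not meets_absolute_cutoff(
            profile, AbsoluteLevel.MODERATELY_HIGH
        )

    def test_raising_min_level_shrinks_set(self, small_bundle):
        table = small_bundle.intermediate_expression
        passing = []
        for level in AbsoluteLevel:
            kept = {
                g
                for g in table.values.index
                if meets_absolute_cutoff(table.profile(g), level)
            }
            passing.append(kept)
        for lo, hi in zip(passing, passing[1:]):
            assert hi <= lo


def test_parse_level_accepts_spec_strings():
    assert parse_level("moderately high") == AbsoluteLevel.MODERATELY_HIGH
    assert parse_level("Extremely_High") == AbsoluteLevel.EXTREMELY_HIGH
    with pytest.raises(ValueError, match="accepted"):
        parse_level("sort of high")
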