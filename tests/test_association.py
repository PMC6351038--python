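"""Carriership tables, Fisher exact test, Woolf odds-ratio CI."""

import math

import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from mitosyn import (
    Carrier,
    Feature,
    TwoByTwoTable,
    associate,
    build_2x2,
    carrier_status,
    cohort_from_string,
    fisher_two_sided,
    odds_ratio_woolf,
    stratify_by_sex,
    study_feature,
)
from mitosyn.errors import DegenerateTableError, FeatureError
from conftest import make_tsv
from oracles import fisher_two_sided_oracle


def _subject(genotype, loci=("rs2107538",)):
    text = make_tsv([f"S1\tcase\tF\tG\tT\tG\tG\tA\t{genotype}"], loci=loci)
    return cohort_from_string(text).subjects[0]


class TestCarrierStatus:
    def test_heterozygote_carries_allele(self):
        s = _subject("A/G")
        assert carrier_status(s, Feature.allele("rs2107538", "A")) is Carrier.CARRIER

    def test_genotype_feature_needs_exact_match(self):
        s = _subject("A/G", loci=("rs1640923",))
        f = Feature.genotype("rs1640923", "A", "A")
        assert carrier_status(s, f) is Carrier.NONCARRIER
        assert carrier_status(_subject("A/A", loci=("rs1640923",)), f) is Carrier.CARRIER

    def test_unknown_haplogroup_is_missing(self):
        text = make_tsv(["S1\tcase\tF\tG\t.\tG\tG\tA"])
        s = cohort_from_string(text).subjects[0]
        assert carrier_status(s, Feature.haplogroup("J")) is Carrier.MISSING

    def test_unregistered_locus_errors(self):
        with pytest.raises(FeatureError):
            carrier_status(_subject("A/G"), Feature.allele("rs999", "A"))


class TestBuild2x2:
    def test_haplogroup_j_counts(self, ccl5_cohort, feature_j):
        t = build_2x2(ccl5_cohort, feature_j)
        assert (t.a, t.b, t.c, t.d) == (45, 238, 25, 265)

    def test_pvt1_carriage_counts(self, pvt1_cohort):
        t = build_2x2(pvt1_cohort, study_feature("pvt1"))
        assert (t.a, t.b, t.c, t.d) == (169, 114, 170, 120)

    def test_all_missing_column_degenerate(self):
        text = make_tsv(
            ["S1\tcase\tF\tG\tC\tG\tA\tA\t.", "S2\tcontrol\tF\tG\tC\tG\tA\tA\t."],
            loci=["rs1"],
        )
        cohort = cohort_from_string(text)
        with pytest.raises(DegenerateTableError):
            build_2x2(cohort, Feature.allele("rs1", "A"))


class TestFisher:
    def test_balanced_small_table_is_one(self):
        # enumeration over a=0..3: point probs 0.05, 0.45, 0.45, 0.05
        assert fisher_two_sided(TwoByTwoTable(2, 1, 1, 2)) == pytest.approx(1.0)

    def test_perfect_separation(self):
        # only the two extreme tables have probability <= 1/252
        p = fisher_two_sided(TwoByTwoTable(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-10)

    def test_modal_symmetric_table_is_one(self):
        assert fisher_two_sided(TwoByTwoTable(10, 10, 10, 10)) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=200)
    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    def test_matches_exact_enumeration_oracle(self, a, b, c, d):
        """Agreement with full-rational enumeration on all tables N <= 60."""
        if a + b == 0 or c + d == 0 or a + c + b + d == 0 or (a + c == 0 and b + d == 0):
            return
        if a + c == 0 or b + d == 0:
            return  # degenerate carrier margin: conditional dist is a point
        t = TwoByTwoTable(a, b, c, d)
        expected = float(fisher_two_sided_oracle(a, b, c, d))
        assert fisher_two_sided(t) == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.integers(1, 12),
        b=st.integers(1, 12),
        c=st.integers(1, 12),
        d=st.integers(1, 12),
    )
    def test_agrees_with_scipy(self, a, b, c, d):
        """Independent cross-check against scipy's two-sided Fisher test."""
        t = TwoByTwoTable(a, b, c, d)
        expected = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert fisher_two_sided(t) == pytest.approx(expected, rel=1e-6)

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.integers(1, 12),
        b=st.integers(1, 12),
        c=st.integers(1, 12),
        d=st.integers(1, 12),
    )
    def test_symmetry_under_row_and_column_swaps(self, a, b, c, d):
        t = TwoByTwoTable(a, b, c, d)
        p = fisher_two_sided(t)
        assert fisher_two_sided(t.swapped_columns()) == pytest.approx(p, rel=1e-9)
        assert fisher_two_sided(t.swapped_rows()) == pytest.approx(p, rel=1e-9)


class TestWoolf:
    def test_haplogroup_j_table(self):
        or_value, lo, hi, corr = odds_ratio_woolf(TwoByTwoTable(45, 238, 25, 265))
        assert round(or_value, 2) == 2.00
        assert round(lo, 2) == 1.19
        assert round(hi, 2) == 3.37
        assert not corr

    def test_j_pvt1_joint_table(self):
        or_value, lo, hi, corr = odds_ratio_woolf(TwoByTwoTable(35, 248, 14, 276))
        assert round(or_value, 2) == 2.78
        assert round(lo, 2) == 1.46
        assert round(hi, 2) == 5.29
        assert not corr

    def test_equal_proportions_give_unit_or(self):
        or_value, lo, hi, _ = odds_ratio_woolf(TwoByTwoTable(10, 10, 10, 10))
        assert or_value == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_triggers_correction(self):
        or_value, lo, hi, corr = odds_ratio_woolf(TwoByTwoTable(5, 5, 0, 10))
        assert corr
        assert math.isfinite(or_value) and math.isfinite(hi)

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.integers(1, 30),
        b=st.integers(1, 30),
        c=st.integers(1, 30),
        d=st.integers(1, 30),
    )
    def test_column_swap_inverts_or(self, a, b, c, d):
        t = TwoByTwoTable(a, b, c, d)
        or1, lo1, hi1, _ = odds_ratio_woolf(t)
        or2, lo2, hi2, _ = odds_ratio_woolf(t.swapped_columns())
        assert or2 == pytest.approx(1 / or1, rel=1e-9)
        assert lo2 == pytest.approx(1 / hi1, rel=1e-9)

    @pytest.mark.parametrize("scale", [1, 2, 4])
    def test_ci_narrows_with_proportional_growth(self, scale):
        t = TwoByTwoTable(5 * scale, 10 * scale, 8 * scale, 12 * scale)
        or_value, lo, hi, _ = odds_ratio_woolf(t)
        width = math.log(hi) - math.log(lo)
        # fixed OR, width shrinks as 1/sqrt(scale)
        base = odds_ratio_woolf(TwoByTwoTable(5, 10, 8, 12))
        base_width = math.log(base[2]) - math.log(base[1])
        assert width == pytest.approx(base_width / math.sqrt(scale), rel=1e-9)
        assert or_value == pytest.approx(base[0], rel=1e-9)


class TestAssociateAndStrata:
    def test_percentages_match_published_single_features(self, ccl5_cohort):
        res = associate(ccl5_cohort, study_feature("ccl5"))
        # 110/283 = 38.87; agreement at the table's printed 1-dp precision
        assert res.freq_case_pct == pytest.approx(38.8, abs=0.1)
        assert res.freq_control_pct == pytest.approx(36.2, abs=0.1)

    def test_ci_ordering_invariant(self, ccl5_cohort, feature_j):
        res = associate(ccl5_cohort, feature_j)
        assert res.ci_low <= res.or_value <= res.ci_high
        assert 0 < res.p <= 1

    def test_sex_strata_sizes(self, ccl5_cohort):
        female, male = stratify_by_sex(ccl5_cohort)
        assert (female.n_case, female.n_control) == (198, 197)
        assert (male.n_case, male.n_control) == (85, 93)

    def test_missing_sex_in_neither_stratum(self):
        text = make_tsv(["S1\tcase\t.\tG\tC\tG\tA\tA"])
        female, male = stratify_by_sex(cohort_from_string(text))
        assert len(female) == 0 and len(male) == 0
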