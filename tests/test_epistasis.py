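"""Synergy factor, exact interaction test, and interaction classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln, logsumexp

from mitosyn import (
    Feature,
    InteractionCall,
    TwoByTwoByTwoTable,
    analyze_pair,
    build_2x2x2,
    classify_interaction,
    flint_exact,
    reconstruct_from_marginals,
    study_feature,
    study_fixture,
    synergy_factor,
)
from mitosyn.errors import DegenerateTableError, InconsistentMarginalsError
from oracles import flint_oracle

CCL5_TABLE = TwoByTwoByTwoTable((21, 24, 89, 149), (4, 21, 101, 164))
PVT1_TABLE = TwoByTwoByTwoTable((35, 10, 134, 104), (14, 11, 156, 109))


class TestReconstruction:
    def test_ccl5_marginals(self):
        t = reconstruct_from_marginals(45, 110, 21, 283, 25, 105, 4, 290)
        assert t == CCL5_TABLE

    def test_pvt1_marginals(self):
        t = reconstruct_from_marginals(45, 169, 35, 283, 25, 170, 14, 290)
        assert t == PVT1_TABLE

    def test_joint_exceeding_marginal_rejected(self):
        with pytest.raises(InconsistentMarginalsError):
            reconstruct_from_marginals(10, 20, 15, 100, 5, 5, 2, 100)

    def test_marginals_exceeding_total_rejected(self):
        with pytest.raises(InconsistentMarginalsError):
            reconstruct_from_marginals(80, 80, 10, 100, 5, 5, 2, 100)

    def test_cohort_table_matches_reconstruction(self, ccl5_cohort):
        t = build_2x2x2(
            ccl5_cohort, Feature.haplogroup("J"), study_feature("ccl5")
        )
        assert t == CCL5_TABLE

    def test_nobody_carries_b(self):
        t = reconstruct_from_marginals(5, 0, 0, 20, 3, 0, 0, 20)
        assert t.case[0] == 0 and t.case[2] == 0
        assert t.control[0] == 0 and t.control[2] == 0


class TestSynergyFactor:
    def test_ccl5_corrected_point_estimate(self):
        res = synergy_factor(CCL5_TABLE)
        assert res.correction_applied  # min cell 4 < 5
        assert round(res.sf, 2) == 4.32
        assert res.sf == pytest.approx(4.3213, abs=5e-4)

    def test_pvt1_uncorrected_estimate_and_ci(self):
        res = synergy_factor(PVT1_TABLE)
        assert not res.correction_applied  # min cell 10
        assert round(res.sf, 2) == 3.05
        assert res.sf == pytest.approx(3.0546, abs=5e-4)
        assert round(res.ci_low, 2) == 1.00
        assert round(res.ci_high, 2) == 9.31

    def test_multiplicative_null_gives_unit_sf(self):
        # or11 = 4, or10 = 2, or01 = 2 exactly
        t = TwoByTwoByTwoTable((80, 40, 40, 10), (20, 20, 20, 10))
        res = synergy_factor(t, small_cell_threshold=0)
        assert res.sf == pytest.approx(1.0)

    def test_symmetric_under_factor_exchange(self):
        for t in (CCL5_TABLE, PVT1_TABLE):
            a = synergy_factor(t)
            b = synergy_factor(t.swapped_factors())
            assert b.sf == pytest.approx(a.sf, rel=1e-12)
            assert b.ci_low == pytest.approx(a.ci_low, rel=1e-12)

    def test_status_swap_inverts_sf(self):
        a = synergy_factor(PVT1_TABLE)
        b = synergy_factor(PVT1_TABLE.swapped_status())
        assert b.sf == pytest.approx(1 / a.sf, rel=1e-12)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-12)

    def test_zero_cell_without_correction_errors(self):
        t = TwoByTwoByTwoTable((0, 5, 5, 5), (5, 5, 5, 5))
        with pytest.raises(DegenerateTableError):
            synergy_factor(t, small_cell_threshold=0)


def _random_tables():
    cell = st.integers(0, 25)
    return st.tuples(*[cell] * 8).filter(lambda c: sum(c[:4]) > 0 and sum(c[4:]) > 0)


class TestFlint:
    def test_single_feasible_table_gives_one(self):
        # nobody carries B: pivot range is a single value
        t = reconstruct_from_marginals(5, 0, 0, 20, 3, 0, 0, 20)
        res = flint_exact(t)
        assert res.n_tables == 1
        assert res.p_flint == 1.0

    def test_uniform_table_gives_one(self):
        res = flint_exact(TwoByTwoByTwoTable((5, 5, 5, 5), (5, 5, 5, 5)))
        assert res.p_flint == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [CCL5_TABLE, PVT1_TABLE], ids=["ccl5", "pvt1"])
    def test_matches_rational_enumeration_oracle(self, table):
        res = flint_exact(table)
        expected = float(flint_oracle(table.case, table.control))
        assert res.p_flint == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, max_examples=150)
    @given(cells=_random_tables())
    def test_oracle_agreement_on_random_tables(self, cells):
        """Exact-rational enumeration agreement for tables up to N = 200."""
        t = TwoByTwoByTwoTable(tuple(cells[:4]), tuple(cells[4:]))
        try:
            res = flint_exact(t)
        except DegenerateTableError:
            return
        expected = float(flint_oracle(t.case, t.control))
        assert res.p_flint == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(cells=_random_tables())
    def test_null_probabilities_normalize(self, cells):
        t = TwoByTwoByTwoTable(tuple(cells[:4]), tuple(cells[4:]))
        from mitosyn.epistasis import _solve_family

        try:
            offsets, signs, lo, hi = _solve_family(t)
        except DegenerateTableError:
            return
        pivots = np.arange(lo, hi + 1)
        c = offsets[None, :] + signs[None, :] * pivots[:, None]
        logw = -gammaln(c + 1.0).sum(axis=1)
        total = np.exp(logsumexp(logw - logsumexp(logw)))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_status_swap_preserves_p(self):
        a = flint_exact(PVT1_TABLE)
        b = flint_exact(PVT1_TABLE.swapped_status())
        assert b.p_flint == pytest.approx(a.p_flint, rel=1e-9)

    def test_factor_swap_preserves_p(self):
        a = flint_exact(CCL5_TABLE)
        b = flint_exact(CCL5_TABLE.swapped_factors())
        assert b.p_flint == pytest.approx(a.p_flint, rel=1e-9)


class TestClassification:
    def test_epistatic_when_both_criteria_hold(self, ccl5_cohort):
        res = analyze_pair(
            ccl5_cohort, Feature.haplogroup("J"), study_feature("ccl5")
        )
        assert res.synergy.ci_excludes_one
        assert res.flint.p_flint < 0.05
        assert res.classification is InteractionCall.EPISTATIC

    def test_suggestive_when_only_sf_criterion_holds(self, pvt1_cohort):
        res = analyze_pair(
            pvt1_cohort, Feature.haplogroup("J"), study_feature("pvt1")
        )
        assert res.synergy.ci_excludes_one
        assert res.flint.p_flint >= 0.05
        assert res.classification is InteractionCall.SUGGESTIVE

    def test_not_supported_when_neither_holds(self):
        cohort = study_fixture("clec16a")
        res = analyze_pair(
            cohort, Feature.haplogroup("J"), study_feature("clec16a")
        )
        assert res.classification is InteractionCall.NOT_SUPPORTED

    def test_classifier_on_explicit_results(self):
        sf_in = synergy_factor(CCL5_TABLE)
        fl_in = flint_exact(CCL5_TABLE)
        assert classify_interaction(sf_in, fl_in) is InteractionCall.EPISTATIC
        assert (
            classify_interaction(sf_in, fl_in, alpha=0.001)
            is InteractionCall.SUGGESTIVE
        )


class TestCalibration:
    def test_type_i_error_under_multiplicative_null(self):
        """Under simulated null cohorts (SF = 1) the exact test rejects at
        most alpha + 2 Monte-Carlo SE of the time."""
        from mitosyn.simulate import SimulationConfig, stratum_distributions

        rng = np.random.default_rng(2024)
        alpha = 0.05
        n_sim = 400
        cfg = SimulationConfig(
            n_case=250, n_control=250, or10=1.3, or01=1.2, sf=1.0
        )
        case_dist, ctrl_dist = stratum_distributions(cfg)
        rejections = 0
        for _ in range(n_sim):
            case = rng.multinomial(cfg.n_case, case_dist)
            ctrl = rng.multinomial(cfg.n_control, ctrl_dist)
            t = TwoByTwoByTwoTable(tuple(int(x) for x in case), tuple(int(x) for x in ctrl))
            try:
                if flint_exact(t).p_flint < alpha:
                    rejections += 1
            except DegenerateTableError:
                continue
        mc_se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert rejections / n_sim <= alpha + 2 * mc_se
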