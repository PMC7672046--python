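import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varfunnel.association import (
    DIFFERENTIAL,
    NOT_ASSOCIATED,
    NOVEL,
    ContingencyTable,
    associate_all,
    bh_fdr,
    build_contingency,
    chi_squared,
    classify_variant,
    fisher_exact,
)
from varfunnel.funnel import run_funnel
from varfunnel.io import PanelRecord, ValidationError
from varfunnel.simulate import SimulationConfig, generate_dataset

from oracles import bh_stepup_oracle, fisher_two_sided_oracle


class TestBuildContingency:
    def test_het_carriers_absent_panel(self):
        t = build_contingency(3, 0, 195, PanelRecord("CHS", 105, 0.0, present=False))
        assert (t.case_alt, t.case_ref, t.panel_alt, t.panel_ref) == (3, 387, 0, 210)

    def test_zero_carriers(self):
        t = build_contingency(0, 0, 195, PanelRecord("CHS", 105, 0.0, present=False))
        assert (t.case_alt, t.case_ref, t.panel_alt, t.panel_ref) == (0, 390, 0, 210)

    def test_panel_count_rounding(self):
        t = build_contingency(2, 0, 195, PanelRecord("EAS", 4327, 0.05))
        assert t.panel_alt == 433  # round(0.05 * 8654) = round(432.7)

    def test_rounding_ties_go_up(self):
        # af * 2n = 0.5 exactly
        t = build_contingency(2, 0, 195, PanelRecord("X", 5, 0.05))
        assert t.panel_alt == 1

    def test_hom_carriers_count_twice(self):
        t = build_contingency(3, 2, 195, PanelRecord("CHS", 105, 0.0, present=False))
        assert t.case_alt == 1 + 2 * 2

    def test_margins_match_cohort_and_panel_sizes(self):
        t = build_contingency(5, 1, 195, PanelRecord("EAS", 4327, 0.001))
        assert t.case_alt + t.case_ref == 2 * 195
        assert t.panel_alt + t.panel_ref == 2 * 4327

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            build_contingency(3, 4, 195, PanelRecord("CHS", 105, 0.0, present=False))
        with pytest.raises(ValidationError):
            build_contingency(200, 0, 195, PanelRecord("CHS", 105, 0.0, present=False))


class TestFisherExact:
    def test_identical_proportions(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_small_table_by_hand(self):
        # enumerating all 5 margin-fixed tables gives 34/70
        assert fisher_exact(ContingencyTable(3, 1, 1, 3)) == pytest.approx(34 / 70, abs=1e-9)

    def test_cohort_scale_table_matches_enumeration_oracle(self):
        p = fisher_exact(ContingencyTable(3, 387, 0, 210))
        oracle = float(fisher_two_sided_oracle(3, 387, 0, 210))
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_zero_margin_degenerate(self):
        assert fisher_exact(ContingencyTable(0, 10, 0, 20)) == 1.0

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_oracle_on_random_tables(self, a, b, c, d):
        p = fisher_exact(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(float(fisher_two_sided_oracle(a, b, c, d)), abs=1e-10)


class TestChiSquared:
    def test_no_association_gives_zero_statistic(self):
        stat, p, _ = chi_squared(ContingencyTable(5, 5, 5, 5))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_statistic_matches_hand_computation(self):
        # table (10,90 / 1,99): expected cells from margins, sum (O-E)^2/E
        t = ContingencyTable(10, 90, 1, 99)
        n = 200
        expected = np.outer([100, 100], [11, 189]) / n
        observed = np.array([[10, 90], [1, 99]])
        hand = ((observed - expected) ** 2 / expected).sum()
        stat, p, low = chi_squared(t)
        assert stat == pytest.approx(hand, rel=1e-12)
        assert low == bool((expected < 5).any())

    def test_low_expected_flag(self):
        _, _, low = chi_squared(ContingencyTable(2, 398, 0, 400))
        assert low is True

    def test_zero_margin(self):
        stat, p, low = chi_squared(ContingencyTable(0, 10, 0, 10))
        assert np.isnan(stat) and p == 1.0 and low


class TestBhFdr:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_step_up_by_hand(self, ps, expected):
        assert bh_fdr(ps) == pytest.approx(expected)

    def test_out_of_range_p_is_error(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=150, deadline=None)
    def test_matches_stepup_oracle_and_dominates_p(self, ps):
        qs = bh_fdr(ps)
        assert qs == pytest.approx(bh_stepup_oracle(ps), abs=1e-12)
        assert np.all(qs >= np.asarray(ps) - 1e-12)

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=25),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_invariant_to_input_order(self, ps, seed):
        perm = np.random.default_rng(seed).permutation(len(ps))
        qs = bh_fdr(ps)
        qs_perm = bh_fdr([ps[i] for i in perm])
        assert np.asarray(qs)[perm] == pytest.approx(np.asarray(qs_perm), abs=1e-12)


class TestClassifyVariant:
    def test_multi_carrier_panel_absent_is_novel(self):
        cls = classify_variant(3, {"CHS": None, "EAS": None}, {"CHS": None, "EAS": None})
        assert cls == NOVEL

    def test_present_and_significant_everywhere_is_differential(self):
        recs = {
            "CHS": PanelRecord("CHS", 105, 0.01),
            "EAS": PanelRecord("EAS", 4327, 0.01),
        }
        assert classify_variant(5, recs, {"CHS": 0.001, "EAS": 0.001}) == DIFFERENTIAL

    def test_present_not_significant(self):
        recs = {"CHS": PanelRecord("CHS", 105, 0.01), "EAS": None}
        assert classify_variant(5, recs, {"CHS": 0.5, "EAS": None}) == NOT_ASSOCIATED

    def test_single_carrier_absent_everywhere_not_novel(self):
        assert classify_variant(1, {"CHS": None}, {"CHS": None}) == NOT_ASSOCIATED

    def test_any_mode_requires_one_significant_panel(self):
        recs = {
            "CHS": PanelRecord("CHS", 105, 0.01),
            "EAS": PanelRecord("EAS", 4327, 0.01),
        }
        qs = {"CHS": 0.5, "EAS": 0.001}
        assert classify_variant(5, recs, qs, panel_sig_mode="any") == DIFFERENTIAL
        assert classify_variant(5, recs, qs, panel_sig_mode="all") == NOT_ASSOCIATED

    @given(
        carrier_count=st.integers(0, 20),
        af_chs=st.sampled_from([0.0, 0.001, 0.01]),
        af_eas=st.sampled_from([0.0, 0.001, 0.01]),
        q=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_novel_and_differential_mutually_exclusive(self, carrier_count, af_chs, af_eas, q):
        recs = {
            "CHS": PanelRecord("CHS", 105, af_chs, present=af_chs > 0),
            "EAS": PanelRecord("EAS", 4327, af_eas, present=af_eas > 0),
        }
        qs = {"CHS": q if af_chs > 0 else None, "EAS": q if af_eas > 0 else None}
        cls = classify_variant(carrier_count, recs, qs)
        if cls == NOVEL:
            assert af_chs == af_eas == 0.0
        if cls == DIFFERENTIAL:
            assert af_chs > 0 or af_eas > 0


class TestAssociateAll:
    def test_empty_candidates(self):
        assert associate_all([], {"CHS": {}, "EAS": {}}, 195) == []

    def test_planted_truth_recovered_on_one_dataset(self):
        ds = generate_dataset(SimulationConfig(n_variants=400, seed=3))
        candidates, _ = run_funnel(ds.variants, ds.panels)
        results = associate_all(candidates, ds.panels, 195)
        found_novel = {str(r.key) for r in results if r.classification == NOVEL}
        found_diff = {str(r.key) for r in results if r.classification == DIFFERENTIAL}
        assert ds.truth.planted_novel_ids <= found_novel
        n_diff = len(ds.truth.planted_differential_ids)
        assert len(ds.truth.planted_differential_ids & found_diff) >= 0.8 * n_diff

    def test_results_sorted_by_min_q(self):
        ds = generate_dataset(SimulationConfig(n_variants=300, seed=5))
        candidates, _ = run_funnel(ds.variants, ds.panels)
        results = associate_all(candidates, ds.panels, 195)
        qs = [r.min_q for r in results]
        assert qs == sorted(qs)
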