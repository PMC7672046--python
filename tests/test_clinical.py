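import itertools

import numpy as np
import pandas as pd
import pytest

from varfunnel.clinical import (
    SubgroupDefinition,
    cohort_summary,
    dichotomize,
    feature_correlation,
    intersect_variant_sets,
    variant_feature_screen,
    wilcoxon_rank_sum,
)
from varfunnel.io import ValidationError, VariantKey
from varfunnel.simulate import generate_clinical

from conftest import make_variant
from oracles import wilcoxon_exact_oracle


@pytest.fixture(scope="module")
def cohort():
    return generate_clinical(195, seed=42)


class TestCohortSummary:
    def test_female_male_ratio(self, cohort):
        summary = cohort_summary(cohort)
        assert summary["counts"]["sex"] == {"F": 156, "M": 39}
        assert summary["female_male_ratio"] == pytest.approx(4.0)

    def test_shape_counts_sum_to_cohort_size(self, cohort):
        summary = cohort_summary(cohort)
        assert summary["counts"]["shape"] == {"C": 131, "S": 64}
        assert sum(summary["counts"]["shape"].values()) == summary["n_patients"] == 195

    def test_single_record_sds_missing(self, cohort):
        summary = cohort_summary(cohort.head(1))
        assert summary["cobb"]["sd"] is None

    def test_zero_males_ratio_missing(self, cohort):
        females = cohort[cohort["sex"] == "F"]
        assert cohort_summary(females)["female_male_ratio"] is None

    def test_empty_table_is_error(self, cohort):
        with pytest.raises(ValidationError):
            cohort_summary(cohort.iloc[0:0])


class TestDichotomize:
    def test_mean_split(self):
        df = pd.DataFrame({"patient_id": ["a", "b"], "cobb": [30.0, 50.0]})
        labels = dichotomize(df, SubgroupDefinition("cobb", "above_below_mean"))
        assert list(labels) == ["below", "above"]

    def test_value_at_mean_goes_below(self):
        df = pd.DataFrame({"cobb": [30.0, 40.0, 50.0]})
        labels = dichotomize(df, SubgroupDefinition("cobb", "above_below_mean"))
        assert list(labels) == ["below", "below", "above"]

    def test_categorical_passthrough(self):
        df = pd.DataFrame({"shape": ["C", "S", "C"]})
        labels = dichotomize(df, SubgroupDefinition("shape", "categorical", ("C", "S")))
        assert list(labels) == ["C", "S", "C"]

    def test_constant_feature_is_error(self):
        df = pd.DataFrame({"cobb": [40.0, 40.0]})
        with pytest.raises(ValidationError, match="constant"):
            dichotomize(df, SubgroupDefinition("cobb", "above_below_mean"))


class TestWilcoxonRankSum:
    def test_small_exact(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_tie_degenerate(self):
        _, p = wilcoxon_rank_sum([5], [5])
        assert p == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1, 2])

    @pytest.mark.parametrize("n_a,n_b,seed", [(2, 3, 0), (3, 3, 1), (4, 5, 2), (5, 5, 3), (2, 8, 4)])
    def test_exact_matches_enumeration_oracle(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))
        a, b = vals[:n_a], vals[n_a:]
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(wilcoxon_exact_oracle(list(a), list(b)), abs=1e-12)

    def test_null_p_roughly_uniform_large_n(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(400):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(wilcoxon_rank_sum(x, y)[1])
        ps = np.asarray(ps)
        # super-uniformity within Monte-Carlo error at two working levels
        for alpha in (0.05, 0.2):
            rate = (ps <= alpha).mean()
            mcse = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert rate <= alpha + 3 * mcse


class TestVariantFeatureScreen:
    def _clinical(self, n=60, seed=0):
        return generate_clinical(n, seed=seed)

    def test_zero_carrier_variant_skipped_with_warning(self):
        clinical = self._clinical()
        v = make_variant(1, [])
        frame, _, warnings = variant_feature_screen([v], clinical)
        assert frame.empty and any("no carriers" in w for w in warnings)

    def test_variant_carried_by_everyone_skipped(self):
        clinical = self._clinical(n=5)
        v = make_variant(1, [(50, 0.5)] * 5)
        frame, _, warnings = variant_feature_screen([v], clinical)
        assert frame.empty and any("no contrast" in w for w in warnings)

    def test_planted_cobb_shift_detected(self):
        rng = np.random.default_rng(1)
        clinical = self._clinical(n=195, seed=1)
        carriers = list(rng.choice(clinical["patient_id"], size=10, replace=False))
        sd = clinical["cobb"].std()
        clinical.loc[clinical["patient_id"].isin(carriers), "cobb"] += 2 * sd
        v = make_variant(1, [(50, 0.5)] * 10)
        v.calls = [c.__class__(pid, 50, 0.5) for c, pid in zip(v.calls, carriers)]
        frame, significant, _ = variant_feature_screen([v], clinical, features=("cobb",))
        assert v.key in significant["cobb"]

    def test_invariant_to_patient_row_order(self):
        clinical = self._clinical(n=80, seed=3)
        v = make_variant(1, [(50, 0.5)] * 8)
        v.calls = [
            c.__class__(pid, 50, 0.5)
            for c, pid in zip(v.calls, clinical["patient_id"].iloc[:8])
        ]
        frame1, _, _ = variant_feature_screen([v], clinical)
        shuffled = clinical.sample(frac=1, random_state=9).reset_index(drop=True)
        frame2, _, _ = variant_feature_screen([v], shuffled)
        merged = frame1.merge(frame2, on=["chrom", "pos", "ref", "alt", "feature"])
        assert np.allclose(merged["p_x"], merged["p_y"])

    def test_binary_wilcoxon_alternative_runs(self):
        clinical = self._clinical(n=40, seed=5)
        v = make_variant(1, [(50, 0.5)] * 6)
        v.calls = [
            c.__class__(pid, 50, 0.5)
            for c, pid in zip(v.calls, clinical["patient_id"].iloc[:6])
        ]
        frame, _, _ = variant_feature_screen(
            [v], clinical, features=("sex",), binary_feature_test="wilcoxon"
        )
        assert set(frame["test"]) == {"wilcoxon"}


class TestFeatureCorrelation:
    def test_diagonal_is_perfect_association(self):
        clinical = generate_clinical(60, seed=2)
        p, _ = feature_correlation(clinical)
        assert np.allclose(np.diag(p.to_numpy()), 0.0)
        assert np.allclose(p.to_numpy(), p.to_numpy().T)

    def test_duplicated_column_near_zero_p(self):
        clinical = generate_clinical(100, seed=4)
        clinical["cobb2"] = clinical["cobb"]
        from varfunnel import clinical as clin_mod

        clin_mod.FEATURE_TYPES["cobb2"] = "continuous"
        try:
            p, tests = feature_correlation(clinical, features=["cobb", "cobb2", "sex"])
            assert p.loc["cobb", "cobb2"] < 1e-10
            assert tests.loc["cobb", "cobb2"] == "spearman"
        finally:
            del clin_mod.FEATURE_TYPES["cobb2"]

    def test_independent_features_not_flagged(self):
        # generator draws features independently: p-values should rarely be tiny
        ps = []
        for seed in range(20):
            clinical = generate_clinical(100, seed=seed)
            p, _ = feature_correlation(clinical, features=["cobb", "direction"])
            ps.append(p.loc["cobb", "direction"])
        assert np.mean(np.asarray(ps) < 0.01) <= 0.2


class TestIntersectVariantSets:
    def _keys(self, *positions):
        return {VariantKey("1", p, "A", "G") for p in positions}

    def test_disjoint_sets_share_nothing(self):
        sets = {f"f{i}": self._keys(10 * i + 1, 10 * i + 2) for i in range(4)}
        out = intersect_variant_sets(sets)
        assert out["shared_by_all"] == 0
        assert out["union"] == 8

    def test_single_shared_element(self):
        sets = {
            "w": self._keys(1, 2),
            "x": self._keys(1),
            "y": self._keys(1, 3),
            "z": self._keys(1),
        }
        out = intersect_variant_sets(sets)
        assert out["shared_by_all"] == 1
        assert out["shared_by_all_pct"] == pytest.approx(100 / 3)

    def test_region_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        names = ["a", "b", "c"]
        sets = {
            n: {VariantKey("1", int(p), "A", "G") for p in rng.choice(50, size=15, replace=False) + 1}
            for n in names
        }
        out = intersect_variant_sets(sets)
        union = set().union(*sets.values())
        assert out["union"] == len(union)
        # brute force: classify every union element by its membership pattern
        brute: dict[str, int] = {}
        for key in union:
            members = tuple(n for n in names if key in sets[n])
            brute["&".join(members)] = brute.get("&".join(members), 0) + 1
        for region, count in out["regions"].items():
            assert count == brute.get(region, 0)
        assert sum(out["regions"].values()) == len(union)

    def test_fewer_than_two_sets_is_error(self):
        with pytest.raises(ValidationError):
            intersect_variant_sets({"only": self._keys(1)})
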