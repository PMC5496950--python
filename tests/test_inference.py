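"""Relative effects, rank MANOVA, closed testing, Fisher-z and Holm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from eegretest import (
    closed_subset_testing,
    fisher_z_compare,
    holm_correction,
    np_manova,
    relative_effects,
)
from eegretest.inference import EdgeReliabilityMap, edge_comparison_map


class TestRelativeEffects:
    def test_hand_example_two_pairs(self):
        out = relative_effects({"lo": np.array([1, 2]), "hi": np.array([3, 4])})
        assert out["lo"] == pytest.approx(0.25)
        assert out["hi"] == pytest.approx(0.75)

    def test_exchangeable_groups_near_half(self, rng):
        vals = {g: rng.normal(size=400) for g in "abcd"}
        out = relative_effects(vals)
        for p in out.values():
            assert abs(p - 0.5) < 0.05

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(-3, 3), min_size=1, max_size=12),
        st.lists(st.integers(-3, 3), min_size=1, max_size=12),
        st.lists(st.integers(-3, 3), min_size=1, max_size=12),
    )
    def test_weighted_mean_exactly_half_with_ties(self, a, b, c):
        """Midranks force sum_g (n_g/N) p_g = 1/2 on any input."""
        groups = {"a": np.array(a, float), "b": np.array(b, float), "c": np.array(c, float)}
        out = relative_effects(groups)
        N = sum(len(v) for v in groups.values())
        mean = sum(len(groups[g]) / N * out[g] for g in groups)
        assert mean == pytest.approx(0.5, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            relative_effects({"a": np.array([]), "b": np.array([1.0])})


class TestNpManova:
    def test_identical_group_copies_give_null_statistic(self, rng):
        block = rng.normal(size=(10, 3))
        data = np.vstack([block, block])
        groups = ["a"] * 10 + ["b"] * 10
        res = np_manova(data, groups, permutations=500, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.permutation_p > 0.95

    def test_fractional_dfs_and_valid_p(self, rng):
        res = np_manova(rng.normal(size=(60, 3)), np.repeat(list("abcd"), 15))
        assert res.df1 > 0 and res.df2 > 0
        assert 0 <= res.p_value <= 1

    def test_f_and_permutation_p_agree_under_null(self):
        """Box-approximated F p-value tracks the permutation p-value."""
        rng = np.random.default_rng(123)
        diffs = []
        for _ in range(100):
            data = rng.normal(size=(60, 3))
            groups = np.repeat(list("abcd"), 15)
            res = np_manova(data, groups, permutations=5000, seed=7)
            diffs.append(abs(res.p_value - res.permutation_p))
        assert np.max(diffs) < 0.03

    def test_power_against_shifted_group(self, rng):
        hits = 0
        for _ in range(50):
            data = rng.normal(size=(60, 3))
            data[:15] += 2.0  # one group shifted by 2 pooled SDs
            if np_manova(data, np.repeat(list("abcd"), 15)).p_value < 0.05:
                hits += 1
        assert hits / 50 > 0.9

    def test_constant_column_dropped_with_warning(self, rng):
        data = rng.normal(size=(20, 2))
        data[:, 1] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            res = np_manova(data, ["a"] * 10 + ["b"] * 10)
        assert 0 <= res.p_value <= 1

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            np_manova(np.ones((10, 2)), ["a"] * 5 + ["b"] * 5)

    def test_group_size_validation(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            np_manova(rng.normal(size=(3, 2)), ["a", "a", "b"])


class TestClosedTesting:
    def test_two_groups_reduce_to_single_test(self, rng):
        data = rng.normal(size=(20, 2))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        closure = closed_subset_testing(data, groups)
        assert set(closure) == {frozenset(["a", "b"])}
        single = np_manova(data, groups)
        assert closure[frozenset(["a", "b"])]["p_value"] == pytest.approx(single.p_value)

    def test_coherence_no_rejection_without_superset(self, rng):
        for seed in range(10):
            data = np.random.default_rng(seed).normal(size=(40, 2))
            groups = np.repeat(list("abcd"), 10)
            closure = closed_subset_testing(data, groups)
            for subset, entry in closure.items():
                if entry["rejected"]:
                    for sup, sup_entry in closure.items():
                        if subset < sup:
                            assert sup_entry["p_value"] <= 0.05

    def test_familywise_error_controlled_under_global_null(self):
        rng = np.random.default_rng(2024)
        any_rej = 0
        n_sim = 200
        for _ in range(n_sim):
            data = rng.normal(size=(32, 2))
            groups = np.repeat(list("abcd"), 8)
            closure = closed_subset_testing(data, groups)
            any_rej += any(e["rejected"] for e in closure.values())
        assert any_rej / n_sim <= 0.05 + 0.03

    def test_selectivity_for_one_shifted_group(self):
        rng = np.random.default_rng(77)
        good = 0
        n_sim = 30
        for _ in range(n_sim):
            data = rng.normal(size=(40, 2))
            data[:10] += 2.5
            groups = np.repeat(list("abcd"), 10)
            closure = closed_subset_testing(data, groups)
            with_a = [e["rejected"] for s, e in closure.items() if "a" in s]
            without_a = [e["rejected"] for s, e in closure.items() if "a" not in s]
            if all(with_a) and not any(without_a):
                good += 1
        assert good / n_sim >= 0.8


class TestFisherZ:
    def test_equal_correlations_give_null(self):
        Z, p = fisher_z_compare(0.6, 15, 0.6, 40)
        assert Z == 0 and p == pytest.approx(1.0)

    def test_closed_form_hand_value(self):
        Z, _ = fisher_z_compare(0.9, 23, 0.3, 23)
        expected = (math.atanh(0.9) - math.atanh(0.3)) / math.sqrt(1 / 20 + 1 / 20)
        assert Z == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_under_group_swap(self):
        Z1, p1 = fisher_z_compare(0.8, 20, 0.2, 30)
        Z2, p2 = fisher_z_compare(0.2, 30, 0.8, 20)
        assert Z1 == pytest.approx(-Z2)
        assert p1 == pytest.approx(p2)

    def test_unit_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            Z, p = fisher_z_compare(1.0, 10, 0.5, 10)
        assert np.isfinite(Z)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="more than 3"):
            fisher_z_compare(0.5, 3, 0.5, 10)


class TestHolm:
    def test_hand_example(self):
        adjusted, reject = holm_correction([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adjusted, [0.03, 0.06, 0.06])
        np.testing.assert_array_equal(reject, [True, False, False])

    def test_single_p_passthrough(self):
        adjusted, _ = holm_correction([0.2])
        assert adjusted[0] == pytest.approx(0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_statsmodels_holm(self, pvals):
        adjusted, reject = holm_correction(pvals, alpha=0.05)
        sm_reject, sm_adj, *_ = multipletests(pvals, alpha=0.05, method="holm")
        np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, sm_reject)

    def test_sandwich_between_none_and_bonferroni(self, rng):
        for _ in range(20):
            p = rng.random(25)
            _, holm_rej = holm_correction(p, alpha=0.05)
            bonf_rej = p <= 0.05 / p.size
            raw_rej = p <= 0.05
            assert (holm_rej | ~bonf_rej).all()  # Holm rejects all Bonferroni picks
            assert (~holm_rej | raw_rej).all()  # and never an unadjusted non-rejection

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            holm_correction([0.5, 1.2])


class TestEdgeComparison:
    def _maps(self, rho_a, rho_b, n=20):
        return {
            "A": {"COH": EdgeReliabilityMap("A", "COH", rho_a, n)},
            "B": {"COH": EdgeReliabilityMap("B", "COH", rho_b, n)},
        }

    def test_identical_groups_all_zero_significance(self, rng):
        rho = np.clip(rng.normal(0.5, 0.1, size=(2, 4, 4)), -0.99, 0.99)
        res = edge_comparison_map(self._maps(rho, rho.copy()))
        assert (res.table["Z"] == 0).all()
        assert not res.table["significant"].any()

    def test_null_draws_rarely_significant(self, rng):
        # both groups' rho sampled from the Fisher-z null around the same truth
        n = 20
        z0 = np.arctanh(0.4)
        shape = (2, 10, 25)  # 500 cells
        z1 = rng.normal(z0, 1 / np.sqrt(n - 3), size=shape)
        z2 = rng.normal(z0, 1 / np.sqrt(n - 3), size=shape)
        res = edge_comparison_map(self._maps(np.tanh(z1), np.tanh(z2), n))
        frac_zero = (res.table["Z_significant"] == 0).mean()
        assert frac_zero >= 0.99

    def test_nan_cells_skipped_and_counted(self, rng):
        rho_a = rng.uniform(-0.5, 0.5, size=(1, 2, 2))
        rho_b = rho_a.copy()
        rho_a[0, 0, 0] = np.nan
        res = edge_comparison_map(self._maps(rho_a, rho_b))
        assert res.n_skipped == 1
        assert len(res.table) == 3

    def test_large_true_difference_detected(self, rng):
        rho_a = np.full((1, 3, 3), 0.95)
        rho_b = np.full((1, 3, 3), -0.5)
        res = edge_comparison_map(self._maps(rho_a, rho_b, n=40))
        assert res.table["significant"].all()
        zmap = res.significance_maps[("A", "B", "COH")]
        assert (zmap > 0).all()


class TestPoolingScope:
    def _maps_two_measures(self, rng, n=20):
        maps = {}
        for g, shift in (("A", 0.0), ("B", 1.2)):
            per = {}
            for meas in ("COH", "S"):
                z = rng.normal(np.arctanh(0.3) + (shift if meas == "COH" else 0),
                               1 / np.sqrt(n - 3), size=(1, 3, 3))
                per[meas] = EdgeReliabilityMap(g, meas, np.tanh(z), n)
            maps[g] = per
        return maps

    def test_per_measure_pooling_smaller_family(self, rng):
        maps = self._maps_two_measures(rng)
        joint = edge_comparison_map(maps, alpha=0.05, pool="joint")
        per = edge_comparison_map(maps, alpha=0.05, pool="per_measure")
        assert joint.smallest_critical_p == pytest.approx(0.05 / len(joint.table))
        assert per.smallest_critical_p == pytest.approx(0.05 / 9)
        # smaller families can only gain rejections
        assert per.table["significant"].sum() >= joint.table["significant"].sum()

    def test_invalid_pool_rejected(self, rng):
        maps = self._maps_two_measures(rng)
        with pytest.raises(ValueError, match="pool"):
            edge_comparison_map(maps, pool="nope")
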