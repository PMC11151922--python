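"""Partition statistics: CVs, synchrony ratios, invariability, Taylor fits."""

import math

import numpy as np
import pytest

from pollistab import (
    MetacommunityTensor,
    temporal_sd_mean,
    var_partition,
    invariability,
    taylor_fit,
    taylor_units,
)
from pollistab.partition import PartitionResult

from conftest import brute_force_partition, random_tensor


def make_tensor(values, variable="flower_availability", observed=None):
    values = np.asarray(values, float)
    u, k, t = values.shape
    return MetacommunityTensor(
        values=values,
        unit_labels=[f"u{i}" for i in range(u)],
        patch_labels=[f"k{j}" for j in range(k)],
        time_labels=list(range(t)),
        variable=variable,
        observed=observed,
    )


class TestTemporalSdMean:
    def test_two_point_series(self):
        sd, mean = temporal_sd_mean([2, 4])
        assert sd == pytest.approx(abs(2 - 4) / math.sqrt(2))
        assert mean == 3.0

    def test_constant_series(self):
        assert temporal_sd_mean([5, 5, 5]) == (0.0, 5.0)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_homogeneity(self, c):
        x = np.array([1.0, 4.0, 2.5])
        sd, mean = temporal_sd_mean(x)
        sd_c, mean_c = temporal_sd_mean(c * x)
        assert sd_c == pytest.approx(c * sd)
        assert mean_c == pytest.approx(c * mean)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            temporal_sd_mean([3.0])


class TestVarPartition:
    def test_worked_micro_example_matches_oracle(self, micro_tensor):
        res = var_partition(micro_tensor)
        expected = brute_force_partition(micro_tensor.values)
        for name, value in expected.items():
            assert getattr(res, name) == pytest.approx(value, abs=1e-14)
        # frozen oracle values for the 2x2x3 example
        assert res.cv_s_l == pytest.approx(0.375)
        assert res.cv_c_l == pytest.approx(0.25)
        assert res.cv_s_r == pytest.approx(0.125)
        assert res.cv_c_r == pytest.approx(0.125)
        assert res.phi_s2c_l == pytest.approx(2 / 3)
        assert res.phi_c_l2r == pytest.approx(0.5)
        assert res.phi_s_l2r == pytest.approx(1 / 3)
        assert res.phi_s2c_r == pytest.approx(1.0)

    def test_single_unit_hierarchy_collapses(self):
        res = var_partition(make_tensor([[[2, 4]]]))
        for cv in (res.cv_s_l, res.cv_c_l, res.cv_s_r, res.cv_c_r):
            assert cv == pytest.approx(0.4714045, abs=1e-6)
        for phi in (res.phi_s2c_l, res.phi_c_l2r, res.phi_s_l2r, res.phi_s2c_r):
            assert phi == pytest.approx(1.0)

    def test_perfect_spatial_anticorrelation(self):
        res = var_partition(make_tensor([[[2, 4], [4, 2]]]))
        assert res.cv_c_r == 0.0
        assert res.phi_c_l2r == 0.0
        assert math.isinf(res.inv_c_r)

    def test_oracle_equivalence_on_random_tensors(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            tensor = random_tensor(rng)
            res = var_partition(tensor)
            expected = brute_force_partition(tensor.values)
            for name, value in expected.items():
                assert getattr(res, name) == pytest.approx(value, rel=1e-10, abs=1e-10)

    def test_multiplicative_identities_and_bounds(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            res = var_partition(random_tensor(rng))
            assert res.cv_c_r == pytest.approx(res.cv_c_l * res.phi_c_l2r, rel=1e-12)
            assert res.cv_c_l == pytest.approx(res.cv_s_l * res.phi_s2c_l, rel=1e-12)
            assert res.cv_s_r == pytest.approx(res.cv_s_l * res.phi_s_l2r, rel=1e-12)
            assert res.cv_c_r == pytest.approx(res.cv_s_r * res.phi_s2c_r, rel=1e-12)
            # both synchrony routes multiply to the same total
            assert res.phi_s2c_l * res.phi_c_l2r == pytest.approx(
                res.phi_s_l2r * res.phi_s2c_r, rel=1e-10
            )
            for phi in (res.phi_s2c_l, res.phi_c_l2r, res.phi_s_l2r, res.phi_s2c_r):
                assert -1e-12 <= phi <= 1 + 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        tensor = random_tensor(rng)
        scaled = make_tensor(tensor.values * 37.5)
        a, b = var_partition(tensor), var_partition(scaled)
        for name in PartitionResult.CV_FIELDS + PartitionResult.PHI_FIELDS:
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0.5, 5.0, size=(3, 3, 4))
        a = var_partition(make_tensor(values))
        b = var_partition(make_tensor(values[[2, 0, 1]][:, [1, 2, 0]]))
        for name in PartitionResult.CV_FIELDS + PartitionResult.PHI_FIELDS:
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)

    def test_all_zero_tensor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            var_partition(make_tensor(np.zeros((2, 2, 3))))

    def test_constant_series_give_flagged_unit_synchrony(self):
        res = var_partition(make_tensor([[[3, 3, 3]], [[2, 2, 2]]]))
        assert res.phi_s2c_l == 1.0
        assert "phi_s2c_l" in res.degenerate

    def test_variance_scale_squares_the_ratios(self, micro_tensor):
        a = var_partition(micro_tensor, synchrony_scale="cv_ratio")
        b = var_partition(micro_tensor, synchrony_scale="variance")
        for name in PartitionResult.PHI_FIELDS:
            assert getattr(b, name) == pytest.approx(getattr(a, name) ** 2)

    def test_incomplete_units_dropped_before_partition(self):
        values = np.array([[[1, 2, 3], [2, 3, 4]], [[5, 5, 5], [1, 2, 1]]], float)
        observed = np.ones_like(values, bool)
        observed[1, 0, 2] = False  # unit 2 has a missing cell
        full = var_partition(make_tensor(values, observed=observed))
        only_first = var_partition(make_tensor(values[:1]))
        assert full.n_units_excluded == 1
        assert full.cv_s_l == pytest.approx(only_first.cv_s_l)


class TestInvariability:
    def test_reciprocal(self):
        res = var_partition(make_tensor([[[2, 4]]]))
        assert res.inv_c_r == pytest.approx(1 / res.cv_c_r)

    def test_zero_cv_maps_to_infinity_with_flag(self):
        res = PartitionResult(
            cv_s_l=0.5, cv_c_l=0.4, cv_s_r=0.2, cv_c_r=0.0,
            phi_s2c_l=0.8, phi_c_l2r=0.0, phi_s_l2r=0.4, phi_s2c_r=0.0,
        )
        res = invariability(res)
        assert math.isinf(res.inv_c_r)
        assert "inv_c_r_infinite" in res.degenerate
        assert res.inv_s_l == pytest.approx(2.0)

    def test_involution(self):
        res = var_partition(make_tensor([[[1, 3, 2], [2, 5, 4]]]))
        assert 1 / (1 / res.cv_s_l) == pytest.approx(res.cv_s_l)


class TestTaylorFit:
    def test_square_root_scaling_gives_half(self):
        fit = taylor_fit([(1, 1), (4, 2), (16, 4)])
        assert fit.b == pytest.approx(0.5, abs=1e-14)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_cv_gives_slope_one(self):
        fit = taylor_fit([(1, 0.3), (10, 3), (100, 30)])
        assert fit.b == pytest.approx(1.0, abs=1e-12)

    def test_constant_sd_gives_slope_zero(self):
        fit = taylor_fit([(1, 2), (10, 2), (100, 2)])
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_variance_convention_doubles_slope(self):
        fit = taylor_fit([(1, 1), (4, 2), (16, 4)], convention="var_vs_mean")
        assert fit.b == pytest.approx(1.0, abs=1e-14)

    def test_negative_slope_allowed(self):
        fit = taylor_fit([(1, 4), (10, 2), (100, 1)])
        assert fit.b < 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            taylor_fit([(1, 1), (4, 2)])


class TestTaylorUnits:
    def test_population_cardinality(self, micro_tensor):
        pairs, n_excl = taylor_units(micro_tensor, "population")
        assert len(pairs) + n_excl == 4

    def test_constant_series_counted_as_excluded(self):
        tensor = make_tensor([[[1, 2, 3]], [[2, 2, 2]]])
        pairs, n_excl = taylor_units(tensor, "population")
        assert n_excl == 1 and len(pairs) == 1

    def test_community_pairs_match_patch_totals(self, micro_tensor):
        pairs, _ = taylor_units(micro_tensor, "community")
        totals = micro_tensor.values.sum(axis=0)
        expected = sorted(
            (temporal_sd_mean(totals[j])[1], temporal_sd_mean(totals[j])[0])
            for j in range(totals.shape[0])
        )
        assert sorted(pairs) == pytest.approx(expected)

    def test_region_pools_both_levels(self, micro_tensor):
        pop, e1 = taylor_units(micro_tensor, "population")
        com, e2 = taylor_units(micro_tensor, "community")
        reg, e3 = taylor_units(micro_tensor, "region")
        assert len(reg) == len(pop) + len(com)
        assert e3 == e1 + e2
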