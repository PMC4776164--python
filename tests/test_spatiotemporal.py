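import math

import numpy as np
import pytest
from scipy import stats

from rivst import (
    CommunityDataCube,
    SpatialPartition,
    asymptotic_pvalue,
    calibrate_null,
    cube_from_table,
    montecarlo_pvalue,
    permutation_pvalue,
    spatial_vs_seasonal_test,
    sse_seasonal,
    sse_spatial,
    standardize_cube,
    t_statistic,
)
from rivst.io import ValidationError
from rivst.synthetic_data import generate_community

from conftest import survey_config


def random_standardized_cube(rng, I=4, J=3, p=50):
    return standardize_cube(CommunityDataCube(rng.standard_normal((I, J, p))))


class TestStandardize:
    def test_moments_and_idempotence(self, rng):
        cube = CommunityDataCube(rng.standard_normal((4, 3, 20)) * 3 + 1)
        std = standardize_cube(cube)
        flat = std.X.reshape(12, 20)
        assert np.allclose(flat.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(flat.var(axis=0, ddof=1), 1, atol=1e-12)
        again = standardize_cube(std)
        assert np.allclose(again.X, std.X, atol=1e-12)

    def test_constant_taxon_dropped(self, rng):
        X = rng.standard_normal((4, 3, 5))
        X[:, :, 2] = 7.0
        cube = CommunityDataCube(X, taxon_ids=[f"t{k}" for k in range(5)])
        with pytest.warns(UserWarning, match="zero-variance"):
            std = standardize_cube(cube)
        assert std.p == 4
        assert "t2" not in std.taxon_ids


class TestSse:
    def test_constant_within_season_gives_zero_seasonal_sse(self):
        X = np.zeros((4, 3, 2))
        for i in range(4):
            X[i, :, :] = i + 1.0
        assert np.allclose(sse_seasonal(CommunityDataCube(X)), 0)

    def test_constant_within_group_gives_zero_spatial_sse(self, survey_partition):
        X = np.zeros((4, 3, 2))
        X[:, :2, :] = 1.0
        X[:, 2, :] = 9.0
        assert np.allclose(
            sse_spatial(CommunityDataCube(X), survey_partition), 0
        )

    def test_anova_decomposition_bound(self, rng, survey_partition):
        cube = random_standardized_cube(rng)
        n = cube.n
        for sse in (sse_seasonal(cube), sse_spatial(cube, survey_partition)):
            assert np.all(sse >= 0)
            assert np.all(sse <= n - 1 + 1e-9)

    def test_seasonal_term_by_term_oracle(self, rng):
        X = rng.normal(size=(4, 3, 6))
        cube = CommunityDataCube(X)
        expected = np.zeros(6)
        for k in range(6):
            for i in range(4):
                xbar = sum(X[i, j, k] for j in range(3)) / 3
                for j in range(3):
                    expected[k] += (X[i, j, k] - xbar) ** 2
        assert np.allclose(sse_seasonal(cube), expected)

    def test_spatial_term_by_term_oracle(self, rng, survey_partition):
        X = rng.normal(size=(4, 3, 6))
        cube = CommunityDataCube(X)
        expected = np.zeros(6)
        for k in range(6):
            # riverine group mean pools units 1-2 over all 4 seasons (8 samples)
            m1 = sum(X[i, j, k] for i in range(4) for j in range(2)) / 8
            m2 = sum(X[i, 2, k] for i in range(4)) / 4
            for i in range(4):
                for j in range(2):
                    expected[k] += (X[i, j, k] - m1) ** 2
                expected[k] += (X[i, 2, k] - m2) ** 2
        assert np.allclose(sse_spatial(cube, survey_partition), expected)

    def test_singleton_groups_equal_within_unit_ss(self, rng):
        X = rng.normal(size=(4, 3, 5))
        cube = CommunityDataCube(X)
        part = SpatialPartition({1: "a", 2: "b", 3: "c"})
        expected = ((X - X.mean(axis=0, keepdims=True)) ** 2).sum(axis=(0, 1))
        assert np.allclose(sse_spatial(cube, part), expected)


class TestTStatistic:
    def test_worked_asymptotic_pvalue(self):
        assert asymptotic_pvalue(-2.38) == pytest.approx(0.0087, abs=5e-5)

    def test_algebraic_identity(self, rng, survey_partition):
        cube = random_standardized_cube(rng)
        res = t_statistic(cube, survey_partition)
        assert res.T * res.scale + res.centering == pytest.approx(res.sum_diff)
        assert res.centering == pytest.approx(2 * cube.p * 11 / 9)
        assert res.scale == pytest.approx(
            math.sqrt(4 * cube.p * 11**3 / (9**2 * 7))
        )

    def test_equal_sse_gives_minus_centering_over_scale(self, survey_partition):
        # X[i,j,k] = e_i^(k) * f_j with f = (1, -1, 0): season means and both
        # spatial-group means are all zero, so SSE_L(k) = SSE_S(k) = SST(k)
        # for every taxon, sum_diff = 0 and T = -centering/scale exactly
        rng = np.random.default_rng(0)
        e = rng.standard_normal((4, 10))
        f = np.array([1.0, -1.0, 0.0])
        X = np.einsum("ik,j->ijk", e, f)
        cube = standardize_cube(CommunityDataCube(X))
        res = t_statistic(cube, survey_partition)
        assert np.allclose(res.sse_spatial, res.sse_seasonal)
        assert res.sum_diff == pytest.approx(0.0, abs=1e-9)
        assert res.T == pytest.approx(-res.centering / res.scale)

    def test_taxon_order_and_sign_flip_invariance(self, rng, survey_partition):
        cube = random_standardized_cube(rng, p=30)
        t0 = t_statistic(cube, survey_partition).T
        perm = rng.permutation(30)
        flip = np.where(rng.random(30) < 0.5, -1.0, 1.0)
        cube2 = CommunityDataCube(
            cube.X[:, :, perm] * flip, standardized=True
        )
        assert t_statistic(cube2, survey_partition).T == pytest.approx(t0)

    def test_small_n_rejected(self, rng):
        cube = standardize_cube(
            CommunityDataCube(rng.standard_normal((2, 2, 10)))
        )
        with pytest.raises(ValidationError, match="n > 5"):
            t_statistic(cube, SpatialPartition({1: "a", 2: "b"}))

    def test_unstandardized_cube_rejected(self, rng, survey_partition):
        cube = CommunityDataCube(rng.standard_normal((4, 3, 10)))
        with pytest.raises(ValidationError, match="standardized"):
            t_statistic(cube, survey_partition)


class TestMonteCarlo:
    def test_deterministic_and_valid(self, rng, survey_partition):
        cube = random_standardized_cube(rng, p=40)
        a = montecarlo_pvalue(cube, survey_partition, n_sim=199, seed=1)
        b = montecarlo_pvalue(cube, survey_partition, n_sim=199, seed=1)
        assert a.p_value == b.p_value
        assert 0 < a.p_value <= 1
        assert a.method == "montecarlo"

    def test_null_pvalues_roughly_uniform(self, survey_partition):
        rng = np.random.default_rng(2)
        pvals = [
            montecarlo_pvalue(
                random_standardized_cube(rng, p=30),
                survey_partition,
                n_sim=199,
                seed=int(rng.integers(2**31)),
            ).p_value
            for _ in range(200)
        ]
        # calibrated test: empirical rejection near nominal levels
        pvals = np.array(pvals)
        assert abs((pvals <= 0.05).mean() - 0.05) < 0.05
        assert abs((pvals <= 0.5).mean() - 0.5) < 0.12


class TestPermutation:
    def test_three_units_exact_enumeration(self, rng, survey_partition):
        cube = random_standardized_cube(rng, p=20)
        res = permutation_pvalue(cube, survey_partition, n_perm=999)
        assert res.method == "permutation"
        assert len(res.null_sample) == 3
        assert res.p_value in (
            pytest.approx(1 / 3),
            pytest.approx(2 / 3),
            pytest.approx(1.0),
        )

    def test_exact_p_uniform_under_null(self, survey_partition):
        rng = np.random.default_rng(3)
        pvals = [
            permutation_pvalue(
                random_standardized_cube(rng, p=25), survey_partition
            ).p_value
            for _ in range(300)
        ]
        counts = [sum(abs(p - v) < 1e-9 for p in pvals) for v in (1 / 3, 2 / 3, 1.0)]
        assert sum(counts) == 300
        # each achievable value equally likely under exchangeability
        chi2 = sum((c - 100) ** 2 / 100 for c in counts)
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_spatial_signal_ranks_first(self):
        """Strong spatial structure: the observed assignment minimises
        sum_diff among the 3 possible unit labelings in >= 90% of replicates."""
        hits = 0
        reps = 60
        for r in range(reps):
            table, design, _, _ = generate_community(
                survey_config(n_taxa=100, spatial_effect=2.0,
                             seasonal_effect=1.0, seed=900 + r)
            )
            cube, part = cube_from_table(table, design)
            res = permutation_pvalue(standardize_cube(cube), part)
            hits += res.p_value == pytest.approx(1 / 3)
        assert hits >= 0.9 * reps


class TestCalibration:
    def test_mean_matches_exact_null_expectation(self, survey_partition):
        """Under the iid null with same-sample z-scoring the exact mean of
        sum_diff is 2p (the Dirichlet argument), below the asymptotic
        centering 2p(n-1)/(n-3)."""
        cal = calibrate_null(12, 300, survey_partition, n_sim=2000, seed=0)
        assert abs(cal.mean_sum_diff - 2 * 300) < 3 * cal.se_mean_sum_diff
        assert cal.mean_sum_diff + 6 * cal.se_mean_sum_diff < cal.centering_asymptotic

    def test_variance_scales_linearly_in_p(self, survey_partition):
        cal1 = calibrate_null(12, 100, survey_partition, n_sim=3000, seed=1)
        cal2 = calibrate_null(12, 200, survey_partition, n_sim=3000, seed=2)
        ratio = cal2.var_sum_diff / cal1.var_sum_diff
        assert abs(ratio - 2.0) < 0.25

    def test_asymptotic_test_is_miscalibrated_at_survey_n(self, survey_partition):
        cal = calibrate_null(12, 300, survey_partition, n_sim=2000, seed=3)
        assert cal.type_i_error_asymptotic > 0.5  # hence the Monte-Carlo default


class TestEndToEnd:
    def test_detects_dominant_spatial_structure(self):
        table, design, _, _ = generate_community(
            survey_config(seed=21, spatial_effect=2.0, seasonal_effect=1.0)
        )
        res = spatial_vs_seasonal_test(table, design, seed=4)
        assert res.method == "montecarlo"
        assert res.p_value <= 0.05
        assert res.T < 0

    def test_incomplete_crossing_rejected(self):
        from rivst import OtuTable

        table, design, _, _ = generate_community(survey_config(seed=22, n_taxa=40))
        truncated = OtuTable(
            taxon_ids=list(table.taxon_ids),
            sample_ids=list(table.sample_ids[:-1]),
            counts=table.counts[:, :-1],
        )
        with pytest.raises(ValidationError, match="incomplete"):
            cube_from_table(truncated, design[:-1])
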