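"""Dispersal kernel, connectivity, landscape matrix, metapopulation
capacity and the equilibrium prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_landscape, ring_landscape
from metacap.capacity import (SpomParams, build_M, classify_networks,
                              equilibrium_prediction, kernel,
                              mean_field_fixed_point, metapop_capacity,
                              p_lambda_series, patch_connectivity,
                              power_iteration_capacity)
from metacap.landscape import OccupancyHistory, quality_index


class TestKernel:
    @pytest.mark.parametrize("d,alpha,expected", [
        (0.0, 1.0, 1.0),
        (1.0, 1.0, 0.367879),
        (2.0, 0.93, 0.155673),
    ])
    def test_values(self, d, alpha, expected):
        assert kernel(d, alpha) == pytest.approx(expected, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel(-0.1, 1.0)


class TestSpomParams:
    def test_derived_quantities(self):
        p = SpomParams(e=0.38, c=0.11, ex=0.23, im=0.44)
        assert p.delta == pytest.approx(0.38 / 0.11)
        assert p.x == pytest.approx(0.67)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            SpomParams(e=-1.0)


class TestPatchConnectivity:
    def test_empty_occupancy_gives_zero(self, two_patch):
        S = patch_connectivity(two_patch, np.zeros(2), SpomParams())
        assert np.all(S == 0)

    def test_unit_areas_neutralize_exponents(self):
        land = make_landscape([0.0, 1.0])
        S = patch_connectivity(land, np.array([0.0, 1.0]),
                               SpomParams(im=0.7, em=0.9))
        assert S[0] == pytest.approx(np.exp(-1), abs=1e-6)

    def test_linearity_in_occupancy(self):
        rng = np.random.default_rng(2)
        land = make_landscape(list(rng.uniform(0, 5, 12)), list(rng.uniform(0, 5, 12)),
                              areas=list(rng.lognormal(0, 1, 12)))
        p = rng.uniform(0, 0.5, 12)
        S1 = patch_connectivity(land, p, SpomParams())
        S2 = patch_connectivity(land, 2 * p, SpomParams())
        np.testing.assert_allclose(S2, 2 * S1)


class TestBuildM:
    def test_single_patch(self):
        land = make_landscape([0.0])
        with pytest.warns(UserWarning):
            q = quality_index(land)
        M = build_M(land, q, SpomParams())
        res = metapop_capacity(M)
        assert M.shape == (1, 1) and M[0, 0] == 0
        assert res.lambda_M == 0.0

    def test_two_patch_offdiagonal(self):
        land = make_landscape([0.0, 2.0])
        q = quality_index(land)  # identical -> Q = 0
        M = build_M(land, q, SpomParams(alpha=0.8))
        assert M[0, 1] == pytest.approx(np.exp(-1.6))
        assert M[1, 0] == pytest.approx(np.exp(-1.6))

    def test_area_scaling_law(self):
        rng = np.random.default_rng(4)
        land = make_landscape(list(rng.uniform(0, 4, 10)), list(rng.uniform(0, 4, 10)),
                              areas=list(rng.lognormal(0, 0.5, 10)))
        k = 3.0
        land2 = make_landscape(list(land.coords[:, 0]), list(land.coords[:, 1]),
                               areas=list(land.areas * k))
        params = SpomParams()
        q = quality_index(land)
        M1 = build_M(land, q, params)
        M2 = build_M(land2, q, params)
        np.testing.assert_allclose(M2, M1 * k ** (params.x + params.em), rtol=1e-12)
        lam1 = metapop_capacity(M1).lambda_M
        lam2 = metapop_capacity(M2).lambda_M
        assert lam2 == pytest.approx(lam1 * k ** (params.x + params.em), rel=1e-10)


class TestMetapopCapacity:
    def test_two_patch_symmetric(self):
        M = np.array([[0.0, 0.7], [0.7, 0.0]])
        res = metapop_capacity(M)
        assert res.lambda_M == pytest.approx(0.7)
        np.testing.assert_allclose(res.weights, [0.5, 0.5])

    def test_equilateral_triangle(self):
        d = 1.3
        a = np.sqrt(3) / 2
        land = make_landscape([0.0, d, d / 2], [0.0, 0.0, a * d])
        q = quality_index(land)
        res = metapop_capacity(build_M(land, q, SpomParams(alpha=1.0)))
        assert res.lambda_M == pytest.approx(2 * np.exp(-d), rel=1e-10)

    def test_block_diagonal_max_of_blocks(self):
        A = np.array([[0.0, 0.5], [0.5, 0.0]])
        B = np.array([[0.0, 1.5], [1.5, 0.0]])
        M = np.block([[A, np.zeros((2, 2))], [np.zeros((2, 2)), B]])
        res = metapop_capacity(M)
        assert res.lambda_M == pytest.approx(1.5)

    def test_matches_power_iteration_on_random_landscapes(self):
        """Eigen-solver vs brute-force power iteration, 1e-10 relative."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            land = make_landscape(list(rng.uniform(0, 8, 50)),
                                  list(rng.uniform(0, 8, 50)),
                                  areas=list(rng.lognormal(-2, 1.2, 50)))
            M = build_M(land, quality_index(land), SpomParams())
            lam = metapop_capacity(M).lambda_M
            lam_pi = power_iteration_capacity(M)
            assert abs(lam - lam_pi) <= 1e-10 * lam

    def test_monotone_in_area_and_distance(self):
        rng = np.random.default_rng(12)
        land = make_landscape(list(rng.uniform(0, 5, 20)), list(rng.uniform(0, 5, 20)),
                              areas=list(rng.lognormal(0, 0.5, 20)))
        q = quality_index(land)
        params = SpomParams()
        lam0 = metapop_capacity(build_M(land, q, params)).lambda_M
        # grow one patch
        areas = land.areas.copy()
        areas[3] *= 1.5
        land_a = make_landscape(list(land.coords[:, 0]), list(land.coords[:, 1]),
                                areas=list(areas))
        assert metapop_capacity(build_M(land_a, q, params)).lambda_M > lam0
        # move one patch away from the rest
        xs = land.coords[:, 0].copy()
        xs[3] += 30.0
        land_d = make_landscape(list(xs), list(land.coords[:, 1]),
                                areas=list(land.areas))
        assert metapop_capacity(build_M(land_d, q, params)).lambda_M < lam0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            metapop_capacity(np.array([[0.0, np.inf], [1.0, 0.0]]))


class TestPLambdaSeries:
    def test_weighted_average_and_missing(self):
        occ = np.array([[1.0, 0.0, np.nan],
                        [0.0, 0.0, np.nan]])
        hist = OccupancyHistory(years=np.arange(3), occupied=occ)
        pl = p_lambda_series(hist, np.array([0.8, 0.2]))
        assert pl[0] == pytest.approx(0.8)
        assert pl[1] == 0.0
        assert np.isnan(pl[2])

    def test_renormalizes_over_observed(self):
        occ = np.array([[1.0], [np.nan]])
        hist = OccupancyHistory(years=np.arange(1), occupied=occ)
        assert p_lambda_series(hist, np.array([0.3, 0.7]))[0] == pytest.approx(1.0)


class TestEquilibrium:
    @pytest.mark.parametrize("lam,delta,expected", [
        (5.47, 5.47, 0.0),
        (6.1, 5.47, 0.1033),
        (10.94, 5.47, 0.5),
    ])
    def test_prediction(self, lam, delta, expected):
        assert equilibrium_prediction(lam, delta).p_lambda_star == pytest.approx(
            expected, abs=5e-4)

    def test_zero_capacity_nonviable(self):
        pred = equilibrium_prediction(0.0, 5.47)
        assert not pred.viable and pred.p_lambda_star == -np.inf

    def test_classification_strict_inequality(self):
        out = classify_networks([1.0, 6.0, 10.0], 5.47)
        assert out["n_viable"] == 2
        out2 = classify_networks([5.47, 5.47], 5.47)
        assert out2["n_viable"] == 0

    @given(ratio=st.floats(1.2, 5.0))
    @settings(max_examples=10, deadline=None)
    def test_mean_field_fixed_point_matches_capacity_identity(self, ratio, ring60):
        """Weighted mean-field occupancy within 0.05 of 1 - delta/lambda."""
        land, q = ring60
        base = SpomParams(e=0.2, c=1.0, ex=0.25, im=0.2, em=0.2, alpha=1.0)
        res = metapop_capacity(build_M(land, q, base))
        params = base.with_delta(res.lambda_M / ratio)
        p = mean_field_fixed_point(land, q, params)
        assert abs(float(res.weights @ p) - (1 - 1 / ratio)) <= 0.05
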