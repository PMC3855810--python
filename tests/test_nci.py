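"""Competition index, (alpha, beta) grid search, and the zero-intercept
median-regression conversion to the log(CAI) scale."""

import numpy as np
import pytest

from treelight import nci, synthetic
from treelight.allometry import AllometryConfig
from treelight.census import CensusSnapshot, TreeRecord, partition_core
from treelight.nci import (
    DEFAULT_ALPHA_SET,
    NCIConfig,
    apply_conversion,
    compute_nci,
    fit_conversion,
    grid_search,
    neighbor_pairs,
)


def snapshot_of(trees, width=100.0, height=100.0):
    return CensusSnapshot.from_records(0, width, height, trees)


TALL = AllometryConfig()  # any tree here is taller than the 2 m reference


class TestComputeNCI:
    def test_single_neighbor_one_term_sum(self):
        snap = snapshot_of([TreeRecord("n1", "sp", 51.0, 50.0, 100.0)])
        val = compute_nci(
            np.array([[50.0, 50.0]]), 2.0, snap, TALL, NCIConfig(alpha=1, beta=1)
        )
        assert val[0] == pytest.approx(10.0)  # dbh 10 cm at 1 m

    def test_eightfold_size_and_distance_scaling(self):
        base = snapshot_of([TreeRecord("n1", "sp", 52.0, 50.0, 100.0)])
        double_dbh = snapshot_of([TreeRecord("n1", "sp", 52.0, 50.0, 200.0)])
        double_dist = snapshot_of([TreeRecord("n1", "sp", 54.0, 50.0, 100.0)])
        pt = np.array([[50.0, 50.0]])
        a3 = NCIConfig(alpha=3, beta=0)
        b3 = NCIConfig(alpha=0, beta=3)
        assert compute_nci(pt, 2.0, double_dbh, TALL, a3)[0] == pytest.approx(
            8 * compute_nci(pt, 2.0, base, TALL, a3)[0]
        )
        assert compute_nci(pt, 2.0, double_dist, TALL, b3)[0] == pytest.approx(
            compute_nci(pt, 2.0, base, TALL, b3)[0] / 8
        )

    def test_zero_exponents_count_neighbors(self):
        trees = [TreeRecord(f"n{i}", "sp", 50.0 + i, 50.0, 100.0) for i in range(1, 6)]
        snap = snapshot_of(trees)
        val = compute_nci(np.array([[50.0, 50.0]]), 2.0, snap, TALL, NCIConfig(0, 0))
        assert val[0] == 5.0

    def test_taller_only_rule_excludes_short_neighbors(self):
        # height = 3 * dbh_cm^0.6; dbh 10 mm -> 3 m > 2 m; focal height 10 m
        snap = snapshot_of([TreeRecord("n1", "sp", 51.0, 50.0, 10.0)])
        val = compute_nci(np.array([[50.0, 50.0]]), 10.0, snap, TALL, NCIConfig(1, 1))
        assert val[0] == 0.0

    def test_neighbors_beyond_radius_ignored(self):
        snap = snapshot_of([TreeRecord("n1", "sp", 85.0, 50.0, 500.0)])
        val = compute_nci(np.array([[50.0, 50.0]]), 2.0, snap, TALL, NCIConfig(1, 1))
        assert val[0] == 0.0  # 35 m away, radius 30 m

    def test_distance_floor_applied(self):
        snap = snapshot_of([TreeRecord("n1", "sp", 50.0, 50.0, 100.0)])
        val = compute_nci(np.array([[50.0, 50.0]]), 2.0, snap, TALL, NCIConfig(0, 1))
        assert val[0] == pytest.approx(1.0 / 0.1)

    def test_matches_brute_force_on_random_stand(self, small_stand, allometry):
        """Spatial-index implementation equals the O(n^2) double loop."""
        config = NCIConfig(alpha=1.6, beta=0.4)
        grid = partition_core(90, 90, 15, 5)
        centers = grid.cell_centers()[::7]
        fast = compute_nci(centers, 2.0, small_stand, allometry, config)
        alive = small_stand.alive
        xs = alive["x"].to_numpy()
        ys = alive["y"].to_numpy()
        dbh_cm = alive["dbh_mm"].to_numpy() / 10.0
        heights = allometry.height(alive["dbh_mm"].to_numpy())
        slow = np.zeros(len(centers))
        for i, (cx, cy) in enumerate(centers):
            total = 0.0
            for x, y, dc, h in zip(xs, ys, dbh_cm, heights):
                dist = np.hypot(x - cx, y - cy)
                if dist <= config.radius and h > 2.0:
                    total += dc**config.alpha / max(dist, config.dist_floor) ** config.beta
            slow[i] = total
        np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_focal_tree_excluded_from_own_neighborhood(self):
        snap = snapshot_of([TreeRecord("t1", "sp", 50.0, 50.0, 100.0)])
        field = nci.nci_for_trees(snap, TALL, NCIConfig(1, 1))
        assert field.values[0] == 0.0

    def test_removing_a_neighbor_never_increases_nci(self, small_stand, allometry):
        pt = np.array([[45.0, 45.0]])
        config = NCIConfig(1.6, 0.4)
        full = compute_nci(pt, 2.0, small_stand, allometry, config)[0]
        reduced_df = small_stand.trees.iloc[1:]
        reduced = CensusSnapshot(0, 90, 90, reduced_df.copy())
        assert compute_nci(pt, 2.0, reduced, allometry, config)[0] <= full


class TestGridSearch:
    def test_evaluates_256_combinations(self, small_stand, allometry):
        grid = partition_core(90, 90, 15, 5)
        pairs = neighbor_pairs(
            grid.cell_centers()[::4], 2.0, small_stand, allometry, NCIConfig()
        )
        rng = np.random.default_rng(0)
        y = rng.standard_normal(pairs.n_focal)
        result = grid_search([pairs], [y])
        assert result.n_combinations == 256
        assert result.r_pooled.shape == (16, 16)

    def test_recovers_planted_exponent_pair(self, small_stand, allometry):
        grid = partition_core(90, 90, 15, 5)
        pairs = neighbor_pairs(
            grid.cell_centers(), 2.0, small_stand, allometry, NCIConfig()
        )
        planted = pairs.nci(1.6, 0.4)
        rng = np.random.default_rng(1)
        log_cai = -0.002 * planted + 0.01 * rng.standard_normal(pairs.n_focal)
        result = grid_search([pairs], [log_cai])
        assert (result.alpha_star, result.beta_star) == (1.6, 0.4)
        assert result.r_pooled[8, 2] == pytest.approx(-1.0, abs=0.01)

    def test_unrelated_light_still_selects_unique_pair(self, small_stand, allometry):
        grid = partition_core(90, 90, 15, 5)
        pairs = neighbor_pairs(
            grid.cell_centers()[::4], 2.0, small_stand, allometry, NCIConfig()
        )
        rng = np.random.default_rng(2)
        result = grid_search([pairs], [rng.standard_normal(pairs.n_focal)])
        assert np.isfinite(result.alpha_star) and np.isfinite(result.beta_star)
        assert np.nanmax(np.abs(result.r_pooled)) < 0.5

    def test_surface_is_deterministic(self, small_stand, allometry):
        grid = partition_core(90, 90, 15, 5)
        pairs = neighbor_pairs(
            grid.cell_centers()[::4], 2.0, small_stand, allometry, NCIConfig()
        )
        y = np.linspace(-3, 0, pairs.n_focal)
        r1 = grid_search([pairs], [y]).r_pooled
        r2 = grid_search([pairs], [y]).r_pooled
        np.testing.assert_array_equal(r1, r2)


class TestConversion:
    def test_exact_line_interpolated(self):
        x = np.linspace(0, 10, 20)
        coeffs = fit_conversion(x, -0.05 * x, degree=1)
        assert coeffs.b1 == pytest.approx(-0.05, abs=1e-8)

    def test_median_regression_robust_to_heavy_tails(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.uniform(0, 50, n)
        noise = rng.standard_t(df=1, size=n) * 0.5  # Cauchy-like, symmetric
        coeffs = fit_conversion(x, -0.05 * x + noise, degree=1)
        assert coeffs.b1 == pytest.approx(-0.05, abs=0.01)

    def test_agrees_with_statsmodels_quantreg(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 800
        x = rng.uniform(0, 30, n)
        y = -0.04 * x - 0.001 * x**2 + rng.laplace(0, 0.3, n)
        ours = fit_conversion(x, y, degree=2)
        X = np.column_stack([x, x**2])
        theirs = sm.QuantReg(y, X).fit(q=0.5).params
        assert ours.b1 == pytest.approx(theirs[0], abs=2e-3)
        assert ours.b2 == pytest.approx(theirs[1], abs=1e-4)

    def test_median_property_of_residual_signs(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.uniform(0, 50, n)
        y = -0.05 * x + rng.normal(0, 0.5, n)
        coeffs = fit_conversion(x, y, degree=1)
        resid = y - apply_conversion(x, coeffs)
        assert np.mean(resid > 0) == pytest.approx(0.5, abs=0.03)

    def test_zero_maps_to_zero_hence_full_irradiance(self):
        x = np.linspace(0, 10, 50)
        coeffs = fit_conversion(x, -0.1 * x - 0.002 * x**2, degree=2)
        log_cai_at_zero = apply_conversion(np.array([0.0]), coeffs)[0]
        assert log_cai_at_zero == 0.0
        assert np.exp(log_cai_at_zero) == 1.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_conversion(np.ones(10), np.linspace(0, 1, 10))

    def test_quadratic_evaluation_matches_hand_polynomial(self):
        from treelight.nci import ConversionCoeffs

        coeffs = ConversionCoeffs(b1=-0.04, b2=-0.001)
        x = np.array([0.0, 1.0, 10.0])
        np.testing.assert_allclose(
            apply_conversion(x, coeffs), -0.04 * x - 0.001 * x**2
        )
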