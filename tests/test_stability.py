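import numpy as np
import pytest

from adcstab.stability import (
    CategoryMatrix,
    DRInputs,
    bootstrap_ci,
    ccc,
    category_stability,
    dynamic_range,
    occc,
)


class TestOccc:
    def test_identical_columns_give_perfect_agreement(self):
        v = np.tile(np.arange(10.0)[:, None], (1, 5))
        assert occc(v) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_inverse_match_gives_minus_one(self):
        v = np.column_stack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert occc(v) == pytest.approx(-1.0)

    def test_hand_computed_with_mean_shift(self):
        # means 2 and 3, variances 2/3, covariance 2/3 -> 2*(2/3)/(4/3 + 1)
        v = np.column_stack([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert occc(v) == pytest.approx(4.0 / 7.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_reduces_to_lins_ccc_for_two_raters(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 0.4, 25)
        y = x + rng.normal(0.1, 0.2, 25)
        assert occc(np.column_stack([x, y])) == pytest.approx(ccc(x, y), rel=1e-12)

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 1.3), (10.0, -4.0)])
    def test_invariant_under_common_affine_map(self, a, b):
        rng = np.random.default_rng(0)
        v = rng.normal(1.0, 0.3, (20, 5)) + rng.normal(0, 0.05, (20, 5))
        assert occc(a * v + b) == pytest.approx(occc(v), rel=1e-10)

    def test_all_constant_columns_degenerate(self):
        m = CategoryMatrix(np.ones((10, 5)))
        assert np.isnan(occc(m))

    def test_rows_with_missing_values_dropped_pairwise(self):
        v = np.tile(np.arange(6.0)[:, None], (1, 3))
        v[2, 1] = np.nan
        m = CategoryMatrix(v)
        kept, dropped = m.complete_rows()
        assert kept.shape == (5, 3) and dropped == 1
        assert occc(m) == pytest.approx(1.0)

    def test_requires_three_lesions(self):
        with pytest.raises(ValueError):
            occc(np.ones((2, 5)))


class TestDynamicRange:
    def test_identical_retests_give_one(self):
        d = DRInputs.from_vectors(np.array([0.0, 5.0, 10.0]), np.tile([0.0, 5.0, 10.0], (4, 1)))
        assert dynamic_range(d) == pytest.approx(1.0)

    def test_hand_computed_single_retest(self):
        d = DRInputs.from_vectors(np.array([0.0, 5.0, 10.0]), np.array([[1.0, 5.0, 9.0]]))
        assert dynamic_range(d) == pytest.approx(1.0 - (2.0 / 3.0) / 10.0)  # 0.9333...

    def test_four_retest_average(self):
        test = np.array([0.0, 5.0, 10.0])
        retests = np.array(
            [[1.0, 5.0, 9.0], [0.0, 5.0, 10.0], [0.0, 5.0, 10.0], [0.0, 5.0, 10.0]]
        )
        d = DRInputs.from_vectors(test, retests)
        assert dynamic_range(d) == pytest.approx(np.mean([0.93333333333, 1, 1, 1]))

    def test_decreases_as_any_difference_grows(self):
        test = np.array([0.0, 5.0, 10.0])
        base = np.array([[1.0, 5.0, 9.0]])
        worse = np.array([[1.0, 5.0, 7.0]])
        assert dynamic_range(DRInputs.from_vectors(test, worse)) < dynamic_range(
            DRInputs.from_vectors(test, base)
        )

    def test_zero_range_is_degenerate(self):
        d = DRInputs.from_vectors(np.full(5, 2.0), np.full((4, 5), 2.0))
        assert np.isnan(dynamic_range(d))

    def test_warns_below_zero(self):
        d = DRInputs.from_vectors(
            np.array([0.0, 0.5, 1.0]), np.array([[5.0, 5.0, 5.0]])
        )
        with pytest.warns(UserWarning):
            assert dynamic_range(d) < 0.0


class TestBootstrap:
    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(1)
        v = rng.normal(1.0, 0.3, (15, 5)) + rng.normal(0, 0.03, (15, 5))
        assert bootstrap_ci("occc", v, B=200, seed=42) == bootstrap_ci(
            "occc", v, B=200, seed=42
        )

    def test_perfect_agreement_collapses_interval(self):
        v = np.tile(np.arange(8.0)[:, None], (1, 5))
        lo, hi = bootstrap_ci("occc", v, B=100, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_point_estimate_inside_interval(self):
        rng = np.random.default_rng(3)
        v = rng.normal(1.0, 0.3, 30)[:, None] + rng.normal(0, 0.05, (30, 5))
        point = occc(v)
        lo, hi = bootstrap_ci("occc", v, B=1000, seed=5)
        assert lo <= point <= hi

    def test_coverage_of_known_occc_under_moderate_noise(self):
        """x_ij = t_i + e_ij with var(t)=1, var(e)=0.25 gives a true OCCC of
        1/1.25 = 0.8; the 95% percentile interval should cover it ~95% of the
        time (within 5 points) over repeated cohorts."""
        rng = np.random.default_rng(123)
        true = 0.8
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            t = rng.standard_normal(100)
            x = t[:, None] + rng.standard_normal((100, 5)) * 0.5
            lo, hi = bootstrap_ci("occc", x, B=500, seed=s)
            hits += lo <= true <= hi
        assert abs(hits / n_sim - 0.95) <= 0.05

    def test_dr_statistic_supported(self):
        rng = np.random.default_rng(9)
        v = np.sort(rng.uniform(0, 10, 20))[:, None] + rng.normal(0, 0.1, (20, 5))
        lo, hi = bootstrap_ci("dr", v, B=300, seed=2)
        assert 0.8 < lo <= hi <= 1.0


def test_category_stability_bundles_statistics():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.5, 2.5, 25)
    v = base[:, None] + rng.normal(0, 0.02, (25, 5))
    out = category_stability(v, B=100, seed=0)
    assert out["occc"] > 0.99 and out["dr"] > 0.95
    assert out["occc_lo"] <= out["occc"] <= out["occc_hi"]
    assert out["n_lesions"] == 25 and out["n_dropped"] == 0
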