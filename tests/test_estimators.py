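"""Estimator suite: Wald, IVW, Egger, weighted median/mode, Q, radial scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import (
    cochran_q,
    egger,
    estimate_all,
    ivw,
    radial_scan,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrkit.exceptions import (
    AllOutliersError,
    DegenerateDesignError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
    ValidationError,
)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,sx,by,sy,beta,se",
        [
            (0.5, 0.01, 0.1, 0.02, 0.2, 0.04),
            (1.0, 0.1, 0.0, 0.05, 0.0, 0.05),
            (-0.5, 0.01, 0.1, 0.02, -0.2, 0.04),
        ],
    )
    def test_formula(self, bx, sx, by, sy, beta, se):
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


def _random_h(make_h, rng, J):
    return make_h(
        rng.normal(0, 0.2, J) + 0.05,
        rng.normal(0, 0.1, J),
        se_y=rng.uniform(0.01, 0.2, J),
    )


class TestIVW:
    def test_single_snp_reduces_to_wald(self, make_h):
        h = make_h([0.5], [0.1], se_y=[0.02])
        est = ivw(h)
        w = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(w.beta)
        assert est.se == pytest.approx(w.se)

    def test_duplicated_snp_halves_fixed_variance(self, make_h):
        h1 = make_h([0.5], [0.1], se_y=[0.02])
        h2 = make_h([0.5, 0.5], [0.1, 0.1], se_y=[0.02, 0.02])
        e1, e2 = ivw(h1), ivw(h2, model="fixed")
        assert e2.beta == pytest.approx(e1.beta)
        assert e2.se == pytest.approx(e1.se / np.sqrt(2))

    def test_matches_statsmodels_wls_through_origin(self, make_h):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        h = _random_h(make_h, rng, 8)
        fit = sm.WLS(h.beta_y, h.beta_x, weights=h.se_y**-2).fit()
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_matches_normal_equations_oracle(self, make_h):
        rng = np.random.default_rng(4)
        for _ in range(20):
            h = _random_h(make_h, rng, int(rng.integers(3, 10)))
            w = h.se_y**-2.0
            oracle = np.sum(w * h.beta_x * h.beta_y) / np.sum(w * h.beta_x**2)
            assert ivw(h).beta == pytest.approx(oracle, abs=1e-12)

    def test_fixed_se_never_exceeds_random_se(self, make_h):
        rng = np.random.default_rng(9)
        for _ in range(20):
            h = _random_h(make_h, rng, 6)
            assert ivw(h, model="fixed").se <= ivw(h, model="random").se + 1e-15

    def test_negation_invariance(self, make_h):
        rng = np.random.default_rng(2)
        h = _random_h(make_h, rng, 7)
        flipped = make_h(-h.beta_x, -h.beta_y, se_y=h.se_y)
        assert ivw(h).beta == pytest.approx(ivw(flipped).beta)

    def test_all_zero_exposure_effects_degenerate(self, make_h):
        with pytest.raises(DegenerateDesignError):
            ivw(make_h([0.0, 0.0], [0.1, 0.2]))


class TestEgger:
    def test_exact_linear_fit(self, make_h):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_h(bx, 0.1 + 0.3 * bx)
        est = egger(h)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls(self, make_h):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        h = _random_h(make_h, rng, 9)
        h.beta_x = np.abs(h.beta_x)  # already oriented
        X = sm.add_constant(h.beta_x)
        fit = sm.WLS(h.beta_y, X, weights=h.se_y**-2).fit()
        est = egger(h)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        # statsmodels always applies the residual scale; ours floors it at 1
        q_over_df = est.q / (len(h) - 2)
        if q_over_df >= 1:
            assert est.se == pytest.approx(fit.bse[1], rel=1e-8)

    def test_three_points_match_2x2_solve(self, make_h):
        h = make_h([0.1, 0.25, 0.4], [0.03, 0.1, 0.09], se_y=[0.02, 0.05, 0.03])
        w = h.se_y**-2.0
        A = np.array([[w.sum(), (w * h.beta_x).sum()],
                      [(w * h.beta_x).sum(), (w * h.beta_x**2).sum()]])
        c = np.array([(w * h.beta_y).sum(), (w * h.beta_x * h.beta_y).sum()])
        icpt, slope = np.linalg.solve(A, c)
        est = egger(h)
        assert est.intercept == pytest.approx(icpt, abs=1e-12)
        assert est.beta == pytest.approx(slope, abs=1e-12)

    def test_orientation_invariance(self, make_h):
        rng = np.random.default_rng(8)
        h = _random_h(make_h, rng, 6)
        s = np.array([1, -1, 1, -1, -1, 1.0])
        flipped = make_h(s * h.beta_x, s * h.beta_y, se_y=h.se_y)
        assert egger(h).beta == pytest.approx(egger(flipped).beta)
        assert egger(h).intercept == pytest.approx(egger(flipped).intercept)

    def test_needs_three_instruments(self, make_h):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_h([0.1, 0.2], [0.02, 0.05]))

    def test_constant_exposure_effects_degenerate(self, make_h):
        with pytest.raises(DegenerateDesignError):
            egger(make_h([0.2, 0.2, 0.2], [0.01, 0.02, 0.03]))


class TestWeightedMedian:
    def test_equal_weight_examples(self, make_h):
        h = make_h([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert weighted_median(h, n_boot=2, seed=0).beta == pytest.approx(2.0)
        h4 = make_h([1.0] * 4, [1.0, 2.0, 3.0, 4.0])
        assert weighted_median(h4, n_boot=2, seed=0).beta == pytest.approx(2.5)

    def test_dominant_weight_limit(self, make_h):
        # one SNP holds essentially all weight via a tiny outcome SE
        h = make_h([1.0, 1.0, 1.0], [0.7, 2.0, 3.0], se_y=[1e-4, 0.9, 0.9])
        assert weighted_median(h, n_boot=2, seed=0).beta == pytest.approx(0.7, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=15).filter(lambda v: len(v) % 2 == 1))
    def test_equal_weights_odd_j_is_sample_median(self, ratios):
        from mrkit import HarmonizedSet

        J = len(ratios)
        h = HarmonizedSet(
            snp_ids=[f"s{i}" for i in range(J)],
            beta_x=np.ones(J), se_x=np.full(J, 0.01),
            beta_y=np.array(ratios), se_y=np.ones(J),
            eaf=np.full(J, 0.3), n_x=np.full(J, 1e4), n_y=np.full(J, 1e4),
        )
        est = weighted_median(h, n_boot=2, seed=1)
        assert est.beta == pytest.approx(float(np.median(ratios)), abs=1e-9)

    def test_zero_exposure_effect_names_snp(self, make_h):
        h = make_h([0.5, 0.0], [0.1, 0.1])
        with pytest.raises(UndefinedRatioError, match="rs2"):
            weighted_median(h, n_boot=2, seed=0)

    def test_bootstrap_seed_reproducible(self, make_h):
        rng = np.random.default_rng(3)
        h = _random_h(make_h, rng, 10)
        e1 = weighted_median(h, n_boot=50, seed=42)
        e2 = weighted_median(h, n_boot=50, seed=42)
        assert e1.se == e2.se


class TestWeightedMode:
    def test_point_mass(self, make_h):
        h = make_h([1.0, 1.0, 1.0], [0.7, 0.7, 0.7])
        assert weighted_mode(h, n_boot=2, seed=0).beta == pytest.approx(0.7, abs=1e-6)

    def test_bimodal_majority_cluster(self, make_h):
        h = make_h([1.0] * 8, [0.2] * 6 + [1.0] * 2)
        est = weighted_mode(h, bandwidth_factor=0.3, n_boot=2, seed=0)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_dominant_weight_limit(self, make_h):
        h = make_h([1.0, 1.0, 1.0], [0.7, 2.0, 2.5], se_y=[0.001, 0.9, 0.9])
        assert weighted_mode(h, n_boot=2, seed=0).beta == pytest.approx(0.7, abs=0.02)


class TestCochranQ:
    def test_identical_ratios_no_heterogeneity(self, make_h):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_h(bx, 0.4 * bx)
        fit = ivw(h)
        q, df, p = cochran_q(h, fit)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_two_snp_hand_computed(self, make_h):
        # ratios 0.2 and 0.4, weights (bx/sy)^2 = 25 and 100
        h = make_h([0.5, 1.0], [0.1, 0.4], se_y=[0.1, 0.1])
        fit = ivw(h)
        beta = (25 * 0.2 + 100 * 0.4) / 125.0
        q_hand = 25 * (0.2 - beta) ** 2 + 100 * (0.4 - beta) ** 2
        q, df, _ = cochran_q(h, fit)
        assert fit.beta == pytest.approx(beta)
        assert q == pytest.approx(q_hand)
        assert df == 1

    def test_egger_uses_line_residuals(self, make_h):
        bx = np.array([0.1, 0.2, 0.3, 0.45])
        h = make_h(bx, 0.05 + 0.3 * bx + np.array([0.001, -0.002, 0.0015, 0.0]))
        e = egger(h)
        q, df, _ = cochran_q(h, e)
        assert df == 2
        assert q == pytest.approx(e.q)


class TestRadialScan:
    def test_homogeneous_no_outliers(self, make_h):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_h(bx, 0.25 * bx)
        scan = radial_scan(h)
        assert scan.outlier_ids == []
        assert scan.reestimate.beta == pytest.approx(ivw(h).beta)

    def test_gross_outlier_flagged_under_both_rules(self, make_h):
        rng = np.random.default_rng(0)
        J = 21
        bx = rng.uniform(0.1, 0.5, J)
        by = 0.2 * bx
        by[-1] += 0.5  # one gross outlier
        h = make_h(bx, by, se_y=np.full(J, 0.05))
        for rule in ("fraction", "chi2"):
            scan = radial_scan(h, rule=rule)
            assert scan.outlier_ids == ["rs21"]
        scan = radial_scan(h)
        frac = scan.q_contributions[-1] / scan.q_contributions.sum()
        assert frac > 0.5

    def test_contributions_sum_to_ivw_q(self, make_h):
        rng = np.random.default_rng(7)
        h = _random_h(make_h, rng, 12)
        scan = radial_scan(h)
        assert scan.q_contributions.sum() == pytest.approx(scan.original.q, abs=1e-8)

    def test_equal_contributions_all_flagged_is_error(self, make_h):
        # 10 SNPs each contributing exactly 10% > 5% threshold
        bx = np.ones(10)
        by = np.array([0.1, 0.3] * 5)
        h = make_h(bx, by, se_y=np.ones(10))
        with pytest.raises(AllOutliersError):
            radial_scan(h, rule="fraction", fraction_threshold=0.05)


def test_estimate_all_rejects_unknown_method(make_h):
    h = make_h([0.1, 0.2, 0.3], [0.02, 0.05, 0.06])
    with pytest.raises(ValidationError, match="unknown method"):
        estimate_all(h, methods=["ivw", "presso"])
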