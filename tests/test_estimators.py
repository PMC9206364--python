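import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomr.estimators import (
    InsufficientInstrumentsError,
    MRResult,
    bonferroni_threshold,
    classify_significance,
    cochran_q,
    egger_arrays,
    ivw,
    ivw_arrays,
    leave_one_out,
    mr_egger,
    mr_presso,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from cardiomr.harmonize import HarmonizedSet
from cardiomr.simulate import Pleiotropy, SimulationConfig, draw_effects


def hset_from(bx, sx, by, sy):
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_closed_form(self):
        res = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(0.1, abs=1e-12)

    def test_unit_instrument(self):
        assert wald_ratio(1.0, 0.01, 0.123, 0.01).estimate == pytest.approx(0.123)

    def test_sign_symmetry(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.01, -0.05, 0.01)
        assert a.estimate == b.estimate and a.se == b.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_hand_computed_weighted_mean(self):
        # ratios (0.2, 0.05), first-order weights (100, 400) -> 0.08
        hset = hset_from([0.1, 0.2], [0.01, 0.01], [0.02, 0.01], [0.01, 0.01])
        res, _ = ivw(hset)
        assert res.estimate == pytest.approx(0.08, abs=1e-12)

    def test_homogeneous_ratios_q_zero_fixed_equals_random(self):
        bx = np.array([0.1, 0.2, 0.4])
        hset = hset_from(bx, 0.01 * np.ones(3), 0.5 * bx, 0.01 * np.ones(3))
        fixed, het = ivw(hset, model="fixed")
        random_, _ = ivw(hset, model="random")
        assert fixed.estimate == pytest.approx(0.5, abs=1e-12)
        assert het.Q == pytest.approx(0.0, abs=1e-18)
        assert fixed.se == pytest.approx(random_.se, abs=1e-15)

    def test_single_snp_equals_wald(self):
        hset = hset_from([0.1], [0.01], [0.05], [0.01])
        res, _ = ivw(hset)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert res.estimate == wald.estimate and res.se == wald.se

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_wls_through_origin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(3, 40))
        bx = rng.normal(0.2, 0.1, j)
        bx[np.abs(bx) < 1e-3] = 1e-3
        by = rng.normal(0, 0.1, j)
        sy = rng.uniform(0.005, 0.05, j)
        est, _, _ = ivw_arrays(bx, by, sy)
        # independent oracle: WLS of by on bx through origin, weights 1/sy^2
        oracle = np.linalg.lstsq(
            (bx / sy)[:, None], by / sy, rcond=None
        )[0][0]
        assert est == pytest.approx(oracle, abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_fixed_se_never_exceeds_random_se(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(2, 30))
        hset = hset_from(
            rng.uniform(0.05, 0.4, j), rng.uniform(0.001, 0.01, j),
            rng.normal(0, 0.1, j), rng.uniform(0.005, 0.05, j),
        )
        fixed, _ = ivw(hset, model="fixed")
        random_, _ = ivw(hset, model="random")
        assert fixed.se <= random_.se + 1e-15

    def test_no_instruments_error(self):
        hset = hset_from([], [], [], [])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hset)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.1 + 0.3 * bx
        slope, icpt, het = mr_egger(hset_from(bx, 0.01 * np.ones(5), by, 0.01 * np.ones(5)))
        assert slope.estimate == pytest.approx(0.3, abs=1e-10)
        assert icpt.estimate == pytest.approx(0.1, abs=1e-10)
        assert het.Q == pytest.approx(0.0, abs=1e-16)

    def test_intercept_constrained_to_zero_reproduces_fixed_ivw(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.4, 20)
        by = rng.normal(0.3 * bx, 0.02)
        sy = np.full(20, 0.02)
        # through-origin WLS (Egger without intercept) is exactly fixed IVW
        origin = np.linalg.lstsq((bx / sy)[:, None], by / sy, rcond=None)[0][0]
        hset = hset_from(bx, np.full(20, 0.003), by, sy)
        fixed, _ = ivw(hset, model="fixed")
        assert fixed.estimate == pytest.approx(origin, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.4, 10)
        by = rng.normal(0.05 + 0.3 * bx, 0.01)
        base = egger_arrays(bx, np.full(10, 0.003), by, np.full(10, 0.01))
        flipped = egger_arrays(-bx, np.full(10, 0.003), -by, np.full(10, 0.01))
        assert flipped[0] == pytest.approx(base[0], abs=1e-12)  # slope
        assert flipped[2] == pytest.approx(base[2], abs=1e-12)  # intercept

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset_from([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        assert weighted_median_point([0.1, 0.2, 0.9], [1, 1, 1]) == pytest.approx(0.2)

    def test_dominant_weight_returns_that_ratio(self):
        assert weighted_median_point([0.9, 0.1, 0.2], [0.6, 0.2, 0.2]) == pytest.approx(0.9)

    @pytest.mark.parametrize("j", [5, 9, 15])
    def test_equal_weights_odd_j_equals_sample_median(self, j, rng):
        ratios = rng.normal(0, 1, j)
        assert weighted_median_point(ratios, np.ones(j)) == pytest.approx(
            np.median(ratios), abs=1e-12
        )

    def test_bootstrap_se_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.4, 20)
        hset = hset_from(bx, np.full(20, 0.005), 0.3 * bx + rng.normal(0, 0.01, 20),
                         np.full(20, 0.01))
        a = weighted_median(hset, n_boot=200, seed=42)
        b = weighted_median(hset, n_boot=200, seed=42)
        assert a.se == b.se and a.estimate == b.estimate


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance_of_all_estimators(c, rng):
    """gamma -> c*gamma divides theta-hat by c; Gamma -> -Gamma negates it."""
    bx = rng.uniform(0.1, 0.4, 25)
    sx = np.full(25, 0.005)
    by = rng.normal(0.3 * bx, 0.02)
    sy = np.full(25, 0.02)
    base_ivw, _, _ = ivw_arrays(bx, by, sy)
    scaled_ivw, _, _ = ivw_arrays(c * bx, by, sy)
    assert scaled_ivw == pytest.approx(base_ivw / c, abs=1e-12)
    neg_ivw, _, _ = ivw_arrays(bx, -by, sy)
    assert neg_ivw == pytest.approx(-base_ivw, abs=1e-12)

    base_sl = egger_arrays(bx, sx, by, sy)[0]
    assert egger_arrays(c * bx, sx, by, sy)[0] == pytest.approx(base_sl / c, abs=1e-12)
    assert egger_arrays(bx, sx, -by, sy)[0] == pytest.approx(-base_sl, abs=1e-12)

    base_wm = weighted_median_point(by / bx, bx**2 / sy**2)
    scaled_wm = weighted_median_point(by / (c * bx), (c * bx) ** 2 / sy**2)
    assert scaled_wm == pytest.approx(base_wm / c, abs=1e-12)


class TestCochranQ:
    def test_homogeneous_q_zero_p_one(self):
        bx = np.array([0.1, 0.2, 0.3])
        hset = hset_from(bx, 0.01 * np.ones(3), 0.4 * bx, 0.01 * np.ones(3))
        for scheme in ("first_order", "modified"):
            rep = cochran_q(hset, weights=scheme)
            assert rep.Q == pytest.approx(0.0, abs=1e-16)
            assert rep.pvalue == pytest.approx(1.0)

    def test_chi_square_calibration_mean_q(self):
        """Homogeneous data, J=20: E[Q] is about J-1 under the null."""
        config = SimulationConfig(J=20, theta=0.2, seed=0)
        qs = []
        for s in np.random.SeedSequence(77).spawn(500):
            e = draw_effects(config, np.random.default_rng(s))
            hset = hset_from(e["beta_exp_obs"], e["se_exp"],
                             e["beta_out_obs"], e["se_out"])
            qs.append(cochran_q(hset, weights="modified").Q)
        assert np.mean(qs) == pytest.approx(19, rel=0.08)

    def test_planted_heterogeneity_detected(self):
        config = SimulationConfig(
            J=30, theta=0.2, seed=0,
            pleiotropy=Pleiotropy("balanced", sigma_alpha=0.05),
        )
        rejections = 0
        for s in np.random.SeedSequence(78).spawn(100):
            e = draw_effects(config, np.random.default_rng(s))
            hset = hset_from(e["beta_exp_obs"], e["se_exp"],
                             e["beta_out_obs"], e["se_out"])
            rejections += cochran_q(hset).pvalue < 0.05
        assert rejections > 50


class TestLeaveOneOut:
    def _hset(self, rng, outlier=False):
        bx = rng.uniform(0.1, 0.4, 20)
        by = 0.3 * bx + rng.normal(0, 0.01, 20)
        if outlier:
            by[0] += 0.5
        return hset_from(bx, np.full(20, 0.005), by, np.full(20, 0.01))

    def test_output_length_equals_j(self, rng):
        table = leave_one_out(self._hset(rng))
        assert len(table) == 20

    def test_identical_snps_give_identical_estimates(self):
        hset = hset_from([0.2] * 5, [0.01] * 5, [0.1] * 5, [0.01] * 5)
        table = leave_one_out(hset)
        full, _ = ivw(hset)
        assert np.allclose(table["estimate"], full.estimate)

    def test_planted_outlier_has_largest_influence(self, rng):
        hset = self._hset(rng, outlier=True)
        table = leave_one_out(hset)
        full, _ = ivw(hset)
        shifts = np.abs(table["estimate"] - full.estimate)
        assert table.loc[shifts.idxmax(), "excluded_rsid"] == "snp0"


class TestMRPresso:
    def test_planted_outlier_flagged_and_corrected(self, rng):
        bx = rng.uniform(0.1, 0.4, 30)
        by = 0.2 * bx + rng.normal(0, 0.01, 30)
        sy = np.full(30, 0.01)
        by[3] += 10 * sy[3]
        hset = hset_from(bx, np.full(30, 0.005), by, sy)
        rep = mr_presso(hset, n_sim=1000, seed=0)
        assert "snp3" in rep.outliers
        assert abs(rep.estimate_outlier_corrected.estimate - 0.2) <= abs(
            rep.estimate_raw.estimate - 0.2
        )
        assert rep.global_pvalue <= 1.0

    def test_clean_data_no_outliers(self, rng):
        bx = rng.uniform(0.1, 0.4, 30)
        by = 0.2 * bx + rng.normal(0, 0.01, 30)
        hset = hset_from(bx, np.full(30, 0.005), by, np.full(30, 0.01))
        rep = mr_presso(hset, n_sim=1000, seed=1)
        assert rep.outliers == []
        assert rep.distortion_pvalue == 1.0
        assert rep.global_pvalue >= 1 / 1001

    def test_too_few_snps(self):
        hset = hset_from([0.1, 0.2, 0.3], [0.01] * 3, [0.05] * 3, [0.01] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(hset, seed=0)


class TestSignificanceTiers:
    def _res(self, p):
        return MRResult("ivw_random", 0.1, 0.05, 0.0, 0.2, p, 10)

    def test_bonferroni_threshold_value(self):
        assert bonferroni_threshold(n_tests=20, alpha=0.05) == pytest.approx(0.0025)

    @pytest.mark.parametrize(
        "p,tier",
        [(1e-4, "significant"), (0.011, "marginal"), (0.0025, "marginal"),
         (0.049, "marginal"), (0.05, "null"), (0.6, "null")],
    )
    def test_tier_boundaries(self, p, tier):
        out = classify_significance([self._res(p)], n_tests=20)
        assert out["tier"].iloc[0] == tier


def test_parameter_recovery_means():
    """theta = 0.3, J = 50, no pleiotropy: all three estimators unbiased."""
    config = SimulationConfig(J=50, theta=0.3, seed=0)
    ests = {"ivw": [], "egger": [], "wm": []}
    for s in np.random.SeedSequence(99).spawn(400):
        e = draw_effects(config, np.random.default_rng(s))
        bx, sx = e["beta_exp_obs"], e["se_exp"]
        by, sy = e["beta_out_obs"], e["se_out"]
        ests["ivw"].append(ivw_arrays(bx, by, sy)[0])
        ests["egger"].append(egger_arrays(bx, sx, by, sy)[0])
        ests["wm"].append(weighted_median_point(by / bx, bx**2 / sy**2))
    for name, values in ests.items():
        assert np.mean(values) == pytest.approx(0.3, abs=0.01), name
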