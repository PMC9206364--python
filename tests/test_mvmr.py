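import numpy as np
import pytest

from cardiomr.estimators import ivw, weighted_median
from cardiomr.harmonize import HarmonizedSet
from cardiomr.instruments import InstrumentSet, LDTable
from cardiomr.mvmr import (
    CollinearityError,
    MVMRInput,
    assemble_mvmr_input,
    bidirectional_mr,
    mvmr_egger,
    mvmr_ivw,
    mvmr_median,
)
from cardiomr.simulate import (
    Pleiotropy,
    SimulationConfig,
    simulate_multivariable,
    simulate_univariable,
)
from conftest import make_table


def make_input(G, SE, by, sy, labels=("e1", "e2")):
    j = len(by)
    return MVMRInput(
        rsids=[f"rs{i}" for i in range(j)],
        exposure_betas=G, exposure_ses=SE,
        beta_outcome=by, se_outcome=sy, exposures=list(labels),
    )


class TestMVMRIVW:
    def test_zero_second_exposure_reduces_to_univariable(self, rng):
        j = 30
        bx = rng.uniform(0.1, 0.4, j)
        by = 0.3 * bx + rng.normal(0, 0.02, j)
        sy = np.full(j, 0.02)
        G = np.column_stack([bx, np.zeros(j)])
        SE = np.full((j, 2), 0.005)
        res = mvmr_ivw(make_input(G, SE, by, sy))
        uni, _ = ivw(HarmonizedSet.from_arrays(bx, SE[:, 0], by, sy), model="random")
        assert res.results["e1"].estimate == pytest.approx(uni.estimate, abs=1e-12)
        assert np.isnan(res.results["e2"].estimate)

    def test_k1_equals_univariable_ivw_exactly(self, rng):
        j = 25
        bx = rng.uniform(0.1, 0.4, j)
        by = rng.normal(0.3 * bx, 0.02)
        sy = rng.uniform(0.01, 0.03, j)
        inp = MVMRInput(
            rsids=[f"rs{i}" for i in range(j)],
            exposure_betas=bx[:, None], exposure_ses=np.full((j, 1), 0.005),
            beta_outcome=by, se_outcome=sy, exposures=["e1"],
        )
        res = mvmr_ivw(inp)
        uni, _ = ivw(HarmonizedSet.from_arrays(bx, np.full(j, 0.005), by, sy))
        assert res.results["e1"].estimate == pytest.approx(uni.estimate, abs=1e-12)
        assert res.results["e1"].se == pytest.approx(uni.se, abs=1e-12)

    def test_parameter_recovery_two_exposures(self):
        ests = np.empty((200, 2))
        for i, s in enumerate(np.random.SeedSequence(21).spawn(200)):
            seed = int(np.random.default_rng(s).integers(2**31))
            study = simulate_multivariable(
                SimulationConfig(J=100, theta=(0.3, -0.1),
                                 exposure_correlation=0.5, seed=seed)
            )
            r = mvmr_ivw(study.mvmr_input()).results
            ests[i] = [r["exposure1"].estimate, r["exposure2"].estimate]
        assert ests[:, 0].mean() == pytest.approx(0.3, abs=0.02)
        assert ests[:, 1].mean() == pytest.approx(-0.1, abs=0.02)

    def test_per_exposure_rescaling_equivariance(self, rng):
        j = 40
        G = rng.uniform(0.1, 0.4, (j, 2))
        by = G @ np.array([0.3, -0.1]) + rng.normal(0, 0.02, j)
        sy = np.full(j, 0.02)
        SE = np.full((j, 2), 0.005)
        base = mvmr_ivw(make_input(G, SE, by, sy))
        G2 = G.copy()
        G2[:, 0] *= 3.0
        scaled = mvmr_ivw(make_input(G2, SE, by, sy))
        assert scaled.results["e1"].estimate == pytest.approx(
            base.results["e1"].estimate / 3.0, abs=1e-12
        )
        assert scaled.results["e2"].estimate == pytest.approx(
            base.results["e2"].estimate, abs=1e-12
        )

    def test_collinear_exposures_rejected(self, rng):
        j = 20
        bx = rng.uniform(0.1, 0.4, j)
        G = np.column_stack([bx, 2 * bx])
        with pytest.raises(CollinearityError):
            mvmr_ivw(make_input(G, np.full((j, 2), 0.005),
                                rng.normal(0, 0.02, j), np.full(j, 0.02)))


class TestMVMREgger:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(4)
        j = 30
        G = rng.uniform(0.1, 0.4, (j, 2))
        by = 0.05 + G @ np.array([0.3, -0.1])
        res = mvmr_egger(make_input(G, np.full((j, 2), 0.005), by, np.full(j, 0.02)))
        assert res.results["e1"].estimate == pytest.approx(0.3, abs=1e-8)
        assert res.results["e2"].estimate == pytest.approx(-0.1, abs=1e-8)
        assert res.intercept.estimate == pytest.approx(0.05, abs=1e-8)
        assert res.heterogeneity.Q == pytest.approx(0.0, abs=1e-12)

    def test_global_sign_flip_preserves_slopes_and_intercept(self, rng):
        j = 30
        G = rng.uniform(0.1, 0.4, (j, 2))
        by = 0.05 + G @ np.array([0.3, -0.1]) + rng.normal(0, 0.01, j)
        a = mvmr_egger(make_input(G, np.full((j, 2), 0.005), by, np.full(j, 0.02)))
        b = mvmr_egger(make_input(-G, np.full((j, 2), 0.005), -by, np.full(j, 0.02)))
        assert b.results["e1"].estimate == pytest.approx(a.results["e1"].estimate, abs=1e-12)
        assert b.intercept.estimate == pytest.approx(a.intercept.estimate, abs=1e-12)

    def test_null_intercept_coverage(self):
        covered = 0
        n = 150
        for s in np.random.SeedSequence(31).spawn(n):
            rng = np.random.default_rng(s)
            j = 50
            G = rng.uniform(0.1, 0.4, (j, 2))
            by = rng.normal(G @ np.array([0.3, -0.1]), 0.02)
            res = mvmr_egger(
                make_input(G, np.full((j, 2), 0.005), by, np.full(j, 0.02))
            )
            covered += res.intercept.ci_low <= 0 <= res.intercept.ci_high
        assert covered / n == pytest.approx(0.95, abs=0.05)


class TestMVMRMedian:
    def test_agrees_with_ivw_on_clean_data(self, rng):
        j = 80
        G = rng.uniform(0.1, 0.4, (j, 2))
        by = rng.normal(G @ np.array([0.3, -0.1]), 0.01)
        inp = make_input(G, np.full((j, 2), 0.003), by, np.full(j, 0.01))
        med = mvmr_median(inp, n_boot=50, seed=0)
        ivw_res = mvmr_ivw(inp)
        assert med.results["e1"].estimate == pytest.approx(
            ivw_res.results["e1"].estimate, abs=0.02
        )
        assert med.results["e2"].estimate == pytest.approx(
            ivw_res.results["e2"].estimate, abs=0.02
        )

    def test_less_biased_than_ivw_under_directional_pleiotropy(self, rng):
        j = 100
        G = rng.uniform(0.1, 0.4, (j, 2))
        by = rng.normal(G @ np.array([0.3, -0.1]), 0.01)
        invalid = rng.choice(j, size=30, replace=False)
        by[invalid] += 0.1  # directional pleiotropy on 30% of SNPs
        inp = make_input(G, np.full((j, 2), 0.003), by, np.full(j, 0.01))
        med = mvmr_median(inp, n_boot=20, seed=0)
        ivw_res = mvmr_ivw(inp)
        assert abs(med.results["e1"].estimate - 0.3) < abs(
            ivw_res.results["e1"].estimate - 0.3
        )

    def test_nested_equal_weight_case_matches_univariable_median(self, rng):
        j = 21
        bx = np.full(j, 0.2)
        by = 0.2 * 0.3 + rng.normal(0, 0.02, j)
        sy = np.full(j, 0.02)
        G = np.column_stack([bx, np.zeros(j)])
        inp = make_input(G, np.full((j, 2), 1e-8), by, sy)
        med = mvmr_median(inp, n_boot=10, seed=0)
        uni = weighted_median(
            HarmonizedSet.from_arrays(bx, np.full(j, 1e-8), by, sy),
            n_boot=10, seed=0,
        )
        assert med.results["e1"].estimate == pytest.approx(uni.estimate, abs=1e-6)


class TestAssembleMVMRInput:
    def _tables(self, rsids, betas, trait, pvals=None, missing=()):
        rows = []
        for i, r in enumerate(rsids):
            if r in missing:
                continue
            rows.append(
                {"rsid": r, "beta": betas[i], "se": 0.005,
                 "pvalue": 1e-9 if pvals is None else pvals[i]}
            )
        return make_table(rows, trait=trait)

    def test_disjoint_instruments_union(self, rng):
        a = [f"rsA{i}" for i in range(5)]
        b = [f"rsB{i}" for i in range(4)]
        rsids = a + b
        g1 = rng.uniform(0.1, 0.3, 9)
        g2 = rng.uniform(0.1, 0.3, 9)
        by = 0.3 * g1 - 0.1 * g2 + rng.normal(0, 0.01, 9)
        e1 = self._tables(rsids, g1, "e1")
        e2 = self._tables(rsids, g2, "e2")
        out = self._tables(rsids, by, "out", pvals=np.full(9, 0.3))
        inp = assemble_mvmr_input(
            InstrumentSet("a", a), InstrumentSet("b", b),
            {"e1": e1, "e2": e2}, out,
        )
        assert inp.J == 9 and inp.K == 2

    def test_duplicate_snp_appears_once(self, rng):
        shared = ["rs1", "rs2", "rs3"]
        g = rng.uniform(0.1, 0.3, 3)
        e1 = self._tables(shared, g, "e1")
        e2 = self._tables(shared, g * 0.5, "e2")
        out = self._tables(shared, g * 0.3, "out", pvals=np.full(3, 0.3))
        inp = assemble_mvmr_input(
            InstrumentSet("a", shared), InstrumentSet("b", ["rs2", "rs3"]),
            {"e1": e1, "e2": e2}, out,
        )
        assert inp.rsids == shared

    def test_removals_and_clumping_reach_expected_count(self, rng):
        """Union bookkeeping: 2 unextractable + 1 outcome hit + 1 clumped."""
        a = [f"rsA{i}" for i in range(40)]
        b = [f"rsB{i}" for i in range(35)]
        rsids = a + b  # 75
        g1 = rng.uniform(0.1, 0.3, 75)
        g2 = rng.uniform(0.1, 0.3, 75)
        by = 0.3 * g1 + rng.normal(0, 0.01, 75)
        outcome_p = np.full(75, 0.3)
        outcome_p[5] = 1e-9  # planted outcome hit
        e1 = self._tables(rsids, g1, "e1", missing={"rsA0"})
        e2 = self._tables(rsids, g2, "e2", missing={"rsB0"})
        out = self._tables(rsids, by, "out", pvals=outcome_p)
        ld = LDTable()
        for i, r in enumerate(rsids):
            ld.positions[r] = (str(i % 22 + 1), 20_000_000 * (i // 22 + 1))
        ld.positions["rsA7"] = ld.positions["rsA29"][0], ld.positions["rsA29"][1] + 1000
        ld.set_r2("rsA7", "rsA29", 0.9)
        inp = assemble_mvmr_input(
            InstrumentSet("a", a), InstrumentSet("b", b),
            {"e1": e1, "e2": e2}, out, ld=ld,
        )
        assert inp.J == 75 - 2 - 1 - 1 == 71


class TestBidirectional:
    @staticmethod
    def _one_way_tables(rng, theta=0.1):
        """A causes B (theta); B does not cause A.  30 SNPs instrument A,
        20 further SNPs act on B directly and leave A untouched."""
        set_a = [f"rsA{i}" for i in range(30)]
        set_b = [f"rsB{i}" for i in range(20)]
        gamma = rng.uniform(0.1, 0.4, 30)
        delta = rng.uniform(0.1, 0.4, 20)
        se_a, se_b = 0.01, 0.01
        beta_on_a = np.concatenate([gamma, rng.normal(0, se_a, 20)])
        beta_on_b = np.concatenate([theta * gamma, delta]) + rng.normal(0, se_b, 50)
        rows_a = [
            {"rsid": r, "beta": b, "se": se_a,
             "pvalue": 1e-9 if r.startswith("rsA") else 0.5}
            for r, b in zip(set_a + set_b, beta_on_a)
        ]
        rows_b = [
            {"rsid": r, "beta": b, "se": se_b,
             "pvalue": 1e-9 if r.startswith("rsB") else 0.5}
            for r, b in zip(set_a + set_b, beta_on_b)
        ]
        table_a = make_table(rows_a, trait="A")
        table_b = make_table(rows_b, trait="B")
        return table_a, table_b, InstrumentSet("a", set_a), InstrumentSet("b", set_b)

    def test_one_way_causation_recovered(self, rng):
        table_a, table_b, instr_a, instr_b = self._one_way_tables(rng)
        res = bidirectional_mr(table_a, table_b, instr_a, instr_b,
                               n_boot=100, seed=0)
        fwd = res["A->B"][res["A->B"]["method"] == "ivw_random"].iloc[0]
        rev = res["B->A"][res["B->A"]["method"] == "ivw_random"].iloc[0]
        assert fwd["estimate"] == pytest.approx(0.1, abs=0.03)
        assert rev["ci_low"] <= 0 <= rev["ci_high"]

    def test_identical_traits_give_unit_slopes(self, rng):
        table_a, _, instr_a, _ = self._one_way_tables(rng)
        b_clone = make_table(
            [{"rsid": r, "beta": b, "se": s, "pvalue": p}
             for r, b, s, p in zip(table_a.data["rsid"], table_a.data["beta"],
                                   table_a.data["se"], table_a.data["pvalue"])],
            trait="B",
        )
        res = bidirectional_mr(table_a, b_clone, instr_a, instr_a, n_boot=50, seed=0)
        for key in res:
            est = res[key][res[key]["method"] == "ivw_random"]["estimate"].iloc[0]
            assert est == pytest.approx(1.0, abs=1e-12)
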