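"""Multivariable MR, the two-step screen and mediation decomposition."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlink.estimators import MREstimate, ivw
from mrlink.exceptions import CollinearityError, InputError, UndefinedRatioError
from mrlink.mediation import (
    MvmrInput,
    benjamini_hochberg,
    mediate,
    mvmr_ivw,
    product_of_coefficients,
    run_mediation_analysis,
    two_step_screen,
)
from mrlink.simulate import MediationSimConfig, simulate_mediation
from mrlink.sumstats import select_instruments
from conftest import make_hset


def mv_input(x, y, sy, names=None):
    x = np.asarray(x, float)
    n, k = x.shape
    return MvmrInput(
        variant_ids=[f"rs{i}" for i in range(n)],
        beta_exposures=x,
        se_exposures=np.full_like(x, 0.01),
        beta_outcome=np.asarray(y, float),
        se_outcome=np.broadcast_to(np.asarray(sy, float), (n,)).copy(),
        exposure_names=names or [f"exp{j}" for j in range(k)],
    )


class TestMvmrIvw:
    def test_block_orthogonal_design_recovers_univariable_ivw(self):
        # exposure 2 has zero betas on exposure 1's instruments and vice versa
        x = np.array([
            [0.2, 0.0], [0.3, 0.0], [0.25, 0.0], [0.15, 0.0],
            [0.0, 0.2], [0.0, 0.3], [0.0, 0.25],
        ])
        rng = np.random.default_rng(4)
        y = 0.4 * x[:, 0] - 0.1 * x[:, 1] + rng.normal(0, 0.02, 7)
        est = mvmr_ivw(mv_input(x, y, 0.05))
        uni, _ = ivw(make_hset(x[:4, 0], 0.01, y[:4], 0.05), effects_model="fixed")
        assert est[0].beta == pytest.approx(uni.beta, abs=1e-12)

    def test_exact_linear_model(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.4, size=(8, 2))
        y = 0.4 * x[:, 0] - 0.2 * x[:, 1]
        est = mvmr_ivw(mv_input(x, y, 0.05))
        assert est[0].beta == pytest.approx(0.4, abs=1e-12)
        assert est[1].beta == pytest.approx(-0.2, abs=1e-12)

    def test_matches_wls_oracle_k3(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 30))
            x = rng.normal(0.2, 0.1, size=(n, 3))
            y = rng.normal(0, 0.1, n)
            sy = rng.uniform(0.02, 0.2, n)
            est = mvmr_ivw(mv_input(x, y, sy))
            fit = sm.WLS(y, x, weights=1 / sy**2).fit()
            for i in range(3):
                assert est[i].beta == pytest.approx(fit.params[i], abs=1e-10)
            q = float(np.sum((y - x @ fit.params) ** 2 / sy**2))
            scale = max(1.0, math.sqrt(q / (n - 3)))
            cov1 = fit.cov_params(scale=1.0)
            for i in range(3):
                assert est[i].se == pytest.approx(scale * math.sqrt(cov1[i, i]), abs=1e-10)

    def test_duplicated_exposure_raises_collinearity(self):
        x1 = np.linspace(0.1, 0.4, 6)
        x = np.column_stack([x1, x1])
        with pytest.raises(CollinearityError):
            mvmr_ivw(mv_input(x, np.zeros(6), 0.05, names=["a", "b"]))


def brute_bh(pvals):
    """Step-up BH by direct enumeration of the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBenjaminiHochberg:
    def test_equal_spacing_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=8))
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(benjamini_hochberg(pvals), brute_bh(pvals), atol=1e-12)


class TestMediate:
    def est(self, beta, se):
        return MREstimate(method="ivw", beta=beta, se=se, pval=0.5, n_snp=10)

    def test_worked_identity(self):
        res = mediate(self.est(-0.25, 0.05), self.est(-0.10, 0.12))
        assert res.beta_indirect == pytest.approx(-0.15)
        assert res.proportion_mediated == pytest.approx(0.60)

    def test_no_mediation(self):
        res = mediate(self.est(-0.25, 0.05), self.est(-0.25, 0.05))
        assert res.beta_indirect == 0.0
        assert res.proportion_mediated == 0.0

    def test_delta_method_se_hand_evaluated(self):
        res = mediate(self.est(-0.25, 0.05), self.est(-0.10, 0.12))
        assert res.se_indirect == pytest.approx(0.13)
        expect = math.sqrt(0.13**2 / 0.25**2 + (0.15**2 * 0.05**2) / 0.25**4)
        assert res.proportion_se == pytest.approx(expect, abs=1e-12)
        assert res.proportion_ci[0] == pytest.approx(0.6 - 1.959963985 * expect, abs=1e-6)

    def test_delta_se_is_conservative_against_monte_carlo(self, rng):
        """The independence working assumption upper-bounds the true ratio SD."""
        bt, st_, bd, sd_ = -0.25, 0.05, -0.10, 0.12
        t = rng.normal(bt, st_, 1_000_000)
        d = rng.normal(bd, sd_, 1_000_000)
        mc_sd = np.std((t - d) / t)
        res = mediate(self.est(bt, st_), self.est(bd, sd_))
        assert res.proportion_se >= mc_sd * 0.95
        assert res.proportion_se <= mc_sd * 1.5

    def test_scale_invariance_of_proportion(self):
        r1 = mediate(self.est(-0.25, 0.05), self.est(-0.10, 0.12))
        r2 = mediate(self.est(-0.75, 0.15), self.est(-0.30, 0.36))
        assert r1.proportion_mediated == pytest.approx(r2.proportion_mediated)

    def test_zero_total_effect_raises(self):
        with pytest.raises(UndefinedRatioError):
            mediate(self.est(0.0, 0.05), self.est(-0.10, 0.12))

    def test_product_of_coefficients_cross_check(self):
        b, se = product_of_coefficients(self.est(0.6, 0.05), self.est(-0.4, 0.1))
        assert b == pytest.approx(-0.24)
        assert se == pytest.approx(math.sqrt(0.36 * 0.01 + 0.16 * 0.0025))


class TestTwoStepScreen:
    def build(self, seed=0):
        exp, med, out, truth = simulate_mediation(MediationSimConfig(seed=seed))
        return exp, med, out, truth

    def test_true_mediator_selected_null_rejected(self):
        exp, med, out, truth = self.build(seed=1)
        # a null mediator: same variants, effects unrelated to the exposure
        rng = np.random.default_rng(99)
        null_med = med.table.copy()
        null_med["beta"] = rng.normal(0, 0.02, len(null_med))
        null_med["pval"] = 1.0
        from mrlink.sumstats import SumstatsTable

        null_tab = SumstatsTable("null_med", "continuous", null_med)
        res = two_step_screen(
            exp, truth["exposure_instruments"],
            {"true_med": med, "null_med": null_tab}, out,
        )
        assert "true_med" in res.selected
        assert "null_med" not in res.selected
        assert "null_med" in res.skipped or not res.table.set_index("mediator").loc[
            "null_med", "pass1"
        ]

    def test_vacuous_threshold_retains_all_at_step1(self):
        exp, med, out, truth = self.build(seed=2)
        res = two_step_screen(
            exp, truth["exposure_instruments"], {"m": med}, out, fdr_threshold=1.0
        )
        assert bool(res.table["pass1"].all())

    def test_null_path_excluded_across_replicates(self):
        """Mediators generated with no exposure->mediator path rarely pass step 1."""
        passed = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = MediationSimConfig(theta_xm=0.0, theta_my=-0.4, theta_direct=-0.1,
                                     seed=1000 + rep)
            exp, med, out, truth = simulate_mediation(cfg)
            res = two_step_screen(exp, truth["exposure_instruments"], {"m": med}, out)
            if "m" in res.selected:
                passed += 1
        assert passed <= 1  # expected exclusion probability >= 0.95


class TestRunMediationAnalysis:
    def test_chain_recovery_single_draw(self):
        cfg = MediationSimConfig(seed=7)
        exp, med, out, truth = simulate_mediation(cfg)
        res = run_mediation_analysis(exp, out, med, truth["exposure_instruments"])
        assert res.beta_total.beta == pytest.approx(truth["theta_total"], abs=0.05)
        assert res.beta1.beta == pytest.approx(truth["theta_xm"], abs=0.05)
        assert res.beta2.beta == pytest.approx(truth["theta_my"], abs=0.1)
        assert res.proportion_mediated == pytest.approx(
            truth["proportion_mediated"], abs=3 * res.proportion_se
        )

    def test_null_mediator_gives_zero_proportion(self):
        cfg = MediationSimConfig(theta_xm=0.0, theta_my=0.3, theta_direct=-0.3, seed=11)
        exp, med, out, truth = simulate_mediation(cfg)
        res = run_mediation_analysis(exp, out, med, truth["exposure_instruments"])
        assert res.proportion_ci[0] <= 0.0 <= res.proportion_ci[1]

    def test_mediator_identical_to_exposure_raises(self):
        cfg = MediationSimConfig(seed=13)
        exp, med, out, truth = simulate_mediation(cfg)
        with pytest.raises((CollinearityError, InputError)):
            run_mediation_analysis(exp, out, exp, truth["exposure_instruments"])
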