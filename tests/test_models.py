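import numpy as np
import pytest

import pitsval as pv
from pitsval import tables
from pitsval.design import TaskType, bundled_design_profiles
from pitsval.models import ChoiceData, _Pack, _nll_grad, cell_loglik, information_criteria
from pitsval.valueset import ValueSetParams

from conftest import simulate_homogeneous


def _pc_obs(code_a, code_b, chosen, rid="r1", seq=1):
    from pitsval.design import _cached_pc_alternatives

    return pv.ChoiceObservation(
        rid, TaskType.PC, seq, list(_cached_pc_alternatives(code_a, code_b)), chosen, (code_a, code_b)
    )


def _bws_obs(code, chosen, polarity="best", rid="r1", seq=1):
    prof = pv.parse_profile(code)
    alts = [pv.bws_alternative_vector(prof, a, polarity) for a in range(1, 6)]
    ttype = TaskType.BWS_BEST if polarity == "best" else TaskType.BWS_WORST
    return pv.ChoiceObservation(rid, ttype, seq, alts, chosen, (code,))


class TestScaleFactor:
    def test_zero_gamma(self):
        assert pv.scale_factor(pv.ScaleModel(), 0.7, TaskType.PC) == 1.0

    def test_published_sequence_effect(self):
        sm = pv.ScaleModel(gamma_seq=0.8419, gamma_seq2=-0.7427)
        expect = np.exp(0.8419 * 0.56 - 0.7427 * 0.56**2)
        assert pv.scale_factor(sm, 14 / 25, TaskType.BWS_WORST) == pytest.approx(expect)
        assert expect == pytest.approx(1.264, abs=0.01)

    def test_pc_indicator(self):
        sm = pv.ScaleModel(gamma_pc=-0.9930)
        assert pv.scale_factor(sm, 0.0, TaskType.PC) == pytest.approx(np.exp(-0.9930))
        assert np.exp(-0.9930) == pytest.approx(0.3704, abs=5e-4)


class TestChoiceProbabilities:
    def test_uniform_under_zero_params(self):
        zero = ValueSetParams(np.zeros(20))
        pc = _pc_obs("21345", "24242", 0)
        assert np.allclose(pv.choice_probabilities(pc, zero), 0.5)
        bws = _bws_obs("32512", 2)
        assert np.allclose(pv.choice_probabilities(bws, zero), 0.2)

    def test_best_vs_worst_profile(self):
        params = pv.pits_normalize(ValueSetParams(tables.coefficient_column("conditional")))
        obs = _pc_obs("11111", "55555", 0)
        p = pv.choice_probabilities(obs, params)
        assert p[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_scale_coefficient_confounding(self):
        beta = tables.coefficient_column("taste_class_1")
        obs = _bws_obs("24253", 1, "worst")
        p1 = pv.choice_probabilities(obs, ValueSetParams(2 * beta, np.ones(5)), lam=1.0)
        p2 = pv.choice_probabilities(obs, ValueSetParams(beta, 0.5 * np.ones(5)), lam=2.0)
        assert np.allclose(p1, p2)

    def test_eta_shift_invariance(self):
        beta = tables.coefficient_column("taste_class_1")
        eta = np.array([0.3, 0.0, 0.1, 0.5, 0.2])
        for pol in ("best", "worst"):
            obs = _bws_obs("24253", 1, pol)
            p1 = pv.choice_probabilities(obs, ValueSetParams(beta, eta))
            p2 = pv.choice_probabilities(obs, ValueSetParams(beta, eta + 0.77))
            assert np.allclose(p1, p2)


class TestLogLikelihood:
    def test_closed_forms_at_zero(self):
        zero = ValueSetParams(np.zeros(20))
        pcs = [_pc_obs("21345", "24242", 0, seq=i + 1) for i in range(8)]
        assert pv.log_likelihood(pcs, zero) == pytest.approx(8 * np.log(0.5))
        bws = [_bws_obs("32512", i % 5, "best", seq=i + 1) for i in range(7)]
        assert pv.log_likelihood(bws, zero) == pytest.approx(7 * np.log(0.2))

    def test_matches_per_observation_product(self, small_study):
        """Pooled log-likelihood equals the sum of per-task log chosen
        probabilities computed independently task by task."""
        obs = small_study["observations"][:10]
        params = pv.pits_normalize(ValueSetParams(tables.coefficient_column("conditional")))
        sm = pv.ScaleModel(0.8, -0.7, -0.9, 0.2)
        total = 0.0
        for o in obs:
            lam = pv.scale_factor(sm, o.sequence / 25.0, o.task_type)
            total += np.log(pv.choice_probabilities(o, params, lam)[o.chosen])
        assert pv.log_likelihood(obs, params, sm) == pytest.approx(total)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ChoiceData([])


class TestConditionalLogit:
    def test_symmetric_choices_give_zero_beta(self):
        obs = []
        k = 0
        for code_a, code_b in [("21111", "12111"), ("31215", "13251"), ("11123", "32111")]:
            for chosen in (0, 1):
                for rep in range(3):
                    k += 1
                    obs.append(_pc_obs(code_a, code_b, chosen, rid=f"r{k}", seq=1))
        fit = pv.fit_conditional_logit(obs, compute_se=False)
        assert np.allclose(fit.params.beta, 0.0, atol=1e-5)

    def test_loglik_dominates_null(self, small_study):
        data = small_study["data"]
        fit = pv.fit_conditional_logit(data, compute_se=False)
        null = pv.log_likelihood(data, ValueSetParams(np.zeros(20)))
        assert fit.converged and fit.loglik >= null

    def test_recovery_homogeneous(self, homoskedastic_study):
        """Decrements generated from the value-set class are recovered on the
        pits scale."""
        fit = pv.fit_conditional_logit(homoskedastic_study["data"], compute_se=False)
        true_pits = homoskedastic_study["truth"].taste_betas[0]
        true_pits = true_pits / true_pits.sum()
        rmse = np.sqrt(((fit.params_pits.beta - true_pits) ** 2).mean())
        assert rmse < 0.01
        # smallest ancillary is the constrained one
        assert fit.params.eta.min() == 0.0

    def test_eta_shift_invariance_of_fit(self, small_study):
        """The likelihood at the fit is unchanged when all ancillary terms are
        shifted by a constant (so anchoring the smallest at 0 is harmless)."""
        data = small_study["data"]
        fit = pv.fit_conditional_logit(data, compute_se=False)
        shifted = ValueSetParams(fit.params.beta, fit.params.eta + 1.3)
        assert pv.log_likelihood(data, shifted) == pytest.approx(fit.loglik, abs=1e-6)


class TestHeteroskedasticLogit:
    def test_nests_conditional(self, small_study):
        data = small_study["data"]
        cl = pv.fit_conditional_logit(data, compute_se=False)
        pack = _Pack(False, ("sequence", "sequence_sq", "pc", "best"), cl.pack.fixed_eta, True)
        x = np.concatenate([cl.x, np.zeros(4)])
        nll, _ = _nll_grad(x, data, pack)
        assert -nll == pytest.approx(cl.loglik, abs=1e-9)
        hcl = pv.fit_heteroskedastic_logit(data, compute_se=False)
        assert hcl.loglik >= cl.loglik - 1e-6

    def test_gamma_sign_recovery(self, heteroskedastic_study):
        fit = pv.fit_heteroskedastic_logit(heteroskedastic_study["data"], compute_se=False)
        sm = fit.scale
        assert sm.gamma_seq > 0 and sm.gamma_seq2 < 0 and sm.gamma_pc < 0 and sm.gamma_best > 0

    def test_model_selection_bic(self, homoskedastic_study, heteroskedastic_study):
        """BIC prefers HCL on heteroskedastic data and CL on homoskedastic
        data."""
        for study, hcl_wins in ((heteroskedastic_study, True), (homoskedastic_study, False)):
            cl = pv.fit_conditional_logit(study["data"], compute_se=False)
            hcl = pv.fit_heteroskedastic_logit(study["data"], compute_se=False)
            assert (hcl.bic < cl.bic) == hcl_wins

    def test_collinear_scale_covariates_rejected(self, small_study):
        pc_only = [o for o in small_study["observations"] if o.task_type is TaskType.PC]
        with pytest.raises(ValueError, match="collinear"):
            pv.fit_heteroskedastic_logit(pc_only, scale_terms=("pc", "best"))

    def test_unknown_term_rejected(self, small_study):
        with pytest.raises(ValueError, match="unknown scale term"):
            pv.fit_heteroskedastic_logit(small_study["data"], scale_terms=("intercept",))


class TestInteractionModel:
    def test_requires_both_task_types(self, small_study):
        pc_only = [o for o in small_study["observations"] if o.task_type is TaskType.PC]
        with pytest.raises(ValueError, match="both"):
            pv.fit_interaction_model(pc_only)

    def test_fit_and_difference_tests(self, small_study):
        fit = pv.fit_interaction_model(small_study["data"])
        assert fit.params_pc is not None
        assert len(fit.difference_tests) == 20
        assert fit.params_pits.class_logit is not None
        # separate pits normalization of the two sets
        assert fit.params_pits.beta.sum() == pytest.approx(1.0)
        assert fit.params_pc_pits.beta.sum() == pytest.approx(1.0)
        # the interaction model nests the pooled heteroskedastic logit
        hcl = pv.fit_heteroskedastic_logit(small_study["data"], compute_se=False)
        assert fit.loglik >= hcl.loglik - 1e-6


class TestInference:
    def test_information_criteria_formula(self):
        bic, aic, caic = information_criteria(-100.0, 5, 380)
        assert bic == pytest.approx(200 + 5 * np.log(380))
        assert bic == pytest.approx(229.70, abs=0.01)
        assert aic == pytest.approx(210.0)
        assert caic == pytest.approx(bic + 5)

    def test_wald_pvalues(self, small_study):
        fit = pv.fit_conditional_logit(small_study["data"])
        assert np.isfinite(fit.se[: 20]).all()
        # a coefficient sitting at 1.96 standard errors has p close to 0.05
        from scipy import stats

        i = int(np.nanargmax(fit.se[:20]))
        z = fit.x[i] / fit.se[i]
        assert fit.pvalues[i] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-10)
        assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)

    def test_se_shrinks_with_n(self):
        small_obs, _, _ = simulate_homogeneous(30, seed=13)
        big_obs, _, _ = simulate_homogeneous(120, seed=13)
        f1 = pv.fit_conditional_logit(small_obs)
        f2 = pv.fit_conditional_logit(big_obs)
        ratio = np.nanmedian(f1.se[:20] / f2.se[:20])
        assert ratio == pytest.approx(2.0, abs=0.5)  # 1/sqrt(n) scaling
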