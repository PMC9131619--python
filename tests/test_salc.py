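from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import pitsval as pv
from pitsval.models import ChoiceData
from pitsval.salc import (
    _SALCPack,
    em_fit_salc,
    gom_report,
    identify_garbage_class,
    membership_design,
    relabel_classes,
    salc_log_likelihood,
    softmax_probs,
)
from pitsval.valueset import prob_best_over_worst


@pytest.fixture(scope="module")
def small_salc_fit(small_study):
    return em_fit_salc(
        small_study["data"],
        small_study["covariates"],
        T=2,
        S=2,
        n_starts=3,
        seed=5,
        compute_se=True,
    )


class TestMixtureLikelihood:
    def test_degenerate_mixture_equals_hcl(self, small_study):
        data = small_study["data"]
        hcl = pv.fit_heteroskedastic_logit(data, compute_se=False)
        fit = em_fit_salc(
            data, small_study["covariates"], T=1, S=1, n_starts=1, seed=0, compute_se=False
        )
        assert fit.loglik == pytest.approx(hcl.loglik, abs=0.05)
        assert fit.scale_factors.tolist() == [1.0]

    def test_identical_classes_share_invariance(self, small_study):
        """With two identical taste classes the likelihood cannot depend on
        how the mixing weight is split between them."""
        data = small_study["data"]
        hcl = pv.fit_heteroskedastic_logit(data, compute_se=False)
        pack = _SALCPack(2, 1, ("sequence", "sequence_sq", "pc", "best"))
        theta = hcl.params.theta
        x = pack.pack([theta, theta], [0.0], [hcl.scale.gamma])
        n = data.n_respondents
        lls = []
        for p in (0.1, 0.5, 0.9):
            log_pi = np.log(np.tile([p, 1 - p], (n, 1)))
            log_om = np.zeros((n, 1))
            ll, _, _ = salc_log_likelihood(data, pack, x, log_pi, log_om)
            lls.append(ll)
        assert np.ptp(lls) < 1e-9
        assert lls[1] == pytest.approx(hcl.loglik, abs=1e-9)

    def test_brute_force_enumeration_three_respondents(self, small_study):
        """Mixture log-likelihood matches an explicit sum over cells computed
        task by task with choice_probabilities."""
        rids = sorted({o.respondent_id for o in small_study["observations"]})[:3]
        obs = [o for o in small_study["observations"] if o.respondent_id in rids]
        data = ChoiceData(obs)
        truth = small_study["truth"]
        pack = _SALCPack(2, 2, ("sequence", "sequence_sq", "pc", "best"))
        thetas = [np.concatenate([np.asarray(b).ravel(), truth.etas]) for b in truth.taste_betas]
        x = pack.pack(thetas, np.log(truth.scale_factors), [truth.gamma, truth.gamma])
        pi = np.array([0.7, 0.3])
        om = np.array([0.55, 0.45])
        log_pi = np.tile(np.log(pi), (3, 1))
        log_om = np.tile(np.log(om), (3, 1))
        ll, ll_resp, post = salc_log_likelihood(data, pack, x, log_pi, log_om)
        # independent enumeration
        by_resp = {r: [o for o in obs if o.respondent_id == r] for r in rids}
        expected = 0.0
        for r in data.respondent_ids:
            mix = 0.0
            for c in range(2):
                params = pv.ValueSetParams(truth.taste_betas[c], truth.etas)
                for s in range(2):
                    prod = 1.0
                    for o in by_resp[r]:
                        lam = truth.scale_factors[s] * pv.scale_factor(
                            pv.ScaleModel(*truth.gamma), o.sequence / 25.0, o.task_type
                        )
                        prod *= pv.choice_probabilities(o, params, lam)[o.chosen]
                    mix += pi[c] * om[s] * prod
            expected += np.log(mix)
        assert ll == pytest.approx(expected)
        assert np.allclose(post.sum(axis=(1, 2)), 1.0)

    def test_missing_covariate_rejected(self, small_study):
        cov = small_study["covariates"].iloc[:-2]
        with pytest.raises(ValueError, match="missing"):
            em_fit_salc(small_study["data"], cov, T=1, S=1, n_starts=1, seed=0, compute_se=False)


class TestEMFit:
    def test_monotone_loglik_path(self, small_salc_fit):
        path = np.asarray(small_salc_fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-6 * (1 + np.abs(path[:-1])))

    def test_posteriors_and_shares(self, small_salc_fit):
        fit = small_salc_fit
        assert np.allclose(fit.posteriors.sum(axis=(1, 2)), 1.0)
        assert fit.taste_shares.sum() == pytest.approx(1.0)
        assert fit.scale_shares.sum() == pytest.approx(1.0)
        assert fit.scale_factors[0] == 1.0
        assert (fit.scale_factors > 0).all()

    def test_mixture_loglik_wrapper_matches_fit(self, small_salc_fit, small_study):
        from pitsval.salc import mixture_log_likelihood

        ll = mixture_log_likelihood(
            small_study["data"], small_study["covariates"], small_salc_fit
        )
        assert ll == pytest.approx(small_salc_fit.loglik, abs=1e-6)

    def test_seed_determinism(self, small_study):
        kw = dict(T=2, S=1, n_starts=2, seed=11, compute_se=False, short_run_iter=5, max_em_iter=10)
        f1 = em_fit_salc(small_study["data"], small_study["covariates"], **kw)
        f2 = em_fit_salc(small_study["data"], small_study["covariates"], **kw)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.posteriors, f2.posteriors)

    def test_salc_beats_hcl_bic_only_with_heterogeneity(self, small_study, homoskedastic_study):
        """Penalization works: on data simulated without heterogeneity the
        2x2 SALC has the worse BIC."""
        hcl = pv.fit_heteroskedastic_logit(homoskedastic_study["data"], compute_se=False)
        cov = pv.sample_respondents(380, seed=7)
        fit = em_fit_salc(
            homoskedastic_study["data"], cov, T=2, S=2, n_starts=2, seed=1,
            compute_se=False, short_run_iter=8, max_em_iter=30,
        )
        assert fit.bic > hcl.bic


class TestClassSummaries:
    @pytest.mark.parametrize(
        "logit,prob", [(0.2161, 0.554), (0.0, 0.5), (-0.2161, 0.446), (6.213, 0.998)]
    )
    def test_prob_best_over_worst(self, logit, prob):
        assert prob_best_over_worst(logit) == pytest.approx(prob, abs=5e-4)

    def test_identify_garbage(self):
        fit = SimpleNamespace(prob_best_over_worst=np.array([0.998, 0.554]), T=2)
        rep = identify_garbage_class(fit)
        assert rep["garbage_classes"] == [1] and rep["value_set_class"] == 0
        fit1 = SimpleNamespace(prob_best_over_worst=np.array([prob_best_over_worst(5.0)]), T=1)
        rep1 = identify_garbage_class(fit1)
        assert rep1["garbage_classes"] == [] and rep1["value_set_class"] == 0
        fit2 = SimpleNamespace(prob_best_over_worst=np.array([0.5, 0.51]), T=2)
        rep2 = identify_garbage_class(fit2)
        assert rep2["value_set_class"] is None and len(rep2["garbage_classes"]) == 2

    def test_relabel_canonical_and_idempotent(self, small_salc_fit):
        import copy

        fit = small_salc_fit
        assert np.all(np.diff(fit.prob_best_over_worst) <= 1e-12)
        assert np.all(np.diff(fit.scale_factors) <= 1e-12)
        again = relabel_classes(copy.deepcopy(fit))
        assert np.allclose(again.posteriors, fit.posteriors)
        assert np.allclose(again.class_logits, fit.class_logits)

    def test_relabel_preserves_membership_probabilities(self, small_salc_fit, small_study):
        """Re-anchored GOM logits give the same membership probabilities."""
        import copy

        fit = copy.deepcopy(small_salc_fit)
        cov = small_study["covariates"].set_index("respondent_id").loc[fit.respondent_ids].reset_index()
        Zt, _ = membership_design(cov, "taste")
        before = softmax_probs(Zt, fit.gom.taste_coefs)
        # force a swap and relabel back
        fit.prob_best_over_worst = fit.prob_best_over_worst[::-1].copy()
        fit.class_logits = fit.class_logits[::-1].copy()
        fit.taste_params = fit.taste_params[::-1]
        fit.taste_params_pits = fit.taste_params_pits[::-1]
        fit.posteriors = fit.posteriors[:, ::-1].copy()
        fit.taste_shares = fit.taste_shares[::-1].copy()
        fit.gom.taste_coefs = -fit.gom.taste_coefs
        back = relabel_classes(fit)
        after = softmax_probs(Zt, back.gom.taste_coefs)
        assert np.allclose(after, before)


class TestGOMReport:
    def test_report_structure(self, small_salc_fit):
        rep = gom_report(small_salc_fit)
        assert set(rep["equation"]) == {"taste_class_2", "scale_class_2"}
        taste = rep[rep["equation"] == "taste_class_2"]
        assert list(taste["covariate"])[0] == "intercept"
        assert np.allclose(rep["odds_ratio"], np.exp(rep["coef"]))

    def test_zero_coefficient_gives_unit_or(self):
        fit = SimpleNamespace(
            T=2,
            S=1,
            gom=SimpleNamespace(
                taste_coefs=np.zeros((1, 3)),
                scale_coefs=np.zeros((0, 3)),
                taste_names=["intercept", "female", "age_16_35"],
                scale_names=[],
            ),
            gom_cov=None,
        )
        rep = gom_report(fit)
        assert np.allclose(rep["odds_ratio"], 1.0)
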