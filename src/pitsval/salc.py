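"""Heteroskedastic scale-adjusted latent class (SALC) logit.

The population mixes T taste classes (each with its own decrement and
ancillary set) and S scale classes (each multiplying every utility by a
positive factor, reference class fixed at 1).  Membership in the two
dimensions is independent given covariates: taste membership follows a
softmax on demographic/health covariates, scale membership a softmax on
demographics plus behavioural flags (failing the dominant PC task,
perceived difficulty).  Within each scale class the task-level
heteroskedastic scale function applies with class-specific coefficients.
Respondent i's likelihood is

    sum_c sum_s pi_c(z_i) omega_s(w_i) prod_t P(y_it | beta_c, eta_c,
                                                 f_s exp(gamma_s' z_t))

and the model is estimated by maximum likelihood via EM (E-step: posterior
cell membership; M-step: posterior-weighted logit and softmax sub-fits)
with a multistart around the heteroskedastic-logit solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .design import ChoiceObservation, N_ATTRIBUTES, N_COEF
from .models import (
    ChoiceData,
    DEFAULT_SEQ_NORM,
    SCALE_TERMS,
    ScaleModel,
    _Pack,
    cell_loglik,
    fit_heteroskedastic_logit,
    information_criteria,
)
from .valueset import ValueSetParams, pits_normalize, prob_best_over_worst

TASTE_COVARIATES = (
    "female",
    "age_16_35",
    "age_55_plus",
    "educ_low",
    "educ_high",
    "chronic",
    "vas_lt70",
)
SCALE_COVARIATES = (
    "female",
    "age_16_35",
    "age_55_plus",
    "educ_low",
    "educ_high",
    "failed_dominant",
    "found_easy",
    "found_hard",
)


def membership_design(cov: pd.DataFrame, which: str) -> tuple[np.ndarray, list[str]]:
    """Build the GOM design matrix (intercept first) from a respondent
    covariate frame with the documented column dictionary."""
    cols = {
        "female": (cov["gender"] == "female").astype(float),
        "age_16_35": (cov["age_band"] == "16-35").astype(float),
        "age_55_plus": (cov["age_band"] == "55+").astype(float),
        "educ_low": (cov["education"] == "low").astype(float),
        "educ_high": (cov["education"] == "high").astype(float),
        "chronic": cov["chronic_illness"].astype(float),
        "vas_lt70": (cov["vas_band"] == "<70").astype(float),
        "failed_dominant": cov["failed_dominant"].astype(float),
        "found_easy": (cov["difficulty_pc"] == "easy").astype(float),
        "found_hard": (cov["difficulty_pc"] == "difficult").astype(float),
    }
    names = TASTE_COVARIATES if which == "taste" else SCALE_COVARIATES
    Z = np.column_stack([np.ones(len(cov))] + [cols[n].to_numpy() for n in names])
    return Z, ["intercept"] + list(names)


def _align_covariates(cov: pd.DataFrame, respondent_ids: Sequence[str]) -> pd.DataFrame:
    cov = cov.copy()
    cov["respondent_id"] = cov["respondent_id"].astype(str)
    cov = cov.set_index("respondent_id")
    missing = [r for r in respondent_ids if r not in cov.index]
    if missing:
        raise ValueError(f"covariates missing for respondents: {missing[:5]}")
    out = cov.loc[list(respondent_ids)].reset_index()
    for colname in ("gender", "age_band", "education", "vas_band", "difficulty_pc"):
        if out[colname].isna().any():
            bad = out.loc[out[colname].isna(), "respondent_id"].iloc[0]
            raise ValueError(f"missing covariate {colname!r} for respondent {bad}")
    return out


def softmax_probs(Z: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Class probabilities with class 0 as reference; ``coefs`` has shape
    (K-1, p)."""
    n = Z.shape[0]
    logits = np.concatenate([np.zeros((n, 1)), Z @ coefs.T], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _fit_weighted_softmax(Z: np.ndarray, W: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
    """Maximize sum_i sum_k W[i,k] log p_k(Z_i) over reference-coded softmax
    coefficients; W rows are fractional class memberships."""
    n, K = W.shape
    p = Z.shape[1]
    if K == 1:
        return np.zeros((0, p))

    def nll_grad(x):
        coefs = x.reshape(K - 1, p)
        P = softmax_probs(Z, coefs)
        ll = float((W * np.log(np.clip(P, 1e-300, None))).sum())
        resid = W[:, 1:] - W.sum(axis=1, keepdims=True) * P[:, 1:]
        return -ll, -(resid.T @ Z).ravel()

    x0 = np.zeros((K - 1) * p) if x0 is None else x0.ravel()
    res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B", options={"maxiter": 200})
    return res.x.reshape(K - 1, p)


@dataclass
class GOMModel:
    """Grade-of-membership equations (reference class 0 in each dimension)."""

    taste_coefs: np.ndarray  # (T-1, 1+len(TASTE_COVARIATES))
    scale_coefs: np.ndarray  # (S-1, 1+len(SCALE_COVARIATES))
    taste_names: list[str]
    scale_names: list[str]

    def taste_probs(self, Z: np.ndarray) -> np.ndarray:
        return softmax_probs(Z, self.taste_coefs)

    def scale_probs(self, W: np.ndarray) -> np.ndarray:
        return softmax_probs(W, self.scale_coefs)


@dataclass
class SALCFit:
    taste_params: list[ValueSetParams]  # raw scale, per taste class
    taste_params_pits: list[ValueSetParams]
    scale_factors: np.ndarray  # (S,), reference class = 1
    scale_models: list[ScaleModel]  # per scale class
    gom: GOMModel
    posteriors: np.ndarray  # (n_resp, T, S)
    respondent_ids: list[str]
    loglik: float
    n_obs: int
    n_params: int
    bic: float
    aic: float
    caic: float
    taste_shares: np.ndarray
    scale_shares: np.ndarray
    class_logits: np.ndarray  # sum of raw beta per taste class
    prob_best_over_worst: np.ndarray
    converged: bool
    n_em_iter: int
    loglik_path: list[float] = field(default_factory=list)
    gom_cov: np.ndarray | None = None  # OPG covariance of the GOM block
    scale_terms: tuple[str, ...] = SCALE_TERMS

    @property
    def T(self) -> int:
        return len(self.taste_params)

    @property
    def S(self) -> int:
        return len(self.scale_factors)

    def summary_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "bic": self.bic,
            "aic": self.aic,
            "caic": self.caic,
            "taste_shares": self.taste_shares.tolist(),
            "scale_shares": self.scale_shares.tolist(),
            "scale_factors": self.scale_factors.tolist(),
            "prob_best_over_worst": self.prob_best_over_worst.tolist(),
            "converged": self.converged,
            "n_em_iter": self.n_em_iter,
        }


class _SALCPack:
    """Packing of the choice-side free parameters: per taste class 20
    decrements + 4 free ancillaries (one pinned at 0), per non-reference
    scale class a log scale factor, per scale class the heteroskedastic
    coefficients."""

    def __init__(self, T: int, S: int, scale_terms: tuple[str, ...], fixed_eta: int = N_ATTRIBUTES - 1):
        self.T, self.S = T, S
        self.scale_terms = scale_terms
        self.fixed_eta = fixed_eta
        self.eta_free = [a for a in range(N_ATTRIBUTES) if a != fixed_eta]
        self.n_theta = N_COEF + len(self.eta_free)
        self.n = T * self.n_theta + (S - 1) + S * len(scale_terms)

    def unpack(self, x: np.ndarray):
        pos = 0
        thetas = []
        for _ in range(self.T):
            beta = x[pos : pos + N_COEF]
            pos += N_COEF
            eta = np.zeros(N_ATTRIBUTES)
            for a in self.eta_free:
                eta[a] = x[pos]
                pos += 1
            thetas.append(np.concatenate([beta, eta]))
        log_factors = np.concatenate([[0.0], x[pos : pos + self.S - 1]])
        pos += self.S - 1
        k = len(self.scale_terms)
        gammas = [x[pos + s * k : pos + (s + 1) * k] for s in range(self.S)]
        return thetas, log_factors, gammas

    def pack(self, thetas, log_factors, gammas) -> np.ndarray:
        out = []
        for th in thetas:
            # re-anchor so the pinned ancillary is zero; BWS likelihoods are
            # invariant to this shift
            eta = th[N_COEF:] - th[N_COEF + self.fixed_eta]
            out.append(th[:N_COEF])
            out.append(eta[self.eta_free])
        out.append(np.asarray(log_factors)[1:])
        out.extend(np.asarray(g) for g in gammas)
        return np.concatenate(out) if out else np.zeros(0)


def _cell_ll_matrix(data: ChoiceData, pack: _SALCPack, x: np.ndarray) -> np.ndarray:
    """Per-respondent log-likelihood for every (taste, scale) cell."""
    thetas, log_factors, gammas = pack.unpack(x)
    n_resp = data.n_respondents
    out = np.zeros((n_resp, pack.T, pack.S))
    ptr = data.resp_ptr
    for c in range(pack.T):
        for s in range(pack.S):
            ll, _ = cell_loglik(
                data, thetas[c], gamma=gammas[s], z_terms=pack.scale_terms, log_factor=log_factors[s]
            )
            out[:, c, s] = np.add.reduceat(ll, ptr[:-1])
    return out


def salc_log_likelihood(
    data: ChoiceData,
    pack: _SALCPack,
    x: np.ndarray,
    log_pi: np.ndarray,
    log_omega: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mixture log-likelihood, its per-respondent terms, and the posterior
    cell memberships (log-sum-exp stabilized)."""
    cell = _cell_ll_matrix(data, pack, x)
    joint = cell + log_pi[:, :, None] + log_omega[:, None, :]
    flat = joint.reshape(len(joint), -1)
    ll_resp = logsumexp(flat, axis=1)
    post = np.exp(flat - ll_resp[:, None]).reshape(joint.shape)
    return float(ll_resp.sum()), ll_resp, post


def mixture_log_likelihood(
    observations, covariates: pd.DataFrame, fit: SALCFit, seq_norm: float = DEFAULT_SEQ_NORM
) -> float:
    """Mixture log-likelihood of a fitted SALC model on (possibly new) data."""
    data = observations if isinstance(observations, ChoiceData) else ChoiceData(observations, seq_norm)
    cov = _align_covariates(covariates, data.respondent_ids)
    Zt, _ = membership_design(cov, "taste")
    Zs, _ = membership_design(cov, "scale")
    pack, x = _gom_full_pack(fit)
    log_pi = np.log(np.clip(softmax_probs(Zt, fit.gom.taste_coefs), 1e-300, None))
    log_om = np.log(np.clip(softmax_probs(Zs, fit.gom.scale_coefs), 1e-300, None))
    ll, _, _ = salc_log_likelihood(data, pack, x, log_pi, log_om)
    return ll


def _m_step_choice(
    data: ChoiceData,
    pack: _SALCPack,
    x0: np.ndarray,
    post: np.ndarray,
    maxiter: int = 30,
) -> np.ndarray:
    """Posterior-weighted joint update of all choice-side parameters."""
    w_obs = post[data.resp_of_obs]  # (n_obs, T, S)

    def nll_grad(x):
        thetas, log_factors, gammas = pack.unpack(x)
        total = 0.0
        g_theta = [np.zeros(N_COEF + N_ATTRIBUTES) for _ in range(pack.T)]
        g_logf = np.zeros(pack.S)
        g_gamma = [np.zeros(len(pack.scale_terms)) for _ in range(pack.S)]
        for c in range(pack.T):
            for s in range(pack.S):
                w = w_obs[:, c, s]
                ll, gr = cell_loglik(
                    data,
                    thetas[c],
                    gamma=gammas[s],
                    z_terms=pack.scale_terms,
                    log_factor=log_factors[s],
                    weights=w,
                    grad=True,
                )
                total += float(ll @ w)
                g_theta[c] += gr["theta_bws"]
                g_logf[s] += gr["log_factor"]
                if len(pack.scale_terms):
                    g_gamma[s] += gr["gamma"]
        grad = []
        for c in range(pack.T):
            grad.append(g_theta[c][:N_COEF])
            grad.append(g_theta[c][N_COEF:][pack.eta_free])
        grad.append(g_logf[1:])
        grad.extend(g_gamma)
        return -total, -np.concatenate(grad)

    res = optimize.minimize(
        nll_grad, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-12}
    )
    return res.x


def _run_em(
    data: ChoiceData,
    Zt: np.ndarray,
    Zs: np.ndarray,
    pack: _SALCPack,
    x0: np.ndarray,
    taste_coefs: np.ndarray,
    scale_coefs: np.ndarray,
    max_iter: int,
    tol: float = 1e-7,
    m_step_iter: int = 30,
):
    x = x0.copy()
    path: list[float] = []
    post = None
    for it in range(max_iter):
        log_pi = np.log(np.clip(softmax_probs(Zt, taste_coefs), 1e-300, None))
        log_omega = np.log(np.clip(softmax_probs(Zs, scale_coefs), 1e-300, None))
        ll, _, post = salc_log_likelihood(data, pack, x, log_pi, log_omega)
        path.append(ll)
        if len(path) > 1 and abs(path[-1] - path[-2]) <= tol * (1.0 + abs(path[-2])):
            break
        # degenerate class: a taste or scale class with < 1 respondent of mass
        if post.sum(axis=(0, 2)).min() < 1.0 or post.sum(axis=(0, 1)).min() < 1.0:
            return x, taste_coefs, scale_coefs, path, post, True
        x = _m_step_choice(data, pack, x, post, maxiter=m_step_iter)
        taste_coefs = _fit_weighted_softmax(Zt, post.sum(axis=2), taste_coefs)
        scale_coefs = _fit_weighted_softmax(Zs, post.sum(axis=1), scale_coefs)
    return x, taste_coefs, scale_coefs, path, post, False


def em_fit_salc(
    observations: Sequence[ChoiceObservation] | ChoiceData,
    covariates: pd.DataFrame,
    T: int = 2,
    S: int = 2,
    scale_terms: Sequence[str] = SCALE_TERMS,
    n_starts: int = 10,
    seed: int = 0,
    max_em_iter: int = 200,
    short_run_iter: int = 25,
    seq_norm: float = DEFAULT_SEQ_NORM,
    compute_se: bool = True,
) -> SALCFit:
    """Fit the heteroskedastic SALC model by EM with multistart.

    Starts perturb the heteroskedastic-logit solution; each runs a short EM,
    the best continues to convergence.  Deterministic given ``seed``.
    """
    if T < 1 or S < 1:
        raise ValueError("T and S must be >= 1")
    data = observations if isinstance(observations, ChoiceData) else ChoiceData(observations, seq_norm)
    cov = _align_covariates(covariates, data.respondent_ids)
    if data.n_respondents < 50 * T * S:
        import warnings

        warnings.warn(
            f"only {data.n_respondents} respondents for {T * S} latent cells", stacklevel=2
        )
    Zt, taste_names = membership_design(cov, "taste")
    Zs, scale_names = membership_design(cov, "scale")
    terms = tuple(scale_terms)
    pack = _SALCPack(T, S, terms)

    hcl = fit_heteroskedastic_logit(data, scale_terms=terms, compute_se=False)
    theta0 = hcl.params.theta
    gamma0 = np.array([dict(zip(SCALE_TERMS, hcl.scale.gamma))[t] for t in terms])

    rng = np.random.default_rng(seed)
    candidates = []
    for start in range(max(1, n_starts)):
        if start == 0:
            # one structured start: a strong class plus a near-noise class
            thetas = [theta0 * (1.5 if c == 0 else 0.05 * 1.5**c) for c in range(T)]
            log_factors = np.linspace(0.0, np.log(0.5) if S > 1 else 0.0, S)
        else:
            thetas = [
                theta0 * rng.uniform(0.05, 2.0) + rng.normal(0.0, 0.3, len(theta0)) for _ in range(T)
            ]
            log_factors = np.concatenate([[0.0], rng.normal(-0.3, 0.6, S - 1)])
        gammas = [gamma0 + (0 if start == 0 else rng.normal(0, 0.2, len(terms))) for _ in range(S)]
        x0 = pack.pack(thetas, log_factors, gammas)
        tc0 = np.zeros((T - 1, Zt.shape[1]))
        sc0 = np.zeros((S - 1, Zs.shape[1]))
        x, tc, sc, path, post, degen = _run_em(
            data, Zt, Zs, pack, x0, tc0, sc0, max_iter=short_run_iter
        )
        if not degen:
            candidates.append((path[-1], x, tc, sc))
    if not candidates:
        raise RuntimeError("all EM starts collapsed to a degenerate class")
    candidates.sort(key=lambda t: t[0], reverse=True)
    _, x, tc, sc = candidates[0]
    x, tc, sc, path, post, degen = _run_em(data, Zt, Zs, pack, x, tc, sc, max_iter=max_em_iter)

    return _assemble_fit(
        data, pack, x, tc, sc, Zt, Zs, taste_names, scale_names, path, post,
        converged=not degen and len(path) < max_em_iter, compute_se=compute_se,
    )


def _assemble_fit(
    data, pack, x, tc, sc, Zt, Zs, taste_names, scale_names, path, post, converged, compute_se
) -> SALCFit:
    thetas, log_factors, gammas = pack.unpack(x)
    taste_params = []
    for th in thetas:
        beta, eta = th[:N_COEF].reshape(5, 4), th[N_COEF:]
        eta = eta - eta.min()  # re-anchor: smallest ancillary at zero
        taste_params.append(ValueSetParams(beta, eta))
    class_logits = np.array([p.beta.sum() for p in taste_params])
    n_gom = tc.size + sc.size
    n_params = pack.n + n_gom
    loglik = path[-1]
    bic, aic, caic = information_criteria(loglik, n_params, data.n_obs)
    fit = SALCFit(
        taste_params=taste_params,
        taste_params_pits=[pits_normalize(p) for p in taste_params],
        scale_factors=np.exp(log_factors),
        scale_models=[ScaleModel.from_terms(pack.scale_terms, g) for g in gammas],
        gom=GOMModel(tc, sc, taste_names, scale_names),
        posteriors=post,
        respondent_ids=list(data.respondent_ids),
        loglik=loglik,
        n_obs=data.n_obs,
        n_params=n_params,
        bic=bic,
        aic=aic,
        caic=caic,
        taste_shares=post.sum(axis=2).mean(axis=0),
        scale_shares=post.sum(axis=1).mean(axis=0),
        class_logits=class_logits,
        prob_best_over_worst=np.array([prob_best_over_worst(c) for c in class_logits]),
        converged=converged,
        n_em_iter=len(path),
        loglik_path=path,
        scale_terms=pack.scale_terms,
    )
    fit = relabel_classes(fit)
    if compute_se and (fit.T > 1 or fit.S > 1):
        fit.gom_cov = _gom_opg_cov(data, fit, Zt, Zs)
    return fit


def relabel_classes(fit: SALCFit) -> SALCFit:
    """Canonical ordering: taste classes by descending probability of
    choosing 11111 over 55555, scale classes by descending scale factor.
    Likelihood, posteriors and membership probabilities are invariant."""
    t_order = np.argsort(-fit.prob_best_over_worst, kind="stable")
    s_order = np.argsort(-fit.scale_factors, kind="stable")
    if np.array_equal(t_order, np.arange(fit.T)) and np.array_equal(s_order, np.arange(fit.S)):
        return fit
    fit.taste_params = [fit.taste_params[i] for i in t_order]
    fit.taste_params_pits = [fit.taste_params_pits[i] for i in t_order]
    fit.class_logits = fit.class_logits[t_order]
    fit.prob_best_over_worst = fit.prob_best_over_worst[t_order]
    fit.scale_models = [fit.scale_models[i] for i in s_order]
    new_ref = fit.scale_factors[s_order[0]]
    fit.scale_factors = fit.scale_factors[s_order] / new_ref
    fit.posteriors = fit.posteriors[:, t_order][:, :, s_order]
    fit.taste_shares = fit.taste_shares[t_order]
    fit.scale_shares = fit.scale_shares[s_order]
    # re-anchor reference-coded GOM logits to the new reference class
    fit.gom.taste_coefs = _reanchor_softmax(fit.gom.taste_coefs, t_order)
    fit.gom.scale_coefs = _reanchor_softmax(fit.gom.scale_coefs, s_order)
    return fit


def _reanchor_softmax(coefs: np.ndarray, order: np.ndarray) -> np.ndarray:
    if coefs.shape[0] == 0:
        return coefs
    full = np.concatenate([np.zeros((1, coefs.shape[1])), coefs])[order]
    return full[1:] - full[0]


def identify_garbage_class(fit: SALCFit, threshold: float = 0.60) -> dict:
    """Flag taste classes whose probability of preferring 11111 over 55555 is
    below ``threshold`` (default 0.60) as garbage; the remaining class with
    the highest probability is the value-set class."""
    probs = fit.prob_best_over_worst
    garbage = [int(i) for i in range(fit.T) if probs[i] < threshold]
    keep = [i for i in range(fit.T) if i not in garbage]
    report = {
        "garbage_classes": garbage,
        "prob_best_over_worst": probs.tolist(),
        "threshold": threshold,
    }
    if not keep:
        report["value_set_class"] = None
        report["status"] = "all taste classes flagged as garbage; no value set emitted"
    else:
        report["value_set_class"] = int(keep[int(np.argmax(probs[keep]))])
        report["status"] = "ok"
    return report


def _gom_full_pack(fit: SALCFit):
    pack = _SALCPack(fit.T, fit.S, fit.scale_terms)
    thetas = []
    for p in fit.taste_params:
        th = p.theta.copy()
        # the packed parameterization pins eta[fixed_eta] at zero; shift
        # invariance makes the re-anchored vector likelihood-equivalent
        th[N_COEF:] -= th[N_COEF + pack.fixed_eta]
        thetas.append(th)
    gammas = [np.array([dict(zip(SCALE_TERMS, m.gamma))[t] for t in fit.scale_terms]) for m in fit.scale_models]
    x = pack.pack(thetas, np.log(fit.scale_factors), gammas)
    return pack, x


def _gom_opg_cov(data: ChoiceData, fit: SALCFit, Zt, Zs) -> np.ndarray | None:
    """Outer-product-of-gradients covariance of the full parameter vector,
    returned for the GOM block (choice parameters held in the sandwich)."""
    pack, x_choice = _gom_full_pack(fit)
    n_t, n_s = fit.gom.taste_coefs.size, fit.gom.scale_coefs.size
    x_full = np.concatenate([x_choice, fit.gom.taste_coefs.ravel(), fit.gom.scale_coefs.ravel()])

    def resp_ll(v):
        xc = v[: pack.n]
        tc = v[pack.n : pack.n + n_t].reshape(fit.gom.taste_coefs.shape)
        sc = v[pack.n + n_t :].reshape(fit.gom.scale_coefs.shape)
        log_pi = np.log(np.clip(softmax_probs(Zt, tc), 1e-300, None))
        log_om = np.log(np.clip(softmax_probs(Zs, sc), 1e-300, None))
        _, ll_resp, _ = salc_log_likelihood(data, pack, xc, log_pi, log_om)
        return ll_resp

    n = len(x_full)
    scores = np.zeros((data.n_respondents, n))
    for i in range(n):
        h = 1e-5 * max(1.0, abs(x_full[i]))
        vp, vm = x_full.copy(), x_full.copy()
        vp[i] += h
        vm[i] -= h
        scores[:, i] = (resp_ll(vp) - resp_ll(vm)) / (2 * h)
    info = scores.T @ scores
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    return cov[pack.n :, pack.n :]


def gom_report(fit: SALCFit, alpha: float = 0.05) -> pd.DataFrame:
    """Odds-ratio table for the membership equations (garbage-class and
    low-scale-class membership), with Wald CIs when the information matrix
    allowed standard errors."""
    rows = []
    blocks = []
    for c in range(1, fit.T):
        blocks.append((f"taste_class_{c+1}", fit.gom.taste_names, fit.gom.taste_coefs[c - 1]))
    for s in range(1, fit.S):
        blocks.append((f"scale_class_{s+1}", fit.gom.scale_names, fit.gom.scale_coefs[s - 1]))
    se_all = None
    if fit.gom_cov is not None:
        d = np.diag(fit.gom_cov).copy()
        d[d <= 0] = np.nan
        se_all = np.sqrt(d)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    pos = 0
    with np.errstate(over="ignore"):
        for eq, names, coefs in blocks:
            for name, co in zip(names, coefs):
                se = se_all[pos] if se_all is not None else np.nan
                pos += 1
                rows.append(
                    {
                        "equation": eq,
                        "covariate": name,
                        "coef": co,
                        "odds_ratio": np.exp(co),
                        "or_ci_low": np.exp(co - zcrit * se) if np.isfinite(se) else np.nan,
                        "or_ci_high": np.exp(co + zcrit * se) if np.isfinite(se) else np.nan,
                        "pvalue": 2 * stats.norm.sf(abs(co / se)) if np.isfinite(se) and se > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
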