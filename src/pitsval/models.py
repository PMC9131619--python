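"""Maximum-likelihood choice models for the hybrid PC + BWS design.

Every response is a multinomial choice: two alternatives in a paired
comparison, five attribute-levels in a case-2 BWS task.  The utility of
alternative j in task t is ``lambda_t * x_j' theta`` where ``x_j`` is the
alternative's main-effect coding (polarity signs already built in), theta
stacks the twenty incremental decrements and five ancillary terms, and the
scale ``lambda_t = exp(gamma' z_t)`` is an exponential function of task-level
covariates (block-local sequence fraction, its square, and task-type
indicators with BWS-worst as the reference).  Setting gamma to zero gives
the conditional logit; the interaction model carries separate PC and BWS
decrement sets under a common scale function.

Scale and coefficients are confounded (scaling theta up and lambda down
leaves the likelihood unchanged), which is why the scale function has no
intercept, and why only four of the five ancillary terms are identified:
the smallest is constrained to zero after estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import (
    ATTRIBUTES,
    N_ATTRIBUTES,
    N_COEF,
    VEC_LEN,
    ChoiceObservation,
    TaskType,
)
from .valueset import ValueSetParams, pits_normalize

SCALE_TERMS = ("sequence", "sequence_sq", "pc", "best")
DEFAULT_SEQ_NORM = 25.0


@dataclass
class ScaleModel:
    """Task-level heteroskedasticity: lambda = exp(g1*s + g2*s^2 + g3*1[PC]
    + g4*1[BWS-best]), with s the block-local sequence fraction and BWS-worst
    at sequence 0 the reference (lambda = 1)."""

    gamma_seq: float = 0.0
    gamma_seq2: float = 0.0
    gamma_pc: float = 0.0
    gamma_best: float = 0.0

    @property
    def gamma(self) -> np.ndarray:
        return np.array([self.gamma_seq, self.gamma_seq2, self.gamma_pc, self.gamma_best])

    @classmethod
    def from_terms(cls, terms: Sequence[str], values: np.ndarray) -> "ScaleModel":
        full = dict.fromkeys(SCALE_TERMS, 0.0)
        full.update(dict(zip(terms, np.asarray(values, float))))
        return cls(full["sequence"], full["sequence_sq"], full["pc"], full["best"])


def scale_factor(
    scale: ScaleModel, seq_frac: float, task_type: TaskType | str = TaskType.BWS_WORST
) -> float:
    """Evaluate the scale function for one task."""
    t = TaskType(task_type)
    z = scale.gamma
    val = z[0] * seq_frac + z[1] * seq_frac**2
    val += z[2] * (t is TaskType.PC) + z[3] * (t is TaskType.BWS_BEST)
    return float(np.exp(val))


class ChoiceData:
    """Stacked arrays for a set of choice observations, sorted by respondent.

    ``X`` is (n_obs, 5, 25) with unused alternative slots zero; ``mask``
    flags the valid slots.  ``Z`` holds the four scale covariates in
    SCALE_TERMS order.
    """

    def __init__(self, observations: Sequence[ChoiceObservation], seq_norm: float = DEFAULT_SEQ_NORM):
        obs = sorted(observations, key=lambda o: (str(o.respondent_id), o.task_type.value, o.sequence))
        if not obs:
            raise ValueError("no choice observations")
        n = len(obs)
        self.X = np.zeros((n, 5, VEC_LEN))
        self.mask = np.zeros((n, 5), dtype=bool)
        self.chosen = np.zeros(n, dtype=np.int64)
        self.seq_frac = np.zeros(n)
        self.is_pc = np.zeros(n, dtype=bool)
        self.is_best = np.zeros(n, dtype=bool)
        resp_of_obs = np.zeros(n, dtype=np.int64)
        ids: list[str] = []
        index: dict[str, int] = {}
        for i, o in enumerate(obs):
            for j, alt in enumerate(o.alternatives):
                self.X[i, j] = alt.flat
                self.mask[i, j] = True
            self.chosen[i] = o.chosen
            self.seq_frac[i] = o.sequence / seq_norm
            self.is_pc[i] = o.task_type is TaskType.PC
            self.is_best[i] = o.task_type is TaskType.BWS_BEST
            rid = str(o.respondent_id)
            if rid not in index:
                index[rid] = len(ids)
                ids.append(rid)
            resp_of_obs[i] = index[rid]
        self.respondent_ids = ids
        self.resp_of_obs = resp_of_obs
        # contiguous blocks per respondent (observations were sorted by id)
        boundaries = np.flatnonzero(np.diff(resp_of_obs)) + 1
        self.resp_ptr = np.concatenate([[0], boundaries, [n]])
        self.Z = np.column_stack(
            [self.seq_frac, self.seq_frac**2, self.is_pc.astype(float), self.is_best.astype(float)]
        )
        self.n_obs = n
        self.n_respondents = len(ids)
        self._onehot = np.zeros((n, 5))
        self._onehot[np.arange(n), self.chosen] = 1.0

    @property
    def has_bws(self) -> bool:
        return bool((~self.is_pc).any())

    @property
    def has_pc(self) -> bool:
        return bool(self.is_pc.any())

    def z_columns(self, terms: Sequence[str]) -> np.ndarray:
        idx = [SCALE_TERMS.index(t) for t in terms]
        return self.Z[:, idx]


def _masked_log_softmax(U: np.ndarray, mask: np.ndarray):
    U = np.where(mask, U, -np.inf)
    m = np.max(U, axis=1)
    E = np.exp(U - m[:, None])
    E[~mask] = 0.0
    denom = E.sum(axis=1)
    lse = m + np.log(denom)
    P = E / denom[:, None]
    return lse, P


def cell_loglik(
    data: ChoiceData,
    theta_bws: np.ndarray,
    gamma: np.ndarray | None = None,
    z_terms: Sequence[str] = SCALE_TERMS,
    log_factor: float = 0.0,
    theta_pc: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    grad: bool = False,
):
    """Per-observation log-likelihood (and optionally gradients) for one
    parameter configuration.

    ``theta_bws`` (length 25) applies to all rows unless ``theta_pc`` is
    given, in which case PC rows use it instead.  ``log_factor`` is an extra
    additive term on log-lambda (the scale-class factor in SALC models).
    Returns ``(ll_obs, grads)`` with ``grads`` a dict (empty when ``grad`` is
    False) holding d/d theta_bws, theta_pc, gamma, log_factor of the weighted
    log-likelihood sum.
    """
    Zc = data.z_columns(z_terms) if len(z_terms) else np.zeros((data.n_obs, 0))
    loglam = log_factor + (Zc @ gamma if gamma is not None and len(z_terms) else 0.0)
    lam = np.exp(np.broadcast_to(loglam, (data.n_obs,)))
    S_b = data.X @ theta_bws
    if theta_pc is not None:
        S = np.where(data.is_pc[:, None], data.X @ theta_pc, S_b)
    else:
        S = S_b
    U = lam[:, None] * S
    lse, P = _masked_log_softmax(U, data.mask)
    ll_obs = U[np.arange(data.n_obs), data.chosen] - lse
    if not np.all(np.isfinite(ll_obs)):
        raise FloatingPointError("non-finite utilities in likelihood evaluation")
    grads: dict = {}
    if grad:
        w = np.ones(data.n_obs) if weights is None else weights
        W = (data._onehot - P) * (w * lam)[:, None]
        if theta_pc is not None:
            pc = data.is_pc
            grads["theta_pc"] = np.einsum("no,noa->a", W[pc], data.X[pc])
            grads["theta_bws"] = np.einsum("no,noa->a", W[~pc], data.X[~pc])
        else:
            grads["theta_bws"] = np.einsum("no,noa->a", W, data.X)
        s_resid = (S[np.arange(data.n_obs), data.chosen] - (P * S).sum(axis=1)) * lam * w
        if len(z_terms):
            grads["gamma"] = Zc.T @ s_resid
        grads["log_factor"] = float(s_resid.sum())
    return ll_obs, grads


# ---------------------------------------------------------------------------
# public likelihood helpers


def choice_probabilities(obs: ChoiceObservation, params: ValueSetParams, lam: float = 1.0) -> np.ndarray:
    """Multinomial choice probabilities for one task."""
    theta = params.theta
    u = lam * np.array([alt.flat @ theta for alt in obs.alternatives])
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite utilities")
    u -= u.max()
    e = np.exp(u)
    return e / e.sum()


def log_likelihood(
    observations: Sequence[ChoiceObservation] | ChoiceData,
    params: ValueSetParams,
    scale: ScaleModel | None = None,
    seq_norm: float = DEFAULT_SEQ_NORM,
) -> float:
    """Pooled log-likelihood; BWS best and worst responses to the same profile
    enter as two independent observations."""
    data = observations if isinstance(observations, ChoiceData) else ChoiceData(observations, seq_norm)
    gamma = (scale or ScaleModel()).gamma
    ll, _ = cell_loglik(data, params.theta, gamma=gamma)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# parameter packing and fitting


@dataclass
class _Pack:
    """Layout of the free-parameter vector for one model specification."""

    interaction: bool
    scale_terms: tuple[str, ...]
    fixed_eta: int | None  # attribute whose ancillary term is pinned to 0
    has_bws: bool

    def __post_init__(self) -> None:
        names: list[str] = []
        prefixes = ("beta_pc", "beta_bws") if self.interaction else ("beta",)
        for pref in prefixes:
            names += [f"{pref}[{ATTRIBUTES[a]},{k+1}]" for a in range(N_ATTRIBUTES) for k in range(4)]
        self.eta_free = (
            [a for a in range(N_ATTRIBUTES) if a != self.fixed_eta] if self.has_bws else []
        )
        names += [f"eta[{ATTRIBUTES[a]}]" for a in self.eta_free]
        names += [f"gamma[{t}]" for t in self.scale_terms]
        self.names = names
        self.n = len(names)

    def unpack(self, x: np.ndarray):
        pos = 0
        out: dict[str, np.ndarray] = {}
        if self.interaction:
            out["beta_pc"] = x[pos : pos + N_COEF]
            pos += N_COEF
        out["beta_bws"] = x[pos : pos + N_COEF]
        pos += N_COEF
        eta = np.zeros(N_ATTRIBUTES)
        for a in self.eta_free:
            eta[a] = x[pos]
            pos += 1
        out["eta"] = eta
        out["gamma"] = x[pos : pos + len(self.scale_terms)]
        return out

    def thetas(self, x: np.ndarray):
        p = self.unpack(x)
        theta_bws = np.concatenate([p["beta_bws"], p["eta"]])
        theta_pc = np.concatenate([p["beta_pc"], np.zeros(N_ATTRIBUTES)]) if self.interaction else None
        return theta_bws, theta_pc, p["gamma"]

    def assemble_grad(self, grads: dict) -> np.ndarray:
        g = []
        if self.interaction:
            g.append(grads["theta_pc"][:N_COEF])
        g.append(grads["theta_bws"][:N_COEF])
        g.append(grads["theta_bws"][N_COEF:][self.eta_free])
        if self.scale_terms:
            g.append(grads["gamma"])
        return np.concatenate(g)


@dataclass
class FitResult:
    """A converged (or not) maximum-likelihood fit."""

    params: ValueSetParams  # raw scale; pooled (or the BWS set for interaction fits)
    params_pits: ValueSetParams
    scale: ScaleModel
    loglik: float
    n_obs: int
    n_params: int
    bic: float
    aic: float
    caic: float
    se: np.ndarray
    pvalues: np.ndarray
    param_names: list[str]
    cov: np.ndarray | None
    converged: bool
    n_iter: int
    gradient_norm: float
    x: np.ndarray = field(repr=False, default=None)
    pack: _Pack = field(repr=False, default=None)
    # interaction-model extras
    params_pc: ValueSetParams | None = None
    params_pc_pits: ValueSetParams | None = None
    difference_tests: pd.DataFrame | None = None

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        se = dict(zip(self.param_names, self.se))
        pv = dict(zip(self.param_names, self.pvalues))
        sets = [("pooled", "beta", self.params, self.params_pits)]
        if self.params_pc is not None:
            sets = [
                ("PC", "beta_pc", self.params_pc, self.params_pc_pits),
                ("BWS", "beta_bws", self.params, self.params_pits),
            ]
        for task_set, pref, raw, pits in sets:
            for a in range(N_ATTRIBUTES):
                for k in range(4):
                    name = f"{pref}[{ATTRIBUTES[a]},{k+1}]"
                    rows.append(
                        {
                            "attribute": ATTRIBUTES[a],
                            "step": k + 1,
                            "task_set": task_set,
                            "raw_coef": raw.beta[a, k],
                            "pits_coef": pits.beta[a, k] if pits.scale == "pits" else np.nan,
                            "se": se.get(name, np.nan),
                            "pvalue": pv.get(name, np.nan),
                        }
                    )
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "bic": self.bic,
            "aic": self.aic,
            "caic": self.caic,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float, float]:
    """(BIC, AIC, CAIC) from a log-likelihood."""
    bic = -2.0 * loglik + n_params * np.log(n_obs)
    aic = -2.0 * loglik + 2.0 * n_params
    caic = -2.0 * loglik + n_params * (np.log(n_obs) + 1.0)
    return float(bic), float(aic), float(caic)


def _nll_grad(x: np.ndarray, data: ChoiceData, pack: _Pack):
    theta_bws, theta_pc, gamma = pack.thetas(x)
    ll, grads = cell_loglik(
        data, theta_bws, gamma=gamma, z_terms=pack.scale_terms, theta_pc=theta_pc, grad=True
    )
    return -float(ll.sum()), -pack.assemble_grad(grads)


def _numerical_hessian(fun_grad, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = fun_grad(xp)
        _, gm = fun_grad(xm)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _inference(fun_grad, x: np.ndarray):
    """Standard errors from the observed information (numerical Hessian of the
    negative log-likelihood); singular information yields NaN entries."""
    H = _numerical_hessian(fun_grad, x)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov).copy()
        bad = diag <= 0
        diag[bad] = np.nan
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(len(x), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = x / se
        pvalues = 2.0 * stats.norm.sf(np.abs(z))
    return cov, se, pvalues


def _check_scale_terms(data: ChoiceData, terms: Sequence[str]) -> tuple[str, ...]:
    terms = tuple(terms)
    unknown = [t for t in terms if t not in SCALE_TERMS]
    if unknown:
        raise ValueError(f"unknown scale terms {unknown}; choose from {SCALE_TERMS}")
    if terms:
        Zc = data.z_columns(terms)
        if np.linalg.matrix_rank(Zc) < len(terms):
            bad = []
            for i, t in enumerate(terms):
                others = np.delete(Zc, i, axis=1)
                resid = Zc[:, i] - others @ np.linalg.lstsq(others, Zc[:, i], rcond=None)[0]
                if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(Zc[:, i])):
                    bad.append(t)
            raise ValueError(f"collinear scale covariates: {bad or list(terms)}")
    return terms


def _run_fit(
    data: ChoiceData,
    pack: _Pack,
    x0: np.ndarray | None = None,
    gtol: float = 1e-7,
    maxiter: int = 500,
):
    x0 = np.zeros(pack.n) if x0 is None else np.asarray(x0, float)
    res = optimize.minimize(
        _nll_grad,
        x0,
        args=(data, pack),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
    )
    return res


def _shift_eta_to_smallest(pack: _Pack, x: np.ndarray, data: ChoiceData):
    """Re-anchor the ancillary terms so the smallest is the one fixed at zero.

    BWS likelihoods are invariant to adding a constant to all five ancillary
    terms, so the re-anchored solution is exactly the MLE of the re-fit with
    the smallest term constrained; a warm-started re-fit confirms it.
    """
    if not pack.eta_free:
        return pack, x
    p = pack.unpack(x)
    eta = p["eta"]
    amin = int(np.argmin(eta))
    if amin == pack.fixed_eta:
        return pack, x
    new_pack = _Pack(pack.interaction, pack.scale_terms, amin, pack.has_bws)
    shifted = eta - eta[amin]
    x_new = []
    if pack.interaction:
        x_new.append(p["beta_pc"])
    x_new.append(p["beta_bws"])
    x_new.append(shifted[new_pack.eta_free])
    if pack.scale_terms:
        x_new.append(p["gamma"])
    x_new = np.concatenate(x_new)
    res = _run_fit(data, new_pack, x0=x_new)
    return new_pack, res.x


def _build_result(
    data: ChoiceData, pack: _Pack, res, compute_se: bool = True, reanchor: bool = True
) -> FitResult:
    if reanchor:
        pack, x = _shift_eta_to_smallest(pack, res.x, data)
    else:
        x = res.x
    nll, g = _nll_grad(x, data, pack)
    loglik = -nll
    if compute_se:
        cov, se, pvalues = _inference(lambda v: _nll_grad(v, data, pack), x)
    else:
        cov, se, pvalues = None, np.full(pack.n, np.nan), np.full(pack.n, np.nan)
    p = pack.unpack(x)
    raw = ValueSetParams(p["beta_bws"].reshape(5, 4), p["eta"])
    scale = ScaleModel.from_terms(pack.scale_terms, p["gamma"])
    bic, aic, caic = information_criteria(loglik, pack.n, data.n_obs)
    out = FitResult(
        params=raw,
        params_pits=pits_normalize(raw),
        scale=scale,
        loglik=loglik,
        n_obs=data.n_obs,
        n_params=pack.n,
        bic=bic,
        aic=aic,
        caic=caic,
        se=se,
        pvalues=pvalues,
        param_names=pack.names,
        cov=cov,
        converged=bool(res.success),
        n_iter=int(res.nit),
        gradient_norm=float(np.linalg.norm(g, np.inf)),
        x=x,
        pack=pack,
    )
    if pack.interaction:
        raw_pc = ValueSetParams(p["beta_pc"].reshape(5, 4))
        out.params_pc = raw_pc
        out.params_pc_pits = pits_normalize(raw_pc)
        if cov is not None:
            out.difference_tests = _pits_difference_tests(x, cov, out)
    return out


def _pits_difference_tests(x: np.ndarray, cov: np.ndarray, fit: FitResult) -> pd.DataFrame:
    """Wald tests of the per-coefficient PC minus BWS difference.

    The two decrement sets are compared on the pits scale (each normalized by
    its own sum), because the raw PC and BWS coefficients carry different
    scale units; standard errors follow by the delta method through the
    normalization."""
    b_pc, b_bws = x[:N_COEF], x[N_COEF : 2 * N_COEF]

    def jac(b):
        s = b.sum()
        return (np.eye(N_COEF) * s - b[:, None]) / s**2

    J = np.zeros((N_COEF, len(x)))
    J[:, :N_COEF] = jac(b_pc)
    J[:, N_COEF : 2 * N_COEF] = -jac(b_bws)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    diff = b_pc / b_pc.sum() - b_bws / b_bws.sum()
    with np.errstate(invalid="ignore"):
        se = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
        pvals = 2.0 * stats.norm.sf(np.abs(diff / se))
    return pd.DataFrame(
        {
            "attribute": [ATTRIBUTES[j // 4] for j in range(N_COEF)],
            "step": [j % 4 + 1 for j in range(N_COEF)],
            "diff_pits": diff,
            "se_diff": se,
            "pvalue_diff": pvals,
        }
    )


def fit_conditional_logit(
    observations: Sequence[ChoiceObservation] | ChoiceData,
    seq_norm: float = DEFAULT_SEQ_NORM,
    compute_se: bool = True,
    maxiter: int = 500,
    fixed_eta: int | None = None,
) -> FitResult:
    """Homoskedastic conditional logit: IID errors, common decrements.

    ``fixed_eta`` pins a specific attribute's ancillary term at zero; by
    default the smallest estimate is the one constrained."""
    data = observations if isinstance(observations, ChoiceData) else ChoiceData(observations, seq_norm)
    auto = fixed_eta is None
    pin = (N_ATTRIBUTES - 1 if auto else fixed_eta) if data.has_bws else None
    pack = _Pack(False, (), pin, data.has_bws)
    res = _run_fit(data, pack, maxiter=maxiter)
    return _build_result(data, pack, res, compute_se, reanchor=auto)


def fit_heteroskedastic_logit(
    observations: Sequence[ChoiceObservation] | ChoiceData,
    scale_terms: Sequence[str] = SCALE_TERMS,
    seq_norm: float = DEFAULT_SEQ_NORM,
    compute_se: bool = True,
    maxiter: int = 500,
    fixed_eta: int | None = None,
) -> FitResult:
    """Heteroskedastic conditional logit: joint MLE of the decrements and the
    task-level scale coefficients (no respondent-level scale covariates)."""
    data = observations if isinstance(observations, ChoiceData) else ChoiceData(observations, seq_norm)
    terms = _check_scale_terms(data, scale_terms)
    auto = fixed_eta is None
    pin = (N_ATTRIBUTES - 1 if auto else fixed_eta) if data.has_bws else None
    pack = _Pack(False, terms, pin, data.has_bws)
    res = _run_fit(data, pack, maxiter=maxiter)
    return _build_result(data, pack, res, compute_se, reanchor=auto)


INTERACTION_SCALE_TERMS = ("sequence", "sequence_sq", "best")


def fit_interaction_model(
    observations: Sequence[ChoiceObservation] | ChoiceData,
    scale_terms: Sequence[str] = INTERACTION_SCALE_TERMS,
    seq_norm: float = DEFAULT_SEQ_NORM,
    compute_se: bool = True,
    maxiter: int = 500,
) -> FitResult:
    """Heteroskedastic logit with separate PC and BWS decrement sets under a
    common scale function, plus per-coefficient Wald tests of the PC - BWS
    difference on the pits scale.

    The PC task-type scale indicator is excluded: with a PC-specific
    decrement set it is confounded with that set's overall scale (the
    likelihood is flat along the trade-off), so the PC scale shift is
    absorbed into the PC coefficients and the comparison is made after pits
    normalization, which is invariant to it.
    """
    data = observations if isinstance(observations, ChoiceData) else ChoiceData(observations, seq_norm)
    if not (data.has_pc and data.has_bws):
        raise ValueError("interaction model needs both PC and BWS tasks")
    if "pc" in scale_terms:
        raise ValueError(
            "the 'pc' scale term is not identified in the interaction model "
            "(confounded with the scale of the PC decrement set)"
        )
    terms = _check_scale_terms(data, scale_terms)
    pack = _Pack(True, terms, N_ATTRIBUTES - 1, True)
    res = _run_fit(data, pack, maxiter=maxiter)
    return _build_result(data, pack, res, compute_se)
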