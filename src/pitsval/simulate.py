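"""Seeded generator of a full synthetic valuation study.

The generator emulates the study conditions the analysis assumes: a panel
of respondents (default 380 retained plus 5 planted click-throughs) who
each complete 25 case-2 BWS tasks on a fixed 25-profile design followed by
25 paired comparisons against the constant comparator 24242 (one pair
dominant, dropped at analysis time).  Respondents carry covariates drawn
independently from the study's published marginals; latent taste and scale
class memberships follow covariate-driven softmax equations; choices are
multinomial draws from the class- and task-specific logit probabilities.

The generating parameters mirror the published estimates: the value-set
taste class uses the published class-1 pits decrements at class logit 6.213
(probability 0.998 of preferring 11111 over 55555), the garbage class the
published class-2 decrements at logit 0.2161; the heteroskedastic scale
coefficients are (0.8419, -0.7427, -0.9930, 0.2424); the second scale class
halves the scale.  Every generated dataset is byte-identical for a given
configuration, and the generating truth is serialized alongside it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from . import tables
from .design import (
    DEFAULT_COMPARATOR,
    ChoiceObservation,
    TaskTemplate,
    TaskType,
    build_dual_design,
    bundled_design_profiles,
    parse_profile,
    weakly_dominates,
)
from .models import DEFAULT_SEQ_NORM
from .salc import SCALE_COVARIATES, TASTE_COVARIATES, membership_design, softmax_probs

#: sampling marginals of the respondent covariates (published Table-1 shares)
DEFAULT_MARGINALS = {
    "male": 0.521,
    "age": {"16-35": 0.326, "36-55": 0.308, "55+": 0.366},
    "education": {"low": 0.137, "middle": 0.518, "high": 0.345},
    "chronic": 0.571,
    "vas_lt70": 0.526,
    "failed_dominant": 0.190,
    "difficulty_bws": {"easy": 0.187, "neutral": 0.505, "difficult": 0.308},
    "difficulty_pc": {"easy": 0.161, "neutral": 0.455, "difficult": 0.384},
}

#: membership log-odds mirroring the published GOM odds ratios
DEFAULT_TASTE_GOM = {
    "female": np.log(0.5173),
    "age_16_35": np.log(2.4143),
    "age_55_plus": np.log(0.2100),
    "educ_low": np.log(0.6366),
    "educ_high": np.log(0.9140),
    "chronic": np.log(1.0643),
    "vas_lt70": np.log(1.8346),
}
DEFAULT_SCALE_GOM = {
    "female": np.log(1.0399),
    "age_16_35": np.log(1.1669),
    "age_55_plus": np.log(1.4360),
    "educ_low": np.log(0.8678),
    "educ_high": np.log(0.9635),
    "failed_dominant": np.log(3.1286),
    "found_easy": np.log(1.1337),
    "found_hard": np.log(0.6152),
}
GARBAGE_SHARE_TARGET = 0.29
LOW_SCALE_SHARE_TARGET = 0.59


def _default_taste_betas() -> list[np.ndarray]:
    b1 = tables.coefficient_column("taste_class_1").reshape(5, 4)
    b2 = tables.coefficient_column("taste_class_2").reshape(5, 4)
    logit1 = float(logit(tables.VALUE_SET_CLASS_PROB))
    logit2 = tables.GARBAGE_CLASS_LOGIT
    return [b1 / b1.sum() * logit1, b2 / b2.sum() * logit2]


@dataclass
class SyntheticTruth:
    """The generating parameters of a simulated study."""

    taste_betas: list[np.ndarray] = field(default_factory=_default_taste_betas)  # raw scale
    etas: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.0, 0.1, 0.5, 0.2]))
    gamma: np.ndarray = field(default_factory=lambda: np.array([0.8419, -0.7427, -0.9930, 0.2424]))
    scale_factors: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.5]))
    taste_gom: dict = field(default_factory=lambda: dict(DEFAULT_TASTE_GOM))
    scale_gom: dict = field(default_factory=lambda: dict(DEFAULT_SCALE_GOM))
    taste_gom_intercept: float | None = None  # calibrated when None
    scale_gom_intercept: float | None = None
    design_profiles: list[str] = field(default_factory=lambda: [str(p) for p in bundled_design_profiles()])
    comparator: str = DEFAULT_COMPARATOR
    seq_norm: float = DEFAULT_SEQ_NORM

    @property
    def class_logits(self) -> np.ndarray:
        return np.array([b.sum() for b in self.taste_betas])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taste_betas"] = [np.asarray(b).reshape(5, 4).tolist() for b in self.taste_betas]
        for k in ("etas", "gamma", "scale_factors"):
            d[k] = np.asarray(d[k]).tolist()
        d["class_logits"] = self.class_logits.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d.pop("class_logits", None)
        d["taste_betas"] = [np.asarray(b) for b in d["taste_betas"]]
        for k in ("etas", "gamma", "scale_factors"):
            d[k] = np.asarray(d[k])
        return cls(**d)


def sample_respondents(n: int, seed: int, marginals: dict | None = None) -> pd.DataFrame:
    """Independent categorical draws of respondent covariates."""
    m = DEFAULT_MARGINALS if marginals is None else marginals
    for key in ("age", "education", "difficulty_bws", "difficulty_pc"):
        probs = np.array(list(m[key].values()))
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"marginal {key!r} is not a probability vector")
    for key in ("male", "chronic", "vas_lt70", "failed_dominant"):
        if not 0.0 <= m[key] <= 1.0:
            raise ValueError(f"marginal {key!r} outside [0, 1]")
    rng = np.random.default_rng(seed)

    def cat(spec: dict) -> np.ndarray:
        keys = list(spec.keys())
        return np.array(keys)[rng.choice(len(keys), size=n, p=list(spec.values()))]

    return pd.DataFrame(
        {
            "respondent_id": [f"r{i:04d}" for i in range(1, n + 1)],
            "gender": np.where(rng.random(n) < m["male"], "male", "female"),
            "age_band": cat(m["age"]),
            "education": cat(m["education"]),
            "chronic_illness": (rng.random(n) < m["chronic"]).astype(int),
            "vas_band": np.where(rng.random(n) < m["vas_lt70"], "<70", ">=70"),
            "failed_dominant": (rng.random(n) < m["failed_dominant"]).astype(int),
            "difficulty_bws": cat(m["difficulty_bws"]),
            "difficulty_pc": cat(m["difficulty_pc"]),
        }
    )


def _enumerate_covariate_cells(names, marginals):
    """All covariate combinations with their independence probabilities, as a
    design-matrix row (without intercept) per cell."""
    import itertools

    m = marginals

    female_opts = [(0.0, 1 - m["male"]), (1.0, m["male"])]
    age_opts = [((1.0, 0.0), m["age"]["16-35"]), ((0.0, 0.0), m["age"]["36-55"]), ((0.0, 1.0), m["age"]["55+"])]
    educ_opts = [((1.0, 0.0), m["education"]["low"]), ((0.0, 0.0), m["education"]["middle"]), ((0.0, 1.0), m["education"]["high"])]
    chronic_opts = [(0.0, 1 - m["chronic"]), (1.0, m["chronic"])]
    vas_opts = [(0.0, 1 - m["vas_lt70"]), (1.0, m["vas_lt70"])]
    fail_opts = [(0.0, 1 - m["failed_dominant"]), (1.0, m["failed_dominant"])]
    diff_opts = [
        ((1.0, 0.0), m["difficulty_pc"]["easy"]),
        ((0.0, 0.0), m["difficulty_pc"]["neutral"]),
        ((0.0, 1.0), m["difficulty_pc"]["difficult"]),
    ]
    rows, probs = [], []
    if tuple(names) == TASTE_COVARIATES:
        for (f, pf), (ag, pa), (ed, pe), (ch, pc_), (va, pv) in itertools.product(
            female_opts, age_opts, educ_opts, chronic_opts, vas_opts
        ):
            rows.append([f, *ag, *ed, ch, va])
            probs.append(pf * pa * pe * pc_ * pv)
    elif tuple(names) == SCALE_COVARIATES:
        for (f, pf), (ag, pa), (ed, pe), (fl, pl), (df, pd_) in itertools.product(
            female_opts, age_opts, educ_opts, fail_opts, diff_opts
        ):
            rows.append([f, *ag, *ed, fl, *df])
            probs.append(pf * pa * pe * pl * pd_)
    else:
        raise ValueError("unknown covariate set")
    return np.array(rows), np.array(probs)


def calibrate_intercept(coef: dict, names, target: float, marginals: dict | None = None) -> float:
    """Intercept of a binary membership logit such that the population share
    of the non-reference class equals ``target`` under independent covariates
    with the given marginals."""
    m = DEFAULT_MARGINALS if marginals is None else marginals
    rows, probs = _enumerate_covariate_cells(names, m)
    slope = rows @ np.array([coef[n] for n in names])

    def share(b0):
        return float(probs @ expit(b0 + slope)) - target

    return float(optimize.brentq(share, -15.0, 15.0))


def assign_classes(
    respondents: pd.DataFrame, truth: SyntheticTruth, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent taste and scale class labels from the GOM equations."""
    t0 = truth.taste_gom_intercept
    s0 = truth.scale_gom_intercept
    if t0 is None:
        t0 = calibrate_intercept(truth.taste_gom, TASTE_COVARIATES, GARBAGE_SHARE_TARGET)
    if s0 is None:
        s0 = calibrate_intercept(truth.scale_gom, SCALE_COVARIATES, LOW_SCALE_SHARE_TARGET)
    Zt, t_names = membership_design(respondents, "taste")
    Zs, s_names = membership_design(respondents, "scale")
    tc = np.array([[t0] + [truth.taste_gom[n] for n in t_names[1:]]])
    sc = np.array([[s0] + [truth.scale_gom[n] for n in s_names[1:]]])
    rng = np.random.default_rng(seed)
    taste = (rng.random(len(respondents)) < softmax_probs(Zt, tc)[:, 1]).astype(int)
    scale = (rng.random(len(respondents)) < softmax_probs(Zs, sc)[:, 1]).astype(int)
    return taste, scale


def _task_z(task: TaskTemplate, seq_norm: float) -> np.ndarray:
    s = task.sequence / seq_norm
    return np.array(
        [s, s * s, float(task.task_type is TaskType.PC), float(task.task_type is TaskType.BWS_BEST)]
    )


def task_probabilities(
    tasks: list[TaskTemplate], truth: SyntheticTruth
) -> np.ndarray:
    """Choice probabilities per (taste class, scale class, task, alternative);
    unused alternative slots hold zero."""
    T, S = len(truth.taste_betas), len(truth.scale_factors)
    P = np.zeros((T, S, len(tasks), 5))
    for c in range(T):
        theta = np.concatenate([np.asarray(truth.taste_betas[c]).ravel(), truth.etas])
        for s in range(S):
            for t, task in enumerate(tasks):
                lam = truth.scale_factors[s] * np.exp(_task_z(task, truth.seq_norm) @ truth.gamma)
                u = lam * np.array([alt.flat @ theta for alt in task.alternatives])
                u -= u.max()
                e = np.exp(u)
                P[c, s, t, : len(e)] = e / e.sum()
    return P


def _draw_choice_matrix(
    respondents: pd.DataFrame,
    taste_labels: np.ndarray,
    scale_labels: np.ndarray,
    truth: SyntheticTruth,
    seed: int,
    click: np.ndarray,
):
    """Tasks and the (n_tasks, n_resp) matrix of chosen alternative indices."""
    profiles = [parse_profile(c) for c in truth.design_profiles]
    tasks = build_dual_design(profiles, parse_profile(truth.comparator))
    P = task_probabilities(tasks, truth)
    n = len(respondents)
    rng = np.random.default_rng(seed)
    failed = respondents["failed_dominant"].to_numpy().astype(bool)
    choices = np.zeros((len(tasks), n), dtype=int)
    for t, task in enumerate(tasks):
        probs = P[taste_labels, scale_labels, t, : task.n_alternatives]
        u = rng.random(n)
        choice = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
        choice = np.minimum(choice, task.n_alternatives - 1)
        if task.task_type is TaskType.PC:
            a, b = task.profiles
            if weakly_dominates(a, b) or weakly_dominates(b, a):
                # the rationality check: failing it means picking the worse state
                worse = 1 if weakly_dominates(a, b) else 0
                choice = np.where(failed, worse, 1 - worse)
            choice = np.where(click, 0, choice)
        choices[t] = choice
    return tasks, choices


def simulate_observations(
    respondents: pd.DataFrame,
    taste_labels: np.ndarray,
    scale_labels: np.ndarray,
    truth: SyntheticTruth,
    seed: int,
    click_through: np.ndarray | None = None,
    drop_dominant: bool = True,
) -> list[ChoiceObservation]:
    """Draw choices and return analysis-ready observations directly (the
    fast path for simulation studies; ``drop_dominant`` applies the
    analysis-time dominance filter)."""
    n = len(respondents)
    click = np.zeros(n, dtype=bool) if click_through is None else np.asarray(click_through, bool)
    tasks, choices = _draw_choice_matrix(respondents, taste_labels, scale_labels, truth, seed, click)
    rids = respondents["respondent_id"].tolist()
    out: list[ChoiceObservation] = []
    for t, task in enumerate(tasks):
        if drop_dominant and task.task_type is TaskType.PC:
            a, b = task.profiles
            if weakly_dominates(a, b) or weakly_dominates(b, a):
                continue
        codes = tuple(str(p) for p in task.profiles)
        for i, rid in enumerate(rids):
            out.append(
                ChoiceObservation(rid, task.task_type, task.sequence, task.alternatives,
                                  int(choices[t, i]), codes)
            )
    return out


def simulate_choices(
    respondents: pd.DataFrame,
    taste_labels: np.ndarray,
    scale_labels: np.ndarray,
    truth: SyntheticTruth,
    seed: int,
    click_through: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw every respondent's choices; returns the long-format frame.

    The dominant PC pair is included (it is dropped at analysis time) and its
    outcome is forced to agree with the respondent's failed-dominant flag.
    Click-through respondents answer every PC task with the first position.
    """
    n = len(respondents)
    click = np.zeros(n, dtype=bool) if click_through is None else np.asarray(click_through, bool)
    tasks, choice_mat = _draw_choice_matrix(respondents, taste_labels, scale_labels, truth, seed, click)
    rows: list[dict] = []
    rids = respondents["respondent_id"].tolist()
    for t, task in enumerate(tasks):
        choice = choice_mat[t]
        for i, rid in enumerate(rids):
            if task.task_type is TaskType.PC:
                for j, prof in enumerate(task.profiles):
                    rows.append(
                        {
                            "respondent_id": rid,
                            "task_type": task.task_type.value,
                            "sequence": task.sequence,
                            "alt_index": j,
                            "profile_code": str(prof),
                            "attribute_index": "",
                            "chosen": int(choice[i] == j),
                        }
                    )
            else:
                prof = task.profiles[0]
                for j in range(5):
                    rows.append(
                        {
                            "respondent_id": rid,
                            "task_type": task.task_type.value,
                            "sequence": task.sequence,
                            "alt_index": j,
                            "profile_code": str(prof),
                            "attribute_index": j + 1,
                            "chosen": int(choice[i] == j),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class StudyConfig:
    n_respondents: int = 380
    n_click_through: int = 5
    seed: int = 0
    marginals: dict | None = None
    truth: SyntheticTruth | None = None

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if self.n_click_through < 0:
            raise ValueError("n_click_through must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is required and must be an integer")


def generate_study(config: StudyConfig, outdir: str | Path | None = None):
    """Generate a complete synthetic study.

    Returns ``(choices, covariates, truth)``; when ``outdir`` is given the
    three artifacts are also written as ``choices.csv``, ``covariates.csv``
    and ``truth.json`` (byte-identical across runs with the same config).
    """
    truth = config.truth or SyntheticTruth()
    if truth.taste_gom_intercept is None:
        truth.taste_gom_intercept = calibrate_intercept(
            truth.taste_gom, TASTE_COVARIATES, GARBAGE_SHARE_TARGET, config.marginals
        )
    if truth.scale_gom_intercept is None:
        truth.scale_gom_intercept = calibrate_intercept(
            truth.scale_gom, SCALE_COVARIATES, LOW_SCALE_SHARE_TARGET, config.marginals
        )
    n_total = config.n_respondents + config.n_click_through
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    respondents = sample_respondents(n_total, int(seeds[0]), config.marginals)
    taste, scale = assign_classes(respondents, truth, int(seeds[1]))
    click = np.zeros(n_total, dtype=bool)
    if config.n_click_through:
        click[-config.n_click_through :] = True
    choices = simulate_choices(respondents, taste, scale, truth, int(seeds[2]), click)
    covariates = respondents.copy()
    covariates["taste_class_true"] = taste + 1
    covariates["scale_class_true"] = scale + 1
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        choices.to_csv(outdir / "choices.csv", index=False)
        covariates.to_csv(outdir / "covariates.csv", index=False)
        payload = truth.to_dict()
        payload["config"] = {
            "n_respondents": config.n_respondents,
            "n_click_through": config.n_click_through,
            "seed": config.seed,
        }
        with open(outdir / "truth.json", "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return choices, covariates, truth
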