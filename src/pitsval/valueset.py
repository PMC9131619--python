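"""Pits-scale value sets and the agreement statistics used to compare them.

A value set is determined by twenty incremental decrements.  On the pits
scale the decrements are normalized to sum to one so that the best profile
11111 has value 1 and the worst profile 55555 has value 0; the value of any
profile is 1 minus the sum of the decrements for every severity step it has
taken.  The sum of the raw (logit-scale) decrements is the log-odds of
choosing 11111 over 55555 and is kept alongside as the *class logit*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import ATTRIBUTES, N_ATTRIBUTES, N_COEF, N_STEPS, HealthProfile, parse_profile

ALL_PROFILE_CODES: tuple[str, ...] = tuple(
    "".join(str(l + 1) for l in prof) for prof in itertools.product(range(5), repeat=5)
)  # lexicographic, 3125 codes


@dataclass
class ValueSetParams:
    """Twenty incremental decrements plus five ancillary terms.

    ``beta`` has shape (5, 4), attribute-major; ``eta`` shape (5,).  ``scale``
    records whether beta is on the raw logit scale or pits-normalized;
    ``class_logit`` (sum of raw beta) is carried through normalization.
    """

    beta: np.ndarray
    eta: np.ndarray = field(default_factory=lambda: np.zeros(N_ATTRIBUTES))
    scale: str = "raw"
    class_logit: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).reshape(N_ATTRIBUTES, N_STEPS)
        self.eta = np.asarray(self.eta, dtype=float).reshape(N_ATTRIBUTES)

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.ravel()

    @property
    def theta(self) -> np.ndarray:
        """Length-25 parameter vector matching DesignVector.flat order."""
        return np.concatenate([self.beta.ravel(), self.eta])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"attribute": ATTRIBUTES[a], "step": k + 1, "coef": self.beta[a, k]}
            for a in range(N_ATTRIBUTES)
            for k in range(N_STEPS)
        ]
        return pd.DataFrame(rows)


def pits_normalize(params: ValueSetParams) -> ValueSetParams:
    """Normalize raw decrements to the pits scale (sum 1).

    The class logit is the raw sum; ancillary terms are reported unchanged
    (they have no effect on profile values).  A non-positive raw sum has no
    pits interpretation: the input is returned unchanged with
    ``scale='raw-unnormalizable'``.
    """
    total = float(params.beta.sum())
    if params.scale != "raw":
        raise ValueError(f"expected raw-scale params, got scale={params.scale!r}")
    if total <= 0:
        return ValueSetParams(params.beta, params.eta, "raw-unnormalizable", total)
    return ValueSetParams(params.beta / total, params.eta, "pits", total)


def profile_value(params: ValueSetParams, profile: HealthProfile | str) -> float:
    """Pits value of one profile: 1 minus the cumulated decrements."""
    if isinstance(profile, str):
        profile = parse_profile(profile)
    if params.scale != "pits":
        raise ValueError("profile values need pits-normalized params")
    return 1.0 - sum(params.beta[a, : lev - 1].sum() for a, lev in enumerate(profile.levels))


def expand_all_profiles(params: ValueSetParams) -> pd.Series:
    """Values of all 3,125 profiles, indexed by code in lexicographic order."""
    if params.scale != "pits":
        raise ValueError("value tables need pits-normalized params")
    cum = np.concatenate([np.zeros((N_ATTRIBUTES, 1)), np.cumsum(params.beta, axis=1)], axis=1)
    idx = np.array(list(itertools.product(range(5), repeat=5)))
    values = 1.0 - cum[np.arange(N_ATTRIBUTES), idx].sum(axis=1)
    return pd.Series(values, index=list(ALL_PROFILE_CODES), name="value")


def value_table_from_column(beta20: np.ndarray) -> pd.Series:
    """Convenience: pits-normalize a 20-coefficient column and expand it."""
    return expand_all_profiles(pits_normalize(ValueSetParams(np.asarray(beta20, float))))


# ---------------------------------------------------------------------------
# agreement statistics


@dataclass
class AgreementReport:
    pearson: float
    pearson_ci: tuple[float, float]
    lin_ccc: float
    lin_ccc_ci: tuple[float, float]
    median_abs_diff: float
    iqr_abs_diff: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "pearson_ci": list(self.pearson_ci),
            "lin_ccc": self.lin_ccc,
            "lin_ccc_ci": list(self.lin_ccc_ci),
            "median_abs_diff": self.median_abs_diff,
            "iqr_abs_diff": list(self.iqr_abs_diff),
            "n": self.n,
        }


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("agreement undefined for a zero-variance input")
    return x, y


def pearson_with_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Product-moment correlation with a Fisher-z 95% CI."""
    x, y = _check_pair(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def lin_ccc_with_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a z-transform 95% CI.

    rho_c = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), with sample
    (n-1 denominator) moments.
    """
    x, y = _check_pair(x, y)
    n = len(x)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    sx2, sy2 = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    d = float(np.mean(x) - np.mean(y))
    ccc = 2 * sxy / (sx2 + sy2 + d * d)
    # asymptotic variance of atanh(ccc) (Lin 1989)
    r = sxy / np.sqrt(sx2 * sy2)
    u = d / (sx2 * sy2) ** 0.25
    c = np.clip(ccc, -0.999999, 0.999999)
    var_z = (
        (1 - r**2) * c**2 / ((1 - c**2) * r**2)
        + 2 * c**3 * (1 - c) * u**2 / (r * (1 - c**2) ** 2)
        - c**4 * u**4 / (2 * r**2 * (1 - c**2) ** 2)
    ) / (n - 2)
    z = np.arctanh(c)
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var_z, 0.0))
    return float(ccc), (float(np.tanh(z - half)), float(np.tanh(z + half)))


def abs_diff_summary(x, y) -> tuple[float, tuple[float, float]]:
    """Median and (25th, 75th) percentiles of |x - y| using linear-interpolation
    quantiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be equal-length")
    d = np.abs(x - y)
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    return float(q50), (float(q25), float(q75))


def parse_pvalue(p) -> float:
    """Parse a printed p-value; entries like '<0.001' become 0.0005."""
    if isinstance(p, (int, float, np.floating)):
        v = float(p)
    else:
        s = str(p).strip().replace(" ", "")
        if s.startswith("<"):
            v = float(s[1:]) / 2.0
        else:
            v = float(s)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    return v


def count_significant(pvalues, alpha: float = 0.05) -> int:
    """Number of p-values strictly below ``alpha``."""
    return int(sum(parse_pvalue(p) < alpha for p in pvalues))


def max_abs_coefficient_diff(beta_a, beta_b) -> tuple[float, int]:
    """Largest absolute element-wise difference and its (flat) index."""
    a = np.asarray(beta_a, dtype=float).ravel()
    b = np.asarray(beta_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("coefficient vectors must be equal-length")
    d = np.abs(a - b)
    i = int(np.argmax(d))
    return float(d[i]), i


def scale_peak_position(gamma_seq: float, gamma_seq2: float, n_tasks: int = 25):
    """Task position (1..n_tasks) at which the scale function
    exp(g1*s + g2*s^2), s = position/n_tasks, is largest.

    With g2 >= 0 there is no interior maximum and None is returned.
    """
    if gamma_seq2 >= 0:
        return None
    s_star = -gamma_seq / (2.0 * gamma_seq2)
    pos = int(round(s_star * n_tasks))
    return int(np.clip(pos, 1, n_tasks))


def prob_best_over_worst(class_logit: float) -> float:
    """Probability of choosing 11111 over 55555 from a class log-odds value."""
    return float(expit(class_logit))


def compare_value_sets(x, y) -> AgreementReport:
    """Full agreement report between two equal-length value vectors (typically
    two 3,125-profile tables or two 20-coefficient sets)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, rci = pearson_with_ci(x, y)
    c, cci = lin_ccc_with_ci(x, y)
    med, iqr = abs_diff_summary(x, y)
    return AgreementReport(r, rci, c, cci, med, iqr, len(x))


def compare_to_external_valueset(params: ValueSetParams, external_path) -> dict:
    """Compare a fitted value set to an externally supplied 20-coefficient
    file (columns attribute, step, coefficient).  The original Dutch EQ-VT
    value set is not bundled; its file must be provided by the user."""
    try:
        ext = pd.read_csv(external_path)
    except FileNotFoundError as e:
        raise FileNotFoundError(
            f"external value-set data required but not found: {external_path}"
        ) from e
    cols = {c.lower(): c for c in ext.columns}
    for need in ("attribute", "step", "coefficient"):
        if need not in cols:
            raise ValueError(f"external value-set file must have a {need!r} column")
    order = {a: i for i, a in enumerate(ATTRIBUTES)}
    ext = ext.sort_values(
        [cols["attribute"], cols["step"]],
        key=lambda s: s.map(order) if s.name == cols["attribute"] else s,
    )
    ext_beta = ext[cols["coefficient"]].to_numpy(float)
    if len(ext_beta) != N_COEF:
        raise ValueError(f"external value set must have {N_COEF} coefficients")
    mine = params if params.scale == "pits" else pits_normalize(params)
    ext_params = pits_normalize(ValueSetParams(ext_beta))
    return {
        "coefficients": compare_value_sets(mine.beta_flat, ext_params.beta_flat).to_dict(),
        "values_3125": compare_value_sets(
            expand_all_profiles(mine).to_numpy(), expand_all_profiles(ext_params).to_numpy()
        ).to_dict(),
    }
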