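"""Loaders for the published Dutch EQ-5D-5L coefficient tables.

These fixture files transcribe the coefficient columns of the published
Dutch PC+BWS valuation study (conditional logit, heteroskedastic logit, the
PC/BWS interaction columns, and the two SALC taste classes, all on the pits
scale), plus the heteroskedastic scale coefficients.  They let the
comparison statistics of that study be recomputed without any estimation
run.  p-values printed as "<0.001" are kept verbatim as strings.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .design import ATTRIBUTES, N_STEPS

#: class log-odds of choosing 11111 over 55555 printed for the garbage class
GARBAGE_CLASS_LOGIT = 0.2161
#: probability analogue for the value-set class
VALUE_SET_CLASS_PROB = 0.998

MODELS = ("conditional", "heteroskedastic", "pc", "bws", "taste_class_1", "taste_class_2")


def _read(name: str) -> pd.DataFrame:
    with resources.files("pitsval.data").joinpath(name).open("rt") as fh:
        return pd.read_csv(fh, dtype={"pvalue": str, "pvalue_diff": str})


def published_coefficients() -> pd.DataFrame:
    """Long table: attribute, step (1..4), model, coef (pits scale), pvalue."""
    return _read("published_coefficients.csv")


def coefficient_column(model: str) -> np.ndarray:
    """The 20 pits-scale decrements of one published column, attribute-major
    (mobility steps 1-2..4-5 first), as a length-20 array."""
    if model not in MODELS:
        raise ValueError(f"unknown model column {model!r}; choose from {MODELS}")
    df = published_coefficients()
    df = df[df["model"] == model]
    order = {a: i for i, a in enumerate(ATTRIBUTES)}
    df = df.sort_values(["attribute", "step"], key=lambda s: s.map(order) if s.name == "attribute" else s)
    out = df["coef"].to_numpy(float)
    if out.shape != (len(ATTRIBUTES) * N_STEPS,):
        raise ValueError(f"column {model!r} is incomplete")
    return out


def pvalue_column(model: str) -> list[str]:
    df = published_coefficients()
    df = df[df["model"] == model]
    order = {a: i for i, a in enumerate(ATTRIBUTES)}
    df = df.sort_values(["attribute", "step"], key=lambda s: s.map(order) if s.name == "attribute" else s)
    return df["pvalue"].tolist()


def interaction_difference_pvalues() -> list[str]:
    """Per-coefficient p-values for the PC minus BWS difference within the
    heteroskedastic interaction model."""
    df = _read("published_interaction_pvalues.csv")
    order = {a: i for i, a in enumerate(ATTRIBUTES)}
    df = df.sort_values(["attribute", "step"], key=lambda s: s.map(order) if s.name == "attribute" else s)
    return df["pvalue_diff"].tolist()


def published_scale_coefficients() -> dict[str, float]:
    """Heteroskedastic scale-function coefficients: sequence, sequence
    squared, PC indicator, BWS-best indicator (BWS-worst is the reference)."""
    df = _read("published_scale.csv")
    return dict(zip(df["term"], df["coef"].astype(float)))
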