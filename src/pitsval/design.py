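"""EQ-5D-5L profiles, main-effect design coding, and dual PC/BWS task construction.

The EQ-5D-5L descriptive system has five attributes (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each with five
severity levels.  A health profile is written as a 5-digit code, e.g.
``"32512"``.  The main-effect specification codes a profile with twenty
*incremental* indicators — one per level-k -> level-(k+1) step within an
attribute — plus five *ancillary* terms for the hypothetical level-0 -> 1
step relative to an ideal '00000' state that lies outside the descriptive
system.  Ancillary terms cancel in paired comparisons and only matter for
case-2 best-worst scaling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_ATTRIBUTES = 5
N_STEPS = 4
N_COEF = N_ATTRIBUTES * N_STEPS  # 20 incremental coefficients
VEC_LEN = N_COEF + N_ATTRIBUTES  # plus 5 ancillary terms

ATTRIBUTES = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: constant comparator used as 'Health profile B' in every paired comparison
DEFAULT_COMPARATOR = "24242"


class TaskType(str, enum.Enum):
    PC = "PC"
    BWS_BEST = "BWS_BEST"
    BWS_WORST = "BWS_WORST"


@dataclass(frozen=True, order=True)
class HealthProfile:
    """An EQ-5D-5L health state: five attribute levels, each in 1..5."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != N_ATTRIBUTES:
            raise ValueError(f"profile needs {N_ATTRIBUTES} levels, got {len(self.levels)}")
        for pos, lev in enumerate(self.levels):
            if not (isinstance(lev, (int, np.integer)) and 1 <= lev <= 5):
                raise ValueError(f"level {lev!r} at position {pos + 1} is not in 1..5")

    def __str__(self) -> str:
        return "".join(str(l) for l in self.levels)

    @property
    def code(self) -> str:
        return str(self)


def parse_profile(code: str) -> HealthProfile:
    """Parse a 5-digit profile code such as ``"32512"``."""
    if not isinstance(code, str) or len(code) != N_ATTRIBUTES:
        raise ValueError(f"profile code must be a 5-character string, got {code!r}")
    for pos, ch in enumerate(code):
        if ch not in "12345":
            raise ValueError(f"character {ch!r} at position {pos + 1} of {code!r} is not in '1'..'5'")
    return HealthProfile(tuple(int(c) for c in code))


@dataclass
class DesignVector:
    """Main-effect coding of an alternative.

    ``incremental`` has shape (5, 4): entry (a, k) belongs to the step from
    level k+1 to k+2 of attribute a.  ``ancillary`` has shape (5,): the 0 -> 1
    terms.  ``flat`` concatenates both into a length-25 vector ordered
    attribute-major (mobility steps 1-2..4-5, ..., then the five ancillaries).
    """

    incremental: np.ndarray
    ancillary: np.ndarray = field(default_factory=lambda: np.zeros(N_ATTRIBUTES))

    def __post_init__(self) -> None:
        self.incremental = np.asarray(self.incremental, dtype=float).reshape(N_ATTRIBUTES, N_STEPS)
        self.ancillary = np.asarray(self.ancillary, dtype=float).reshape(N_ATTRIBUTES)

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate([self.incremental.ravel(), self.ancillary])

    def __neg__(self) -> "DesignVector":
        return DesignVector(-self.incremental, -self.ancillary)

    def __sub__(self, other: "DesignVector") -> "DesignVector":
        return DesignVector(self.incremental - other.incremental, self.ancillary - other.ancillary)


def incremental_indicator(profile: HealthProfile) -> DesignVector:
    """Indicator coding of a profile: (a, k) is 1 iff the level of attribute a
    exceeds k+1; every ancillary entry is 1 (each attribute is at level >= 1
    relative to the hypothetical '00000' ideal)."""
    inc = np.zeros((N_ATTRIBUTES, N_STEPS))
    for a, lev in enumerate(profile.levels):
        inc[a, : lev - 1] = 1.0
    return DesignVector(inc, np.ones(N_ATTRIBUTES))


def pc_difference_vector(a: HealthProfile, b: HealthProfile) -> DesignVector:
    """Difference coding for the paired comparison of profile ``a`` against
    ``b``; the ancillary terms cancel and are identically zero."""
    d = incremental_indicator(a) - incremental_indicator(b)
    d.ancillary[:] = 0.0
    return d


def bws_alternative_vector(profile: HealthProfile, attribute: int, polarity: str) -> DesignVector:
    """Coding of one attribute-level alternative in a case-2 BWS task.

    ``attribute`` is 1-based.  For attribute a at level l the vector carries
    sign * (ancillary_a + incremental steps k < l); ``polarity`` is ``"best"``
    (sign -1) or ``"worst"`` (sign +1).
    """
    if not 1 <= attribute <= N_ATTRIBUTES:
        raise ValueError(f"attribute index {attribute} not in 1..5")
    if polarity not in ("best", "worst"):
        raise ValueError(f"polarity must be 'best' or 'worst', got {polarity!r}")
    sign = -1.0 if polarity == "best" else 1.0
    a = attribute - 1
    lev = profile.levels[a]
    inc = np.zeros((N_ATTRIBUTES, N_STEPS))
    inc[a, : lev - 1] = sign
    anc = np.zeros(N_ATTRIBUTES)
    anc[a] = sign
    return DesignVector(inc, anc)


@dataclass
class TaskTemplate:
    """One choice task before any respondent answers it.

    For PC, ``profiles`` holds (profile A, comparator) and ``alternatives``
    their difference-free codings (one vector per profile).  For BWS the five
    alternatives are the profile's attribute-levels.
    """

    task_type: TaskType
    sequence: int
    profiles: tuple[HealthProfile, ...]
    alternatives: list[DesignVector]

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)


from functools import lru_cache


@lru_cache(maxsize=8192)
def _cached_pc_alternatives(code_a: str, code_b: str) -> tuple[DesignVector, DesignVector]:
    return tuple(_pc_alternatives(parse_profile(code_a), parse_profile(code_b)))


@lru_cache(maxsize=8192)
def _cached_bws_alternative(code: str, attribute: int, polarity: str) -> DesignVector:
    return bws_alternative_vector(parse_profile(code), attribute, polarity)


def _pc_alternatives(a: HealthProfile, b: HealthProfile) -> list[DesignVector]:
    # utility of a profile is minus its incremental load; ancillary terms are
    # common to both alternatives and dropped (they cancel in the logit)
    va = -incremental_indicator(a)
    vb = -incremental_indicator(b)
    va.ancillary[:] = 0.0
    vb.ancillary[:] = 0.0
    return [va, vb]


def build_dual_design(
    profiles: Sequence[HealthProfile],
    comparator: HealthProfile | str = DEFAULT_COMPARATOR,
) -> list[TaskTemplate]:
    """Build the dual design: a BWS-best and BWS-worst task per profile
    (sequence 1..25) followed by one PC task per profile against the constant
    comparator (sequence 1..25, renumbered after dominance filtering)."""
    if isinstance(comparator, str):
        comparator = parse_profile(comparator)
    profiles = list(profiles)
    if len(profiles) != 25:
        raise ValueError(f"dual design needs exactly 25 profiles, got {len(profiles)}")
    if len({str(p) for p in profiles}) != 25:
        raise ValueError("design profiles must be distinct")
    tasks: list[TaskTemplate] = []
    for seq, prof in enumerate(profiles, start=1):
        for ttype, pol in ((TaskType.BWS_BEST, "best"), (TaskType.BWS_WORST, "worst")):
            alts = [bws_alternative_vector(prof, a + 1, pol) for a in range(N_ATTRIBUTES)]
            tasks.append(TaskTemplate(ttype, seq, (prof,), alts))
    for seq, prof in enumerate(profiles, start=1):
        tasks.append(TaskTemplate(TaskType.PC, seq, (prof, comparator), _pc_alternatives(prof, comparator)))
    return tasks


def weakly_dominates(a: HealthProfile, b: HealthProfile) -> bool:
    """True iff ``a`` is at least as good as ``b`` on every attribute (level
    <=) and strictly better on at least one."""
    la, lb = np.array(a.levels), np.array(b.levels)
    return bool(np.all(la <= lb) and np.any(la < lb))


def filter_dominant_pairs(tasks: Iterable[TaskTemplate]) -> tuple[list[TaskTemplate], list[TaskTemplate]]:
    """Drop PC tasks where one profile weakly dominates the other.

    Surviving PC tasks are renumbered 1..n within the PC block; BWS tasks are
    untouched.  Returns (kept, removed).
    """
    kept: list[TaskTemplate] = []
    removed: list[TaskTemplate] = []
    pc_seq = 0
    for t in tasks:
        if t.task_type is TaskType.PC:
            a, b = t.profiles
            if weakly_dominates(a, b) or weakly_dominates(b, a):
                removed.append(t)
                continue
            pc_seq += 1
            kept.append(TaskTemplate(t.task_type, pc_seq, t.profiles, t.alternatives))
        else:
            kept.append(t)
    return kept, removed


def detect_click_through(pc_choices: Sequence[int]) -> bool:
    """True iff a respondent gave the same PC response position every time
    (no variation in responses).  Needs at least two PC responses."""
    if len(pc_choices) < 2:
        raise ValueError("click-through is indeterminate with fewer than 2 PC responses")
    first = pc_choices[0]
    return all(c == first for c in pc_choices)


# ---------------------------------------------------------------------------
# file interfaces

CHOICE_COLUMNS = [
    "respondent_id",
    "task_type",
    "sequence",
    "alt_index",
    "profile_code",
    "attribute_index",
    "chosen",
]


def read_profiles(path) -> list[HealthProfile]:
    """Read one 5-digit profile code per line (optional 'profile' header)."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip()
            if not tok or tok.lower() in ("profile", "code"):
                continue
            out.append(parse_profile(tok))
    return out


def bundled_design_profiles() -> list[HealthProfile]:
    """The packaged synthetic 25-profile design: a balanced orthogonal-array
    style plan (each level appears 5 times per attribute) with exactly one
    profile dominant against the 24242 comparator, placed last so dropping it
    leaves PC sequence numbers 1..24 intact.  It is a synthetic stand-in for
    a study-specific OMEP design and carries no empirical content."""
    with resources.files("pitsval.data").joinpath("design_profiles.txt").open("rt") as fh:
        return [parse_profile(t.strip()) for t in fh if t.strip()]


def choices_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


@dataclass
class ChoiceObservation:
    """One answered task: the alternatives' design vectors plus the chosen
    index, its block-local sequence position and the respondent it belongs
    to."""

    respondent_id: str
    task_type: TaskType
    sequence: int
    alternatives: list[DesignVector]
    chosen: int
    profile_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.alternatives)
        want = 2 if self.task_type is TaskType.PC else 5
        if n != want:
            raise ValueError(f"{self.task_type.value} task needs {want} alternatives, got {n}")
        if not 0 <= self.chosen < n:
            raise ValueError(f"chosen index {self.chosen} out of range for {n} alternatives")


def read_choice_data(path) -> list[ChoiceObservation]:
    """Read the long-format choice CSV (one row per task x alternative).

    Columns: respondent_id, task_type (PC|BWS_BEST|BWS_WORST), sequence,
    alt_index (0-based), profile_code, attribute_index (1..5, BWS only),
    chosen (0/1).  PC rows carry each alternative's own profile code; BWS rows
    repeat the single profile under evaluation and identify the alternative by
    attribute_index.
    """
    df = pd.read_csv(path, dtype={"profile_code": str, "respondent_id": str})
    return observations_from_frame(df)


def observations_from_frame(df: pd.DataFrame) -> list[ChoiceObservation]:
    """Build observations from an in-memory long-format choice frame."""
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice file is missing columns: {missing}")
    df = df.copy()
    df["profile_code"] = df["profile_code"].astype(str)
    df["respondent_id"] = df["respondent_id"].astype(str)
    df = df.sort_values(["respondent_id", "task_type", "sequence", "alt_index"], kind="mergesort")
    rid = df["respondent_id"].to_numpy()
    tt = df["task_type"].to_numpy()
    seq = df["sequence"].to_numpy()
    codes_col = df["profile_code"].to_numpy()
    attr_col = df["attribute_index"].to_numpy()
    chosen_col = df["chosen"].to_numpy(dtype=int)
    change = np.ones(len(df), dtype=bool)
    change[1:] = (rid[1:] != rid[:-1]) | (tt[1:] != tt[:-1]) | (seq[1:] != seq[:-1])
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], len(df))
    obs: list[ChoiceObservation] = []
    for s, e in zip(starts, ends):
        ttype = TaskType(tt[s])
        chosen_rows = np.flatnonzero(chosen_col[s:e] == 1)
        if len(chosen_rows) != 1:
            raise ValueError(
                f"task ({rid[s]}, {ttype.value}, {seq[s]}) must have exactly one chosen row"
            )
        if ttype is TaskType.PC:
            codes = tuple(codes_col[s:e])
            alts = list(_cached_pc_alternatives(*codes))
        else:
            pol = "best" if ttype is TaskType.BWS_BEST else "worst"
            codes = (codes_col[s],)
            alts = [_cached_bws_alternative(codes[0], int(a), pol) for a in attr_col[s:e]]
        obs.append(ChoiceObservation(str(rid[s]), ttype, int(seq[s]), alts, int(chosen_rows[0]), codes))
    return obs


def apply_cleaning(
    observations: list[ChoiceObservation],
) -> tuple[list[ChoiceObservation], dict]:
    """Apply the two data-cleaning rules: drop PC tasks whose profile pair is
    dominant, then drop respondents who clicked through the PC block (no
    variation in chosen position).  PC sequences are renumbered 1..n after the
    dominance drop.  Returns (clean observations, log dict)."""
    kept: list[ChoiceObservation] = []
    n_dominant = 0
    for o in observations:
        if o.task_type is TaskType.PC and len(o.profile_codes) == 2:
            a, b = (parse_profile(c) for c in o.profile_codes)
            if weakly_dominates(a, b) or weakly_dominates(b, a):
                n_dominant += 1
                continue
        kept.append(o)
    # renumber PC sequences per respondent
    by_resp: dict[str, list[ChoiceObservation]] = {}
    for o in kept:
        by_resp.setdefault(o.respondent_id, []).append(o)
    clean: list[ChoiceObservation] = []
    click_through: list[str] = []
    for rid, obs in by_resp.items():
        pcs = sorted((o for o in obs if o.task_type is TaskType.PC), key=lambda o: o.sequence)
        for new_seq, o in enumerate(pcs, start=1):
            o.sequence = new_seq
        if len(pcs) >= 2 and detect_click_through([o.chosen for o in pcs]):
            click_through.append(rid)
            continue
        clean.extend(obs)
    log = {
        "n_respondents_in": len(by_resp),
        "n_dominant_pc_dropped": n_dominant,
        "click_through_respondents": click_through,
        "n_respondents_out": len(by_resp) - len(click_through),
    }
    return clean, log
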