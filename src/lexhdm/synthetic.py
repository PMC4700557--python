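"""Synthetic trial-level data for the bilingual lexical-decision design.

No behavioral data were deposited by the study this pipeline emulates, so
this module generates the design from a hierarchical ground truth:
28 participants x 2 language blocks (German L1, English L2) x
{word, pseudo-word} x lengths 3-6 letters, 31 items per length-by-type
cell (248 trials per block), 2 s response deadline.

Each participant's 18 diffusion parameters (per condition: non-decision
intercept/slope t0/t1 and drift intercept/slope v0/v1; per language: one
boundary alpha) are drawn from condition-specific normal population laws
with shared between-participant SDs. Non-decision time and drift rate vary
linearly with stimulus length through link functions centered at 4.5
letters (the mean of 3-6), so intercepts equal across-length averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import simulate_trials

LANGUAGES = ("german", "english")
STIMULUS_TYPES = ("word", "pseudoword")
#: condition order used everywhere: index = 2 * language_index + type_index
CONDITIONS = tuple((g, w) for g in LANGUAGES for w in STIMULUS_TYPES)

LENGTH_CENTER = 4.5

TRIAL_COLUMNS = [
    "participant",
    "language",
    "type",
    "length",
    "item",
    "rt_s",
    "response",
    "correct",
]


def condition_index(language: str, stimulus_type: str) -> int:
    return 2 * LANGUAGES.index(language) + STIMULUS_TYPES.index(stimulus_type)


@dataclass(frozen=True)
class StudyDesign:
    """Counts and timing of the lexical-decision experiment."""

    n_participants: int = 28
    lengths: tuple[int, ...] = (3, 4, 5, 6)
    items_per_cell: int = 31
    deadline: float = 2.0

    @property
    def trials_per_block(self) -> int:
        return self.items_per_cell * len(self.lengths) * len(STIMULUS_TYPES)


@dataclass(frozen=True)
class GroupParameters:
    """Population-level means per condition and shared between-participant SDs.

    ``t0``/``t1``/``v0``/``v1`` map (language, stimulus_type) -> mean;
    ``alpha`` maps language -> mean boundary separation. The SDs are shared
    across conditions within each parameter type (the model's equal-variance
    assumption).
    """

    t0: dict[tuple[str, str], float]
    t1: dict[tuple[str, str], float]
    v0: dict[tuple[str, str], float]
    v1: dict[tuple[str, str], float]
    alpha: dict[str, float]
    sigma_t0: float = 0.03
    sigma_t1: float = 0.002
    sigma_v0: float = 0.30
    sigma_v1: float = 0.02
    sigma_alpha: float = 0.10

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            for d in (self.t0, self.t1, self.v0, self.v1):
                if cond not in d:
                    raise ValueError(f"missing condition {cond}")
        for g in LANGUAGES:
            if self.alpha[g] <= 0:
                raise ValueError("alpha means must be positive")
        for s in (self.sigma_t0, self.sigma_t1, self.sigma_v0, self.sigma_v1, self.sigma_alpha):
            if s <= 0:
                raise ValueError("between-participant SDs must be positive")

    def mean_vector(self) -> np.ndarray:
        """Group means in the flat 18-slot layout (t0 x4, t1 x4, v0 x4, v1 x4, alpha x2)."""
        mu = np.empty(18)
        for i, cond in enumerate(CONDITIONS):
            mu[i] = self.t0[cond]
            mu[4 + i] = self.t1[cond]
            mu[8 + i] = self.v0[cond]
            mu[12 + i] = self.v1[cond]
        mu[16] = self.alpha[LANGUAGES[0]]
        mu[17] = self.alpha[LANGUAGES[1]]
        return mu

    def sigma_vector(self) -> np.ndarray:
        """Shared SDs per parameter type (t0, t1, v0, v1, alpha)."""
        return np.array(
            [self.sigma_t0, self.sigma_t1, self.sigma_v0, self.sigma_v1, self.sigma_alpha]
        )


@dataclass(frozen=True)
class ParticipantParameters:
    """The 18 per-participant diffusion parameters in the flat layout."""

    participant_id: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (18,):
            raise ValueError("expected exactly 18 parameter values")
        if np.any(self.values[16:18] <= 0):
            raise ValueError("boundary separations must be positive")

    def t0(self, language: str, stimulus_type: str) -> float:
        return float(self.values[condition_index(language, stimulus_type)])

    def t1(self, language: str, stimulus_type: str) -> float:
        return float(self.values[4 + condition_index(language, stimulus_type)])

    def v0(self, language: str, stimulus_type: str) -> float:
        return float(self.values[8 + condition_index(language, stimulus_type)])

    def v1(self, language: str, stimulus_type: str) -> float:
        return float(self.values[12 + condition_index(language, stimulus_type)])

    def boundary(self, language: str) -> float:
        return float(self.values[16 + LANGUAGES.index(language)])


def default_group_parameters() -> GroupParameters:
    """Generating ground truth: group posterior means reported for this
    design, with between-participant SDs chosen to give realistic spread.
    """
    g, e = LANGUAGES
    w, pw = STIMULUS_TYPES
    return GroupParameters(
        t0={(g, pw): 0.41, (g, w): 0.37, (e, pw): 0.44, (e, w): 0.41},
        t1={(g, pw): 0.006, (g, w): 0.004, (e, pw): 0.013, (e, w): 0.004},
        v0={(g, pw): 2.80, (g, w): 3.05, (e, pw): 2.24, (e, w): 2.56},
        v1={(g, pw): -0.19, (g, w): 0.04, (e, pw): -0.08, (e, w): 0.17},
        alpha={g: 1.55, e: 1.51},
    )


def link_value(intercept: float, slope: float, length: float, center: float = LENGTH_CENTER):
    """Linear link: parameter value at a given stimulus length.

    Centering at 4.5 letters makes the intercept the across-length average
    for the 3-6 letter design.
    """
    return intercept + slope * (np.asarray(length) - center)


def make_design(config: StudyDesign, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Trial scaffold: one row per (participant, block, item) slot.

    Item order is randomized independently per participant block from the
    injected seed. Items are identified as `<lang>_<type>_<length>_<idx>`
    and shared across participants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for p in range(config.n_participants):
        for lang in LANGUAGES:
            block = []
            for stype in STIMULUS_TYPES:
                for length in config.lengths:
                    for i in range(config.items_per_cell):
                        block.append(
                            (p, lang, stype, length, f"{lang[:2]}_{stype[0]}{length}_{i:02d}")
                        )
            order = rng.permutation(len(block))
            rows.extend(block[j] for j in order)
    return pd.DataFrame(rows, columns=["participant", "language", "type", "length", "item"])


def draw_participant_params(
    group: GroupParameters, n: int, rng: np.random.Generator
) -> list[ParticipantParameters]:
    """Draw participant parameter sets from the population laws.

    Boundary values are redrawn until > 0.2 (keeps trials well-defined);
    a whole participant is redrawn if any implied non-decision time at a
    design length falls to 0.05 s or below.
    """
    mu = group.mean_vector()
    sig = group.sigma_vector()
    sd18 = np.repeat(sig, (4, 4, 4, 4, 2))
    out: list[ParticipantParameters] = []
    offsets = np.array([3.0, 4.0, 5.0, 6.0]) - LENGTH_CENTER
    for p in range(n):
        while True:
            vals = rng.normal(mu, sd18)
            for k in (16, 17):
                while vals[k] <= 0.2:
                    vals[k] = rng.normal(mu[k], sd18[k])
            taus = vals[0:4][:, None] + vals[4:8][:, None] * offsets[None, :]
            if np.all(taus > 0.05):
                break
        out.append(ParticipantParameters(participant_id=p, values=vals))
    return out


def participants_to_frame(participants: list[ParticipantParameters]) -> pd.DataFrame:
    rows = []
    for pp in participants:
        for lang, stype in CONDITIONS:
            rows.append(
                {
                    "participant": pp.participant_id,
                    "language": lang,
                    "type": stype,
                    "t0": pp.t0(lang, stype),
                    "t1": pp.t1(lang, stype),
                    "v0": pp.v0(lang, stype),
                    "v1": pp.v1(lang, stype),
                    "alpha": pp.boundary(lang),
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(
    group: GroupParameters,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    dt: float = 0.0005,
) -> tuple[pd.DataFrame, list[ParticipantParameters], dict]:
    """Simulate the full experiment from the hierarchical ground truth.

    Per trial the condition link functions give (v, tau) at the trial's
    length, the participant/language boundary gives alpha; the outcome is
    an Euler-simulated first passage under the deadline. The upper boundary
    codes the correct response (accuracy coding). Trials that reach the
    deadline without a response are omissions: they are dropped from the
    returned table and their fraction is reported in the info dict.

    Returns (trials, ground-truth participant parameters, info).
    """
    ss = np.random.SeedSequence(seed)
    s_draw, s_design, s_trials = ss.spawn(3)
    participants = draw_participant_params(
        group, design.n_participants, np.random.default_rng(s_draw)
    )
    scaffold = make_design(design, np.random.default_rng(s_design))

    lang_idx = scaffold["language"].map(lambda g: LANGUAGES.index(g)).to_numpy()
    type_idx = scaffold["type"].map(lambda w: STIMULUS_TYPES.index(w)).to_numpy()
    cond = 2 * lang_idx + type_idx
    part = scaffold["participant"].to_numpy()
    xlen = scaffold["length"].to_numpy(dtype=float) - LENGTH_CENTER

    theta = np.stack([pp.values for pp in participants])
    tau = theta[part, cond] + theta[part, 4 + cond] * xlen
    v = theta[part, 8 + cond] + theta[part, 12 + cond] * xlen
    alpha = theta[part, 16 + lang_idx]

    sim_seed = int(s_trials.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
    rt, upper, cens = simulate_trials(alpha, tau, v, design.deadline, dt, sim_seed)

    correct = upper > 0.5
    is_word = scaffold["type"].to_numpy() == "word"
    response = np.where(correct == is_word, "word", "nonword")

    trials = scaffold.copy()
    trials["rt_s"] = rt
    trials["response"] = response
    trials["correct"] = correct

    keep = cens < 0.5
    info = {
        "n_scheduled": len(trials),
        "n_censored": int((~keep).sum()),
        "censored_fraction": float((~keep).mean()),
    }
    trials = trials.loc[keep].reset_index(drop=True)
    return trials, participants, info


def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_participants(participants: list[ParticipantParameters], path) -> None:
    participants_to_frame(participants).to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
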