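"""Hierarchical diffusion model: specification, MCMC estimation, diagnostics.

Per participant the model has 18 parameters: non-decision intercept/slope
(t0, t1) and drift intercept/slope (v0, v1) for each of the four
language x stimulus-type conditions, plus one boundary separation per
language block. Trial-level (tau, v) come from linear length links
centered at 4.5 letters; the upper boundary codes the correct response
(accuracy coding), so drift is positive toward correct for words and
pseudo-words alike. Bias is fixed at 0.5, within-trial SD at 1, and
inter-trial variabilities at 0.

Participant parameters are draws from condition-specific normal population
laws whose SDs are shared across conditions within a parameter type.
Group means and SDs carry uniform priors. Estimation is by
Metropolis-within-Gibbs (see :mod:`lexhdm._sampler`); starting values come
from the EZ-diffusion closed forms. The observed 2 s deadline is not
modeled in the likelihood: fitted RTs are treated as uncensored, matching
how the data would be fit in practice (omissions never enter the table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from ._kernels import wiener_logpdf_upper_unbiased
from ._sampler import SLOT_TYPE, run_chain
from .synthetic import (
    CONDITIONS,
    LANGUAGES,
    LENGTH_CENTER,
    STIMULUS_TYPES,
    GroupParameters,
    StudyDesign,
)
from .wiener import ez_point_estimates

PARAM_TYPES = ("t0", "t1", "v0", "v1", "alpha")

QUANTILE_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class HDMSpec:
    """Prior boxes (uniform) for group means, per parameter type, and the
    shared box for group SDs. Ranges are wide relative to plausible values."""

    mu_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "t0": (0.05, 1.0),
            "t1": (-0.2, 0.2),
            "v0": (-7.0, 7.0),
            "v1": (-2.0, 2.0),
            "alpha": (0.3, 4.0),
        }
    )
    sigma_bounds: tuple[float, float] = (0.001, 2.0)
    length_center: float = LENGTH_CENTER

    def mu_lo_hi(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(18)
        hi = np.empty(18)
        for k in range(18):
            b = self.mu_bounds[PARAM_TYPES[SLOT_TYPE[k]]]
            lo[k], hi[k] = b
        return lo, hi


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings; n_samples counts post-burn-in draws per chain."""

    n_chains: int = 2
    n_samples: int = 10_000
    n_burnin: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for R-hat")
        if self.n_burnin < 0 or self.n_samples < 2:
            raise ValueError("invalid chain lengths")


@dataclass
class HDMState:
    """One point in parameter space: participant values, group means, SDs."""

    theta: np.ndarray  # (P, 18)
    mu: np.ndarray  # (18,)
    sigma: np.ndarray  # (5,)


@dataclass
class FittedData:
    """Trial table flattened to sampler arrays, sorted by (participant, condition)."""

    rt: np.ndarray
    acc: np.ndarray
    xlen: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    participant_ids: list


def prepare_data(trials: pd.DataFrame, spec: HDMSpec = HDMSpec()) -> FittedData:
    pids = sorted(trials["participant"].unique().tolist())
    pmap = {pid: i for i, pid in enumerate(pids)}
    part = trials["participant"].map(pmap).to_numpy()
    cond = (
        2 * trials["language"].map(lambda g: LANGUAGES.index(g)).to_numpy()
        + trials["type"].map(lambda w: STIMULUS_TYPES.index(w)).to_numpy()
    )
    order = np.lexsort((cond, part))
    rt = trials["rt_s"].to_numpy(dtype=float)[order]
    acc = trials["correct"].to_numpy(dtype=float)[order]
    xlen = trials["length"].to_numpy(dtype=float)[order] - spec.length_center
    part = part[order]
    cond = cond[order]
    P = len(pids)
    starts = np.zeros((P, 4), dtype=np.int64)
    ends = np.zeros((P, 4), dtype=np.int64)
    key = part * 4 + cond
    bounds = np.searchsorted(key, np.arange(4 * P + 1))
    for p in range(P):
        for c in range(4):
            starts[p, c] = bounds[p * 4 + c]
            ends[p, c] = bounds[p * 4 + c + 1]
    if np.any(ends - starts == 0):
        raise ValueError("every participant x condition cell must be nonempty")
    return FittedData(rt=rt, acc=acc, xlen=xlen, starts=starts, ends=ends, participant_ids=pids)


# ---------------------------------------------------------------------------
# posterior density (reference implementation; the sampler kernel computes
# the same quantity incrementally)
# ---------------------------------------------------------------------------


def log_posterior(state: HDMState, data: FittedData, spec: HDMSpec = HDMSpec()) -> float:
    """Joint log posterior; -inf outside the uniform prior support."""
    mu_lo, mu_hi = spec.mu_lo_hi()
    if np.any(state.mu <= mu_lo) or np.any(state.mu >= mu_hi):
        return -np.inf
    slo, shi = spec.sigma_bounds
    if np.any(state.sigma <= slo) or np.any(state.sigma >= shi):
        return -np.inf
    if np.any(state.theta[:, 16:18] <= 0):
        return -np.inf

    total = 0.0
    P = state.theta.shape[0]
    for p in range(P):
        for c in range(4):
            t0, t1 = state.theta[p, c], state.theta[p, 4 + c]
            v0, v1 = state.theta[p, 8 + c], state.theta[p, 12 + c]
            a = state.theta[p, 16 + c // 2]
            for i in range(data.starts[p, c], data.ends[p, c]):
                tau = t0 + t1 * data.xlen[i]
                v = v0 + v1 * data.xlen[i]
                drift = v if data.acc[i] > 0.5 else -v
                total += wiener_logpdf_upper_unbiased(data.rt[i], a, tau, drift)
    # hierarchy
    sig18 = state.sigma[SLOT_TYPE]
    z = (state.theta - state.mu[None, :]) / sig18[None, :]
    total += float(
        -0.5 * np.sum(z * z) - P * np.sum(np.log(sig18)) - P * 18 * 0.5 * np.log(2 * np.pi)
    )
    return total


# ---------------------------------------------------------------------------
# EZ initialization
# ---------------------------------------------------------------------------


def init_from_ez(
    trials: pd.DataFrame,
    n_chains: int = 2,
    rng: np.random.Generator | None = None,
    spec: HDMSpec = HDMSpec(),
    jitter: float = 0.05,
) -> list[HDMState]:
    """Starting states from the EZ-diffusion closed forms.

    Per participant x condition, moments pooled across lengths give
    (v0, t0) and a boundary; slopes start at 0; the per-language boundary
    is the mean of that block's two EZ boundaries. Group means/SDs are the
    across-participant moments (SDs floored at 0.01). Chains beyond the
    first receive 5% multiplicative jitter.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    pids = sorted(trials["participant"].unique().tolist())
    P = len(pids)
    theta = np.zeros((P, 18))
    for pi, pid in enumerate(pids):
        sub = trials[trials["participant"] == pid]
        a_by_lang: dict[str, list[float]] = {g: [] for g in LANGUAGES}
        for ci, (lang, stype) in enumerate(CONDITIONS):
            cell = sub[(sub["language"] == lang) & (sub["type"] == stype)]
            n = len(cell)
            acc = float(cell["correct"].mean())
            rt_c = cell.loc[cell["correct"], "rt_s"]
            if len(rt_c) < 2 or rt_c.var(ddof=1) <= 0:
                # degenerate cell: fall back to weakly informative values
                est_v, est_a, est_t = 1.0, 1.5, 0.3
            else:
                ez = ez_point_estimates(acc, float(rt_c.mean()), float(rt_c.var(ddof=1)), n_trials=n)
                est_v = ez.params.drift_rate
                est_a = ez.params.boundary_separation
                est_t = ez.params.nondecision_time
            theta[pi, ci] = max(est_t, 0.08)
            theta[pi, 8 + ci] = est_v
            a_by_lang[lang].append(est_a)
        for li, lang in enumerate(LANGUAGES):
            theta[pi, 16 + li] = max(float(np.mean(a_by_lang[lang])), 0.3)

    mu = theta.mean(axis=0)
    sd = theta.std(axis=0, ddof=1) if P > 1 else np.zeros(18)
    sigma = np.empty(5)
    for t in range(5):
        sigma[t] = max(float(np.mean(sd[SLOT_TYPE == t])), 0.01)

    mu_lo, mu_hi = spec.mu_lo_hi()
    slo, shi = spec.sigma_bounds

    states = []
    for chain in range(n_chains):
        th = theta.copy()
        m = mu.copy()
        s = sigma.copy()
        if chain > 0:
            th = th * (1.0 + jitter * rng.standard_normal(th.shape))
            m = m * (1.0 + jitter * rng.standard_normal(m.shape))
            s = s * (1.0 + jitter * rng.standard_normal(s.shape))
        th[:, 16:18] = np.maximum(th[:, 16:18], 0.25)
        th[:, 0:4] = np.maximum(th[:, 0:4], 0.08)
        m = np.clip(m, mu_lo + 1e-6, mu_hi - 1e-6)
        s = np.clip(s, max(slo * 2, 0.005), min(shi / 2, 1.0))
        states.append(HDMState(theta=th, mu=m, sigma=s))
    return states


# ---------------------------------------------------------------------------
# sampling and diagnostics
# ---------------------------------------------------------------------------


def _param_names(pids: list) -> list[str]:
    names = []
    for pid in pids:
        for k in range(18):
            t = PARAM_TYPES[SLOT_TYPE[k]]
            if k < 16:
                lang, stype = CONDITIONS[k % 4]
                names.append(f"{t}[{lang},{stype}][{pid}]")
            else:
                names.append(f"alpha[{LANGUAGES[k - 16]}][{pid}]")
    for k in range(16):
        lang, stype = CONDITIONS[k % 4]
        names.append(f"mu_{PARAM_TYPES[SLOT_TYPE[k]]}[{lang},{stype}]")
    for lang in LANGUAGES:
        names.append(f"mu_alpha[{lang}]")
    for t in PARAM_TYPES:
        names.append(f"sigma_{t}")
    return names


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is (m, n): m >= 2 chains of equal length n. Zero
    within-chain variance yields +inf with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (m>=2, n) array of chains")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        if B_over_n == 0:
            return 1.0  # identical constant chains
        warnings.warn("zero within-chain variance; R-hat undefined (+inf)")
        return np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorSummary:
    """Chains plus per-parameter posterior summaries and diagnostics."""

    param_names: list[str]
    chains: np.ndarray  # (n_chains, n_samples, n_params)
    participant_ids: list
    accept_rates: np.ndarray
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        flat = self.chains.reshape(-1, self.chains.shape[-1])
        self.mean = flat.mean(axis=0)
        self.q025 = np.quantile(flat, 0.025, axis=0)
        self.q975 = np.quantile(flat, 0.975, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.rhat = np.array(
                [gelman_rubin(self.chains[:, :, j]) for j in range(self.chains.shape[-1])]
            )
        self._index = {n: j for j, n in enumerate(self.param_names)}

    def __getitem__(self, name: str) -> int:
        return self._index[name]

    def posterior_mean(self, name: str) -> float:
        return float(self.mean[self._index[name]])

    def group_mean(self, ptype: str, language: str, stimulus_type: str | None = None) -> float:
        """Posterior mean of a group-level mean, e.g. ('v1','german','pseudoword')."""
        if ptype == "alpha":
            return self.posterior_mean(f"mu_alpha[{language}]")
        return self.posterior_mean(f"mu_{ptype}[{language},{stimulus_type}]")

    def max_rhat(self) -> float:
        return float(np.max(self.rhat))

    def group_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            if name.startswith(("mu_", "sigma_")):
                j = self._index[name]
                rows.append(
                    {
                        "parameter": name,
                        "mean": self.mean[j],
                        "q2.5": self.q025[j],
                        "q97.5": self.q975[j],
                        "rhat": self.rhat[j],
                    }
                )
        return pd.DataFrame(rows)

    def participant_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.participant_ids:
            for lang, stype in CONDITIONS:
                row = {"participant": pid, "language": lang, "type": stype}
                for t in ("t0", "t1", "v0", "v1"):
                    row[t] = self.posterior_mean(f"{t}[{lang},{stype}][{pid}]")
                row["alpha"] = self.posterior_mean(f"alpha[{lang}][{pid}]")
                rows.append(row)
        return pd.DataFrame(rows)

    def group_parameters(self) -> GroupParameters:
        """Posterior-mean GroupParameters (means and shared SDs), e.g. for
        posterior-predictive simulation."""
        return GroupParameters(
            t0={c: self.group_mean("t0", *c) for c in CONDITIONS},
            t1={c: self.group_mean("t1", *c) for c in CONDITIONS},
            v0={c: self.group_mean("v0", *c) for c in CONDITIONS},
            v1={c: self.group_mean("v1", *c) for c in CONDITIONS},
            alpha={g: self.group_mean("alpha", g) for g in LANGUAGES},
            sigma_t0=self.posterior_mean("sigma_t0"),
            sigma_t1=self.posterior_mean("sigma_t1"),
            sigma_v0=self.posterior_mean("sigma_v0"),
            sigma_v1=self.posterior_mean("sigma_v1"),
            sigma_alpha=self.posterior_mean("sigma_alpha"),
        )

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.group_frame().to_csv(out / "posterior_group.tsv", sep="\t", index=False, float_format="%.8f")
        self.participant_frame().to_csv(
            out / "posterior_participants.tsv", sep="\t", index=False, float_format="%.8f"
        )
        np.savez_compressed(
            out / "chains.npz",
            chains=self.chains.astype(np.float32),
            param_names=np.array(self.param_names),
            participant_ids=np.array(self.participant_ids),
            accept_rates=self.accept_rates,
        )


def run_mcmc(
    trials: pd.DataFrame,
    config: MCMCConfig,
    spec: HDMSpec = HDMSpec(),
) -> PosteriorSummary:
    """Fit the hierarchical model by Metropolis-within-Gibbs MCMC.

    Deterministic given (data, config.seed). Chains are initialized from
    EZ-diffusion starting values (jittered for chains beyond the first).
    """
    data = prepare_data(trials, spec)
    ss = np.random.SeedSequence(config.seed)
    s_init, *s_chains = ss.spawn(1 + config.n_chains)
    states = init_from_ez(trials, config.n_chains, np.random.default_rng(s_init), spec)
    mu_lo, mu_hi = spec.mu_lo_hi()
    slo, shi = spec.sigma_bounds

    chains = []
    rates = []
    for ci, state in enumerate(states):
        seed = int(s_chains[ci].generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        samples, rate = run_chain(
            data.rt, data.acc, data.xlen, data.starts, data.ends,
            state.theta, state.mu, state.sigma,
            mu_lo, mu_hi, slo, shi,
            config.n_burnin, config.n_samples, seed,
        )
        chains.append(samples)
        rates.append(rate)

    summary = PosteriorSummary(
        param_names=_param_names(data.participant_ids),
        chains=np.stack(chains),
        participant_ids=data.participant_ids,
        accept_rates=np.mean(rates, axis=0),
    )
    stuck = [
        summary.param_names[j]
        for j in range(len(summary.param_names))
        if summary.accept_rates[j] == 0.0
    ]
    for name in stuck:
        summary.warnings_.append(f"parameter {name} rejected every proposal")
        warnings.warn(f"parameter {name} rejected every proposal")
    return summary


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------


def empirical_quantiles(
    trials: pd.DataFrame, levels: tuple[float, ...] = QUANTILE_LEVELS
) -> pd.DataFrame:
    """Correct-response RT quantiles pooled across participants, per
    condition x length cell."""
    rows = []
    correct = trials[trials["correct"]]
    for (lang, stype, length), cell in correct.groupby(["language", "type", "length"]):
        if len(cell) == 0:
            continue
        qs = cell["rt_s"].quantile(list(levels))
        for q, v in zip(levels, qs):
            rows.append(
                {"language": lang, "type": stype, "length": length, "q": q, "rt_s": float(v)}
            )
    return pd.DataFrame(rows)


def posterior_predictive_quantiles(
    summary: PosteriorSummary,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    levels: tuple[float, ...] = QUANTILE_LEVELS,
) -> pd.DataFrame:
    """Simulate a cohort from the group-level posterior means and return
    its pooled correct-RT quantiles per condition x length."""
    group = summary.group_parameters()
    sim, _, _ = synthetic.simulate_dataset(group, design, seed=seed)
    out = empirical_quantiles(sim, levels)
    n_cells = 4 * len(design.lengths)
    if len(out) < n_cells * len(levels):
        warnings.warn("empty cells in the posterior-predictive simulation")
    return out


def quantile_agreement(empirical: pd.DataFrame, predicted: pd.DataFrame) -> float:
    """Pearson correlation between matched empirical and predicted
    quantiles across all (condition, length, q) cells."""
    merged = empirical.merge(
        predicted, on=["language", "type", "length", "q"], suffixes=("_emp", "_pred")
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 matched quantile pairs")
    r = np.corrcoef(merged["rt_s_emp"], merged["rt_s_pred"])[0, 1]
    return float(r)
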