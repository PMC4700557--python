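"""Two-boundary Wiener diffusion measurement model.

The decision process is a Brownian motion with drift ``v`` (evidence
units/s), diffusion coefficient ``s`` (fixed to 1 here; it only sets the
scale of the other parameters), started at ``bias * boundary_separation``
between absorbing boundaries at 0 and ``boundary_separation``. A response
is emitted when a boundary is hit; observed RT adds the non-decision time
``tau`` (encoding + motor). The joint density over (RT, boundary) is the
Wiener first-passage-time distribution, evaluated by a dual-regime
(small-time / large-time) series with adaptive truncation.

The study-specific restriction is an unbiased process (bias = 0.5) with
unit diffusion; constructing :class:`DiffusionParams` outside that
restriction requires an explicit override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._kernels import (
    LOGLIK_FLOOR,
    _SERIES_EPS,
    simulate_fpt_one,
    wiener_pdf_lower,
    wiener_pdf_upper,
)

Boundary = Literal["upper", "lower"]


class ParameterDomainError(ValueError):
    """A diffusion parameter is outside its mathematical domain."""


@dataclass(frozen=True)
class DiffusionParams:
    """One trial-generating diffusion parameter set.

    Parameters
    ----------
    boundary_separation : float
        Evidence needed for a response (alpha > 0); decision caution.
    bias : float
        Starting point as a fraction of the boundary separation (0..1);
        0.5 is unbiased and is enforced unless ``allow_nonstandard``.
    nondecision_time : float
        Seconds of RT outside evidence accumulation (tau >= 0).
    drift_rate : float
        Mean evidence accumulation rate, positive toward the upper boundary.
    within_trial_sd : float
        Diffusion coefficient; a scaling constant, fixed to 1 here.
    """

    boundary_separation: float
    bias: float = 0.5
    nondecision_time: float = 0.0
    drift_rate: float = 0.0
    within_trial_sd: float = 1.0
    allow_nonstandard: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.boundary_separation > 0):
            raise ParameterDomainError("boundary_separation must be > 0")
        if not (0.0 < self.bias < 1.0):
            raise ParameterDomainError("bias must be in (0, 1)")
        if not (self.nondecision_time >= 0):
            raise ParameterDomainError("nondecision_time must be >= 0")
        if not (self.within_trial_sd > 0):
            raise ParameterDomainError("within_trial_sd must be > 0")
        if not math.isfinite(self.drift_rate):
            raise ParameterDomainError("drift_rate must be finite")
        if not self.allow_nonstandard:
            if self.bias != 0.5:
                raise ParameterDomainError(
                    "bias is fixed at 0.5 in this pipeline; "
                    "pass allow_nonstandard=True to override"
                )
            if self.within_trial_sd != 1.0:
                raise ParameterDomainError(
                    "within_trial_sd is fixed at 1 in this pipeline; "
                    "pass allow_nonstandard=True to override"
                )


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated first passage: RT (s), boundary hit, censoring flag."""

    rt: float
    response: Boundary
    censored: bool = False


def _scaled(params: DiffusionParams) -> tuple[float, float, float, float]:
    """Rescale to unit diffusion coefficient (s=1) for the kernels."""
    s = params.within_trial_sd
    return (
        params.boundary_separation / s,
        params.bias,
        params.nondecision_time,
        params.drift_rate / s,
    )


def wiener_fpt_density(t: float, params: DiffusionParams, boundary: Boundary) -> float:
    """Joint first-passage density of hitting ``boundary`` at time ``t``.

    Zero for ``t <= nondecision_time``; nonnegative and continuous in t
    above it. Series truncation error <= 1e-10.
    """
    if not math.isfinite(t):
        raise ParameterDomainError("t must be finite")
    a, w, tau, v = _scaled(params)
    if boundary == "upper":
        return wiener_pdf_upper(t, a, w, tau, v, _SERIES_EPS)
    if boundary == "lower":
        return wiener_pdf_lower(t, a, w, tau, v, _SERIES_EPS)
    raise ValueError(f"unknown boundary: {boundary!r}")


def wiener_log_likelihood(rt: float, boundary: Boundary, params: DiffusionParams) -> float:
    """Log of the first-passage density, floored at -700.

    The floor (rather than -inf or an exception) keeps MCMC proposals that
    imply rt <= tau evaluable, so a sampler can recover from bad states.
    """
    dens = wiener_fpt_density(rt, params, boundary)
    if dens <= 0.0 or not math.isfinite(dens):
        return LOGLIK_FLOOR
    ll = math.log(dens)
    return ll if ll > LOGLIK_FLOOR else LOGLIK_FLOOR


def sample_fpt(
    params: DiffusionParams,
    deadline: float,
    rng: np.random.Generator,
    dt: float = 0.0005,
) -> TrialOutcome:
    """Euler–Maruyama first passage under a response deadline.

    Censored (no boundary reached within ``deadline - tau`` of decision
    time) outcomes carry ``censored=True`` and rt equal to the deadline.
    """
    if deadline <= 0:
        raise ParameterDomainError("deadline must be positive")
    if deadline <= params.nondecision_time:
        raise ParameterDomainError("deadline must exceed the non-decision time")
    # route numba's global RNG through the injected generator for determinism
    seed = int(rng.integers(0, 2**31 - 1))
    np.random.seed(seed)
    rt, upper, cens = simulate_fpt_one(
        params.boundary_separation / params.within_trial_sd,
        params.bias,
        params.nondecision_time,
        params.drift_rate / params.within_trial_sd,
        1.0,
        deadline,
        dt,
    )
    return TrialOutcome(
        rt=float(rt),
        response="upper" if upper > 0.5 else "lower",
        censored=bool(cens > 0.5),
    )


def upper_boundary_probability(params: DiffusionParams) -> float:
    """Probability of absorption at the upper boundary.

    For the unbiased unit-diffusion case this is the logistic
    1 / (1 + exp(-alpha * v)); the general form follows the standard
    two-barrier absorption formula.
    """
    a, w, _, v = _scaled(params)
    if v == 0.0:
        return w
    z = w * a
    # P(hit a before 0) = (1 - exp(-2 v z)) / (1 - exp(-2 v a))
    num = -math.expm1(-2.0 * v * z)
    den = -math.expm1(-2.0 * v * a)
    return num / den


def mean_decision_time(params: DiffusionParams) -> float:
    """Expected decision time (s) for the unbiased process.

    (alpha / 2v) * tanh(v * alpha / 2) for v != 0, alpha^2 / 4 at v = 0
    (unit diffusion); continuous at v = 0.
    """
    if params.bias != 0.5:
        raise ParameterDomainError("mean_decision_time requires bias = 0.5")
    a, _, _, v = _scaled(params)
    if v == 0.0:
        return a * a / 4.0
    return (a / (2.0 * v)) * math.tanh(v * a / 2.0)


@dataclass(frozen=True)
class EZEstimate:
    """EZ-diffusion point estimates plus bookkeeping flags."""

    params: DiffusionParams
    accuracy_corrected: bool = False
    drift_sign_flipped: bool = False


def ez_forward_moments(params: DiffusionParams) -> tuple[float, float, float]:
    """Closed-form (accuracy, mean correct RT, variance of correct RT)
    implied by an unbiased diffusion — the EZ forward equations.

    'Correct' means absorption at the upper boundary (drift toward it).
    """
    if params.bias != 0.5:
        raise ParameterDomainError("EZ forward equations require bias = 0.5")
    a, _, tau, v = _scaled(params)
    if v == 0.0:
        return 0.5, tau + a * a / 4.0, a**4 * (1.0 / 24.0)
    y = math.exp(-a * v)
    pc = 1.0 / (1.0 + y)
    mdt = (a / (2.0 * v)) * ((1.0 - y) / (1.0 + y))
    vdt = (a / (2.0 * v**3)) * (
        (1.0 - 2.0 * a * v * y - y * y) / ((y + 1.0) ** 2)
    )
    return pc, tau + mdt, vdt


def ez_point_estimates(
    accuracy: float,
    mean_rt_correct: float,
    var_rt_correct: float,
    n_trials: int | None = None,
) -> EZEstimate:
    """Invert the EZ-diffusion closed forms (unit diffusion).

    Accuracy exactly 1.0 (or 0.5) is edge-corrected to 1 - 1/(2n)
    (0.5 + 1/(2n)) given the cell size ``n_trials``; accuracy below 0.5
    after correction is mirrored and the drift sign flipped, with the
    flag set in the result.
    """
    if var_rt_correct <= 0:
        raise ParameterDomainError("var_rt_correct must be positive")
    if not (0 < accuracy <= 1):
        raise ParameterDomainError("accuracy must be in (0, 1]")

    corrected = False
    if accuracy == 1.0 or accuracy == 0.5:
        if n_trials is None or n_trials < 1:
            raise ParameterDomainError(
                "edge accuracy (0.5 or 1.0) requires the cell size n_trials"
            )
        accuracy = 1.0 - 1.0 / (2 * n_trials) if accuracy == 1.0 else 0.5 + 1.0 / (2 * n_trials)
        corrected = True

    flipped = False
    if accuracy < 0.5:
        accuracy = 1.0 - accuracy
        flipped = True

    pc = accuracy
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / var_rt_correct
    v = math.copysign(1.0, pc - 0.5) * x**0.25
    a = L / v
    y = math.exp(-a * v)
    mdt = (a / (2.0 * v)) * ((1.0 - y) / (1.0 + y))
    tau = mean_rt_correct - mdt
    if flipped:
        v = -v
    params = DiffusionParams(
        boundary_separation=a,
        bias=0.5,
        nondecision_time=max(tau, 0.0),
        drift_rate=v,
        within_trial_sd=1.0,
    )
    return EZEstimate(params=params, accuracy_corrected=corrected, drift_sign_flipped=flipped)
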