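"""Numba kernels: Wiener first-passage-time density and path simulation.

Everything here is scalar/loop code compiled with numba so that the MCMC
sampler and the trial simulator stay fast on one CPU. Python-facing wrappers
with validation live in :mod:`lexhdm.wiener`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Absolute truncation error targeted by the series evaluation.
_SERIES_EPS = 1e-10

# Log-likelihood floor for impossible/underflowing trials.
LOGLIK_FLOOR = -700.0


@njit(cache=True)
def _fpt_f_standardized(u, w, eps):
    """Density f(u|w) of the standardized (a=1, v=0) first passage at the
    lower boundary, normalized time u = t/a^2, start point w in (0,1).

    Chooses the small-time or large-time expansion by the number of terms
    each needs for absolute error <= eps.
    """
    if u <= 0.0:
        return 0.0

    # terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        sq = math.sqrt(u) + 1.0
        if sq > ks:
            ks = sq
    else:
        ks = 2.0

    # terms needed by the large-time expansion
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        inv = 1.0 / (math.pi * math.sqrt(u))
        if inv > kl:
            kl = inv
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    p = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            z = w + 2.0 * k
            p += z * math.exp(-z * z / (2.0 * u))
        p /= math.sqrt(2.0 * math.pi * u * u * u)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    return p


@njit(cache=True)
def wiener_pdf_lower(t, a, w, tau, v, eps):
    """Joint density of hitting the LOWER boundary at time t.

    Drift v is positive toward the upper boundary; start point at w*a.
    Returns 0 for t <= tau.
    """
    tt = t - tau
    if tt <= 0.0:
        return 0.0
    u = tt / (a * a)
    f = _fpt_f_standardized(u, w, eps)
    if f <= 0.0:
        return 0.0
    return f / (a * a) * math.exp(-v * a * w - v * v * tt / 2.0)


@njit(cache=True)
def wiener_pdf_upper(t, a, w, tau, v, eps):
    """Joint density of hitting the UPPER boundary at time t (reflection)."""
    return wiener_pdf_lower(t, a, 1.0 - w, tau, -v, eps)


@njit(cache=True)
def wiener_logpdf_upper_unbiased(t, a, tau, v):
    """Floored log density at the upper boundary for the unbiased (w=0.5)
    process used throughout the hierarchical model.

    Floored at LOGLIK_FLOOR so Metropolis proposals that imply rt <= tau
    remain evaluable.
    """
    tt = t - tau
    if tt <= 0.0:
        return LOGLIK_FLOOR
    u = tt / (a * a)
    f = _fpt_f_standardized(u, 0.5, _SERIES_EPS)
    if f <= 0.0:
        return LOGLIK_FLOOR
    ld = math.log(f) - 2.0 * math.log(a) + 0.5 * v * a - v * v * tt / 2.0
    if ld < LOGLIK_FLOOR or math.isnan(ld):
        return LOGLIK_FLOOR
    return ld


@njit(cache=True)
def simulate_fpt_one(a, w, tau, v, s, deadline, dt):
    """Euler–Maruyama first passage. Returns (rt, upper, censored) with
    upper in {0., 1.}; rt = decision time + tau, or the deadline if censored.

    Discrete time steps miss within-step boundary crossings, which biases
    passage times upward by O(sqrt(dt)); the standard continuity correction
    (each absorbing boundary moved inward by 0.5826 * s * sqrt(dt)) removes
    the leading-order bias.

    Uses numba's global RNG: seed with np.random.seed before calling.
    """
    x = w * a
    sq = s * math.sqrt(dt)
    shift = 0.5826 * sq
    if shift > 0.25 * a:
        shift = 0.25 * a
    hi = a - shift
    lo = shift
    t_budget = deadline - tau
    n_steps = int(t_budget / dt)
    t = 0.0
    for _ in range(n_steps):
        x += v * dt + sq * np.random.normal()
        t += dt
        if x >= hi:
            return t + tau, 1.0, 0.0
        if x <= lo:
            return t + tau, 0.0, 0.0
    return deadline, 0.0, 1.0


@njit(cache=True)
def simulate_fpt_batch(a, w, tau, v, s, deadline, dt, n, seed):
    """n independent first passages at one parameter set; seeded."""
    np.random.seed(seed)
    rt = np.empty(n)
    upper = np.empty(n)
    cens = np.empty(n)
    for i in range(n):
        rt[i], upper[i], cens[i] = simulate_fpt_one(a, w, tau, v, s, deadline, dt)
    return rt, upper, cens


@njit(cache=True)
def simulate_trials(a_arr, tau_arr, v_arr, deadline, dt, seed):
    """One Euler first passage per trial (w=0.5, s=1); seeded, deterministic."""
    np.random.seed(seed)
    n = a_arr.shape[0]
    rt = np.empty(n)
    upper = np.empty(n)
    cens = np.empty(n)
    for i in range(n):
        rt[i], upper[i], cens[i] = simulate_fpt_one(
            a_arr[i], 0.5, tau_arr[i], v_arr[i], 1.0, deadline, dt
        )
    return rt, upper, cens
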