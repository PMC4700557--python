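"""Numba kernel for the hierarchical-model MCMC sampler.

One chain = repeated sweeps of:

* adaptive scalar random-walk Metropolis on every participant-level
  parameter (cell log-likelihoods cached and updated incrementally),
* exact Gibbs draws of the group means (truncated-normal conjugate update
  given the participant values and the shared SDs, uniform prior box),
* adaptive scalar random-walk Metropolis on the five shared group SDs,
* an interweaved non-centered move per SD (ancillarity-sufficiency
  interweaving): the SD is proposed while every participant's
  standardized deviation from the group mean is held fixed, so all
  participant values rescale jointly. This breaks the funnel-shaped
  coupling between a hierarchy SD and the spread of its participant
  values that traps purely centered samplers when the SD is small
  relative to per-participant estimation noise,
* an interweaved translation move per group mean: the mean and all its
  participant values shift together, sampling the pooled, data-informed
  direction directly (hierarchy terms cancel; only the trial likelihood
  and the prior box decide acceptance). Without it the group mean can
  only move at the speed of 28 weakly-identified participant values.

Proposal scales adapt toward 0.44 acceptance during burn-in only and are
frozen afterward, preserving detailed balance for the retained samples.

Parameter layout (per participant, 18 slots): t0 x 4 conditions,
t1 x 4, v0 x 4, v1 x 4, alpha x 2 languages; condition index =
2 * language + stimulus_type. Flat state vector = participants
(p-major, slot-minor), then 18 group means, then 5 group SDs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._kernels import wiener_logpdf_upper_unbiased

#: slot -> parameter-type index (t0, t1, v0, v1, alpha)
SLOT_TYPE = np.array([0] * 4 + [1] * 4 + [2] * 4 + [3] * 4 + [4] * 2, dtype=np.int64)

#: hard floor on proposed boundary separations
MIN_ALPHA = 0.05

TARGET_ACCEPT = 0.44


@njit(cache=True)
def _cell_loglik(rt, acc, xlen, i0, i1, t0, t1, v0, v1, a):
    """Summed trial log-likelihood for one participant x condition cell."""
    if a <= MIN_ALPHA:
        return -1e250
    total = 0.0
    for i in range(i0, i1):
        tau = t0 + t1 * xlen[i]
        v = v0 + v1 * xlen[i]
        drift = v if acc[i] > 0.5 else -v
        total += wiener_logpdf_upper_unbiased(rt[i], a, tau, drift)
    return total


@njit(cache=True)
def _cell_ll_from_theta(rt, acc, xlen, starts, ends, theta, p, c):
    a = theta[p, 16 + (c // 2)]
    return _cell_loglik(
        rt, acc, xlen, starts[p, c], ends[p, c],
        theta[p, c], theta[p, 4 + c], theta[p, 8 + c], theta[p, 12 + c], a,
    )


@njit(cache=True)
def _trunc_normal(mean, sd, lo, hi):
    """Rejection-sampled truncated normal; clamps after 200 failures."""
    for _ in range(200):
        x = mean + sd * np.random.normal()
        if lo < x < hi:
            return x
    if mean <= lo:
        return lo + 1e-8
    if mean >= hi:
        return hi - 1e-8
    return mean


@njit(cache=True)
def run_chain(
    rt, acc, xlen, starts, ends,
    theta0, mu0, sigma0,
    mu_lo, mu_hi, sigma_lo, sigma_hi,
    n_burnin, n_keep, seed,
):
    """Run one MCMC chain; returns (samples, acceptance rates).

    samples: (n_keep, P*18 + 18 + 5); rates aligned with the same layout
    (Gibbs-updated group means report rate 1).
    """
    np.random.seed(seed)
    P = theta0.shape[0]
    theta = theta0.copy()
    mu = mu0.copy()
    sigma = sigma0.copy()

    n_par = P * 18 + 18 + 5
    out = np.empty((n_keep, n_par))

    # cached per-cell log-likelihoods
    cll = np.empty((P, 4))
    for p in range(P):
        for c in range(4):
            cll[p, c] = _cell_ll_from_theta(rt, acc, xlen, starts, ends, theta, p, c)

    # adaptive proposal scales
    scale = np.empty((P, 18))
    for p in range(P):
        for k in range(18):
            t = SLOT_TYPE[k]
            scale[p, k] = max(sigma[t], 1e-3)
    sig_scale = np.empty(5)
    for t in range(5):
        sig_scale[t] = max(0.3 * sigma[t], 1e-3)

    acc_ct = np.zeros((P, 18))
    prop_ct = np.zeros((P, 18))
    sig_acc = np.zeros(5)
    sig_prop = np.zeros(5)
    asis_scale = np.empty(5)
    for t in range(5):
        asis_scale[t] = max(0.2 * sigma[t], 1e-3)
    shift_scale = np.empty(18)
    for k in range(18):
        t = SLOT_TYPE[k]
        shift_scale[k] = max(0.5 * sigma[t] / math.sqrt(P), 1e-4)
    theta_prop = np.empty(18)
    prop_cll = np.empty((P, 4))

    # type -> participants-per-type count for the SD update
    type_n = np.array([4 * P, 4 * P, 4 * P, 4 * P, 2 * P], dtype=np.float64)

    n_total = n_burnin + n_keep
    for it in range(n_total):
        adapting = it < n_burnin
        gamma = 1.0 / (10.0 + it) ** 0.6 if adapting else 0.0

        # --- participant-level random-walk updates -----------------------
        for p in range(P):
            for k in range(18):
                t = SLOT_TYPE[k]
                old = theta[p, k]
                new = old + scale[p, k] * np.random.normal()
                if k >= 16 and new <= MIN_ALPHA:
                    a_prob = 0.0
                    prop_ct[p, k] += 1.0
                    if adapting:
                        scale[p, k] *= math.exp(gamma * (a_prob - TARGET_ACCEPT))
                    continue
                # hierarchy term
                d_old = old - mu[k]
                d_new = new - mu[k]
                dlp = (d_old * d_old - d_new * d_new) / (2.0 * sigma[t] * sigma[t])
                # likelihood term: which cells does slot k touch?
                new_ll = 0.0
                nl0 = 0.0
                nl1 = 0.0
                c0 = 0
                theta[p, k] = new
                if k < 16:
                    c = k % 4
                    new_ll = _cell_ll_from_theta(rt, acc, xlen, starts, ends, theta, p, c)
                    dlp += new_ll - cll[p, c]
                else:
                    lang = k - 16
                    c0 = 2 * lang
                    nl0 = _cell_ll_from_theta(rt, acc, xlen, starts, ends, theta, p, c0)
                    nl1 = _cell_ll_from_theta(rt, acc, xlen, starts, ends, theta, p, c0 + 1)
                    dlp += (nl0 - cll[p, c0]) + (nl1 - cll[p, c0 + 1])
                a_prob = 1.0 if dlp >= 0 else math.exp(dlp)
                prop_ct[p, k] += 1.0
                if np.random.random() < a_prob:
                    acc_ct[p, k] += 1.0
                    if k < 16:
                        cll[p, k % 4] = new_ll
                    else:
                        cll[p, c0] = nl0
                        cll[p, c0 + 1] = nl1
                else:
                    theta[p, k] = old
                if adapting:
                    scale[p, k] *= math.exp(gamma * (a_prob - TARGET_ACCEPT))

        # --- group means: exact Gibbs ------------------------------------
        for k in range(18):
            t = SLOT_TYPE[k]
            m = 0.0
            for p in range(P):
                m += theta[p, k]
            m /= P
            mu[k] = _trunc_normal(m, sigma[t] / math.sqrt(P), mu_lo[k], mu_hi[k])

        # --- group SDs: random-walk Metropolis ---------------------------
        for t in range(5):
            k0 = 4 * t if t < 4 else 16
            k1 = k0 + 4 if t < 4 else 18
            ss = 0.0
            for p in range(P):
                for k in range(k0, k1):
                    d = theta[p, k] - mu[k]
                    ss += d * d
            old = sigma[t]
            new = old + sig_scale[t] * np.random.normal()
            sig_prop[t] += 1.0
            if new <= sigma_lo or new >= sigma_hi:
                a_prob = 0.0
            else:
                dlp = -type_n[t] * (math.log(new) - math.log(old))
                dlp -= ss / 2.0 * (1.0 / (new * new) - 1.0 / (old * old))
                a_prob = 1.0 if dlp >= 0 else math.exp(dlp)
                if np.random.random() < a_prob:
                    sigma[t] = new
                    sig_acc[t] += 1.0
            if adapting:
                sig_scale[t] *= math.exp(gamma * (a_prob - TARGET_ACCEPT))

        # --- group SDs: interweaved non-centered rescaling move ----------
        # Holding z_pk = (theta_pk - mu_k)/sigma_t fixed, propose sigma_t';
        # all theta of the type move to mu_k + sigma_t' * z_pk. With the
        # uniform SD prior the acceptance ratio is the trial-likelihood
        # ratio alone (the standardized deviations' density is unchanged).
        for t in range(5):
            k0 = 4 * t if t < 4 else 16
            k1 = k0 + 4 if t < 4 else 18
            old = sigma[t]
            new = old + asis_scale[t] * np.random.normal()
            if new <= sigma_lo or new >= sigma_hi:
                a_prob = 0.0
            else:
                ratio = new / old
                dlp = 0.0
                for p in range(P):
                    for k in range(18):
                        theta_prop[k] = theta[p, k]
                    for k in range(k0, k1):
                        theta_prop[k] = mu[k] + ratio * (theta[p, k] - mu[k])
                    if t == 4 and (theta_prop[16] <= MIN_ALPHA or theta_prop[17] <= MIN_ALPHA):
                        dlp = -1e250
                        break
                    for c in range(4):
                        a = theta_prop[16 + c // 2]
                        prop_cll[p, c] = _cell_loglik(
                            rt, acc, xlen, starts[p, c], ends[p, c],
                            theta_prop[c], theta_prop[4 + c],
                            theta_prop[8 + c], theta_prop[12 + c], a,
                        )
                        dlp += prop_cll[p, c] - cll[p, c]
                a_prob = 1.0 if dlp >= 0 else math.exp(dlp)
                if np.random.random() < a_prob:
                    sigma[t] = new
                    for p in range(P):
                        for k in range(k0, k1):
                            theta[p, k] = mu[k] + ratio * (theta[p, k] - mu[k])
                        for c in range(4):
                            cll[p, c] = prop_cll[p, c]
            if adapting:
                asis_scale[t] *= math.exp(gamma * (a_prob - TARGET_ACCEPT))

        # --- group means: interweaved translation move -------------------
        # Shift mu_k and every theta_pk by the same delta; the hierarchy
        # terms cancel, so acceptance is the likelihood ratio within the
        # prior box for mu_k.
        for k in range(18):
            delta = shift_scale[k] * np.random.normal()
            new_mu = mu[k] + delta
            if new_mu <= mu_lo[k] or new_mu >= mu_hi[k]:
                a_prob = 0.0
            elif k >= 16 and np.min(theta[:, k]) + delta <= MIN_ALPHA:
                a_prob = 0.0
            else:
                dlp = 0.0
                if k < 16:
                    c = k % 4
                    for p in range(P):
                        old_v = theta[p, k]
                        theta[p, k] = old_v + delta
                        prop_cll[p, 0] = _cell_ll_from_theta(
                            rt, acc, xlen, starts, ends, theta, p, c
                        )
                        theta[p, k] = old_v
                        dlp += prop_cll[p, 0] - cll[p, c]
                else:
                    c0 = 2 * (k - 16)
                    for p in range(P):
                        old_v = theta[p, k]
                        theta[p, k] = old_v + delta
                        prop_cll[p, 0] = _cell_ll_from_theta(
                            rt, acc, xlen, starts, ends, theta, p, c0
                        )
                        prop_cll[p, 1] = _cell_ll_from_theta(
                            rt, acc, xlen, starts, ends, theta, p, c0 + 1
                        )
                        theta[p, k] = old_v
                        dlp += (prop_cll[p, 0] - cll[p, c0]) + (prop_cll[p, 1] - cll[p, c0 + 1])
                a_prob = 1.0 if dlp >= 0 else math.exp(dlp)
                if np.random.random() < a_prob:
                    mu[k] = new_mu
                    if k < 16:
                        c = k % 4
                        for p in range(P):
                            theta[p, k] += delta
                            cll[p, c] = prop_cll[p, 0]
                    else:
                        c0 = 2 * (k - 16)
                        for p in range(P):
                            theta[p, k] += delta
                            cll[p, c0] = prop_cll[p, 0]
                            cll[p, c0 + 1] = prop_cll[p, 1]
            if adapting:
                shift_scale[k] *= math.exp(gamma * (a_prob - TARGET_ACCEPT))

        # --- store -------------------------------------------------------
        if it >= n_burnin:
            j = it - n_burnin
            idx = 0
            for p in range(P):
                for k in range(18):
                    out[j, idx] = theta[p, k]
                    idx += 1
            for k in range(18):
                out[j, idx] = mu[k]
                idx += 1
            for t in range(5):
                out[j, idx] = sigma[t]
                idx += 1

    rates = np.ones(n_par)
    idx = 0
    for p in range(P):
        for k in range(18):
            rates[idx] = acc_ct[p, k] / max(prop_ct[p, k], 1.0)
            idx += 1
    idx += 18  # Gibbs-updated group means
    for t in range(5):
        rates[idx] = sig_acc[t] / max(sig_prop[t], 1.0)
        idx += 1
    return out, rates
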