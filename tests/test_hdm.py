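"""Hierarchical model: posterior density, initialization, MCMC, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lexhdm import hdm, synthetic
from lexhdm.hdm import (
    HDMSpec,
    HDMState,
    MCMCConfig,
    empirical_quantiles,
    gelman_rubin,
    init_from_ez,
    log_posterior,
    posterior_predictive_quantiles,
    prepare_data,
    quantile_agreement,
    run_mcmc,
)
from lexhdm.wiener import DiffusionParams, wiener_fpt_density


def small_trials(n_participants=2, items=3, seed=42):
    trials, pps, _ = synthetic.simulate_dataset(
        synthetic.default_group_parameters(),
        synthetic.StudyDesign(n_participants=n_participants, items_per_cell=items),
        seed=seed,
    )
    return trials, pps


def naive_log_posterior(state, trials, spec):
    """Independent unvectorized reference: loop over the trial table rows,
    evaluate the density per trial via the public density function, add
    normal hierarchy terms via scipy."""
    lo_hi = spec.mu_lo_hi()
    if np.any(state.mu <= lo_hi[0]) or np.any(state.mu >= lo_hi[1]):
        return -np.inf
    if np.any(state.sigma <= spec.sigma_bounds[0]) or np.any(state.sigma >= spec.sigma_bounds[1]):
        return -np.inf
    pids = sorted(trials["participant"].unique().tolist())
    total = 0.0
    for _, row in trials.iterrows():
        p = pids.index(row["participant"])
        c = synthetic.condition_index(row["language"], row["type"])
        x = row["length"] - spec.length_center
        tau = state.theta[p, c] + state.theta[p, 4 + c] * x
        v = state.theta[p, 8 + c] + state.theta[p, 12 + c] * x
        a = state.theta[p, 16 + (0 if row["language"] == "german" else 1)]
        drift = v if row["correct"] else -v
        dens = wiener_fpt_density(row["rt_s"], DiffusionParams(a, 0.5, tau, drift), "upper")
        ll = math.log(dens) if dens > 0 else -700.0
        total += max(ll, -700.0)
    from lexhdm._sampler import SLOT_TYPE

    for p in range(len(pids)):
        for k in range(18):
            total += stats.norm.logpdf(state.theta[p, k], state.mu[k], state.sigma[SLOT_TYPE[k]])
    return total


class TestLogPosterior:
    def setup_method(self):
        # 2 participants x 2 blocks x (2 items x 4 lengths x 2 types): a
        # small fixture that keeps every participant x condition cell filled
        self.trials, self.pps = small_trials(items=2)
        self.spec = HDMSpec()
        group = synthetic.default_group_parameters()
        theta = np.stack([p.values for p in self.pps])
        self.state = HDMState(theta=theta, mu=group.mean_vector(), sigma=group.sigma_vector())

    def test_matches_naive_summation(self):
        data = prepare_data(self.trials, self.spec)
        ours = log_posterior(self.state, data, self.spec)
        ref = naive_log_posterior(self.state, self.trials, self.spec)
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_outside_prior_support_is_minus_inf(self):
        data = prepare_data(self.trials, self.spec)
        bad = HDMState(self.state.theta.copy(), self.state.mu.copy(), self.state.sigma.copy())
        bad.mu[16] = 10.0  # boundary mean above its prior box
        assert log_posterior(bad, data, self.spec) == -np.inf
        bad2 = HDMState(self.state.theta.copy(), self.state.mu.copy(), self.state.sigma.copy())
        bad2.sigma[0] = 5.0
        assert log_posterior(bad2, data, self.spec) == -np.inf

    def test_hierarchy_washes_out_with_huge_sds(self):
        """With very wide population SDs, posterior differences between two
        states of a single participant reduce to likelihood differences."""
        trials = self.trials[self.trials["participant"] == 0]
        data = prepare_data(trials, self.spec)
        theta = self.state.theta[:1].copy()
        big = HDMState(theta, self.state.mu.copy(), np.full(5, 1.999))
        theta2 = theta.copy()
        theta2[0, 8:12] += 0.21  # shift all drift intercepts
        big2 = HDMState(theta2, self.state.mu.copy(), np.full(5, 1.999))

        def pure_loglik(th):
            s = 0.0
            for _, row in trials.iterrows():
                c = synthetic.condition_index(row["language"], row["type"])
                x = row["length"] - 4.5
                tau = th[0, c] + th[0, 4 + c] * x
                v = th[0, 8 + c] + th[0, 12 + c] * x
                a = th[0, 16 + (0 if row["language"] == "german" else 1)]
                drift = v if row["correct"] else -v
                dens = wiener_fpt_density(row["rt_s"], DiffusionParams(a, 0.5, tau, drift), "upper")
                s += max(math.log(dens) if dens > 0 else -700.0, -700.0)
            return s

        dp = log_posterior(big2, data, self.spec) - log_posterior(big, data, self.spec)
        dl = pure_loglik(theta2) - pure_loglik(theta)
        # hierarchy contribution is O(shift^2 / sigma^2) ~ 1e-2, not exactly 0
        assert dp == pytest.approx(dl, abs=0.05)


class TestEZInitialization:
    def test_slopes_start_at_zero(self, small_cohort):
        states = init_from_ez(small_cohort["trials"], n_chains=2)
        assert np.all(states[0].theta[:, 4:8] == 0)
        assert np.all(states[0].theta[:, 12:16] == 0)

    def test_chains_differ_by_jitter(self, small_cohort):
        states = init_from_ez(small_cohort["trials"], n_chains=3)
        assert not np.allclose(states[0].theta, states[1].theta)
        assert not np.allclose(states[1].theta, states[2].theta)

    def test_group_drift_intercepts_near_truth(self, small_cohort):
        """EZ starting values for the drift intercepts land within 15% of
        the generating group means on a full-size dataset."""
        states = init_from_ez(small_cohort["trials"], n_chains=1)
        truth = small_cohort["group"].mean_vector()
        for k in range(8, 12):
            assert states[0].mu[k] == pytest.approx(truth[k], rel=0.15)

    def test_initial_state_has_finite_posterior(self, small_cohort):
        spec = HDMSpec()
        data = prepare_data(small_cohort["trials"], spec)
        for state in init_from_ez(small_cohort["trials"], n_chains=2, spec=spec):
            assert np.isfinite(log_posterior(state, data, spec))


class TestGelmanRubin:
    def test_same_distribution_near_one(self, rng):
        chains = rng.normal(0.0, 1.0, size=(2, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_hand_value(self, rng):
        """Chains at means 0 and 10 (SD 1, n=1000): B/n = 50, W ~= 1, so
        R-hat = sqrt(((n-1)/n * W + B/n) / W) ~= 7.14."""
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        W = chains.var(axis=1, ddof=1).mean()
        B_over_n = chains.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((999 / 1000) * W + B_over_n) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)
        assert gelman_rubin(chains) == pytest.approx(7.14, abs=0.4)

    def test_constant_chains(self):
        same = np.full((2, 100), 3.0)
        assert gelman_rubin(same) == 1.0
        distinct = np.stack([np.full(100, 0.0), np.full(100, 1.0)])
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            assert gelman_rubin(distinct) == np.inf

    def test_rejects_single_chain(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestRunMCMC:
    def test_same_seed_identical_chains(self, tiny_fit):
        again = run_mcmc(tiny_fit["trials"], tiny_fit["config"])
        np.testing.assert_array_equal(tiny_fit["fit"].chains, again.chains)

    def test_different_seed_differs(self, tiny_fit):
        cfg = tiny_fit["config"]
        other = run_mcmc(
            tiny_fit["trials"],
            MCMCConfig(n_chains=cfg.n_chains, n_samples=cfg.n_samples,
                       n_burnin=cfg.n_burnin, seed=cfg.seed + 1),
        )
        assert not np.array_equal(tiny_fit["fit"].chains, other.chains)

    def test_summary_structure(self, tiny_fit):
        fit = tiny_fit["fit"]
        n_params = 4 * 18 + 18 + 5
        assert fit.chains.shape == (2, 300, n_params)
        assert len(fit.param_names) == n_params
        assert np.all(fit.q025 <= fit.q975)
        assert np.all(np.isfinite(fit.rhat))
        gf = fit.group_frame()
        assert len(gf) == 23
        pf = fit.participant_frame()
        assert len(pf) == 4 * 4

    def test_posterior_means_in_plausible_range(self, tiny_fit):
        fit = tiny_fit["fit"]
        assert 0.2 < fit.group_mean("t0", "german", "word") < 0.6
        assert 1.0 < fit.group_mean("v0", "german", "word") < 6.0
        assert 0.8 < fit.group_mean("alpha", "german") < 2.5

    def test_group_interval_coverage_of_generating_values(self, raw_fit):
        """On untrimmed data from the full design, the 95% posterior
        intervals of at least 16 of the 18 group means cover their
        generating values."""
        fit = raw_fit["fit"]
        truth = raw_fit["group"].mean_vector()
        names = fit.param_names[-23:-5]
        covered = sum(
            fit.q025[fit[n]] <= t <= fit.q975[fit[n]] for n, t in zip(names, truth)
        )
        assert covered >= 16

    def test_participant_estimates_shrink_toward_group_mean(self, recovery_run):
        """Partial pooling: on average, participant-level posterior means
        sit closer to the group mean than their no-pooling EZ estimates."""
        fit = recovery_run["fit"]
        ez_state = init_from_ez(recovery_run["clean"], n_chains=1)[0]
        pf = fit.participant_frame()
        for lang, stype, slot in (("german", "word", 8), ("english", "pseudoword", 11)):
            mu = fit.group_mean("v0", lang, stype)
            cell = pf[(pf.language == lang) & (pf.type == stype)].sort_values("participant")
            post_spread = (cell["v0"].to_numpy() - mu) ** 2
            cond = synthetic.condition_index(lang, stype)
            ez_spread = (ez_state.theta[:, 8 + cond] - mu) ** 2
            assert post_spread.mean() < ez_spread.mean()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            MCMCConfig(n_samples=1)


class TestPosteriorPredictive:
    def test_quantiles_nondecreasing_in_q(self, tiny_fit):
        pred = posterior_predictive_quantiles(
            tiny_fit["fit"], synthetic.StudyDesign(n_participants=6, items_per_cell=10), seed=4
        )
        for _, cell in pred.groupby(["language", "type", "length"]):
            ordered = cell.sort_values("q")["rt_s"].to_numpy()
            assert np.all(np.diff(ordered) >= 0)

    def test_minimum_rt_above_fitted_nondecision_floor(self, tiny_fit):
        fit = tiny_fit["fit"]
        pred = posterior_predictive_quantiles(
            fit, synthetic.StudyDesign(n_participants=6, items_per_cell=10), seed=4
        )
        for (lang, stype, length), cell in pred.groupby(["language", "type", "length"]):
            t0 = fit.group_mean("t0", lang, stype)
            t1 = fit.group_mean("t1", lang, stype)
            tau = t0 + t1 * (length - 4.5)
            sd = 3 * fit.posterior_mean("sigma_t0")
            assert cell["rt_s"].min() > tau - 3 * sd

    def test_pseudoword_upper_quantiles_exceed_word(self):
        """At the generating parameters the slow tail is heavier for
        pseudo-words than words (lower drift, higher non-decision time).

        Only lengths 4-6 are checked: the opposite-signed drift slopes
        (words speed up, pseudo-words slow down with length) cross near 3
        letters, where pseudo-word drift actually exceeds word drift and
        the tail ordering legitimately flips."""
        trials, _, _ = synthetic.simulate_dataset(
            synthetic.default_group_parameters(),
            synthetic.StudyDesign(n_participants=24),
            seed=31,
        )
        q = empirical_quantiles(trials)
        piv = q[q["q"] == 0.9].set_index(["language", "type", "length"])["rt_s"]
        for lang in ("german", "english"):
            for length in (4, 5, 6):
                assert piv[(lang, "pseudoword", length)] > piv[(lang, "word", length)]


class TestQuantileAgreement:
    def test_identity_and_shift_invariance(self, small_cohort):
        q = empirical_quantiles(small_cohort["trials"])
        assert quantile_agreement(q, q) == pytest.approx(1.0)
        shifted = q.copy()
        shifted["rt_s"] = shifted["rt_s"] + 0.25
        assert quantile_agreement(q, shifted) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame(
            {"language": ["german"], "type": ["word"], "length": [4], "q": [0.5], "rt_s": [0.6]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            quantile_agreement(df, df)
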