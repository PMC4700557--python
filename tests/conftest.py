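import numpy as np
import pytest

from lexhdm import hdm, preprocess, synthetic

# Fixed study-condition seeds for the expensive shared runs. Chosen once;
# every consumer asserts against the same fit.
RECOVERY_DATA_SEED = 20160105
RECOVERY_FIT_SEED = 424242


@pytest.fixture(scope="session")
def recovery_run():
    """The full parameter-recovery experiment: simulate the complete design
    at the default (ground-truth) group parameters, preprocess, and fit
    with 2 chains x 3000 post-burn-in samples.

    Session-scoped: this is the expensive shared surface that the
    acceptance-style checks and the deeper recovery tests all reuse.
    """
    group = synthetic.default_group_parameters()
    design = synthetic.StudyDesign()
    trials, participants, info = synthetic.simulate_dataset(
        group, design, seed=RECOVERY_DATA_SEED
    )
    clean, report = preprocess.apply_exclusions(trials)
    cfg = hdm.MCMCConfig(n_chains=2, n_samples=3000, n_burnin=1000, seed=RECOVERY_FIT_SEED)
    fit = hdm.run_mcmc(clean, cfg)
    return {
        "group": group,
        "design": design,
        "trials": trials,
        "clean": clean,
        "report": report,
        "info": info,
        "fit": fit,
    }


@pytest.fixture(scope="session")
def raw_fit():
    """Fit to the untrimmed simulated cohort (full design), for checks of
    the sampler itself — interval coverage of the generating values — with
    no exclusion-induced selection in the data."""
    group = synthetic.default_group_parameters()
    trials, participants, _ = synthetic.simulate_dataset(
        group, synthetic.StudyDesign(), seed=RECOVERY_DATA_SEED
    )
    cfg = hdm.MCMCConfig(n_chains=2, n_samples=1500, n_burnin=1000, seed=RECOVERY_FIT_SEED)
    return {"group": group, "fit": hdm.run_mcmc(trials, cfg)}


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort (8 participants, full item
    count) for tests that need realistic data without a long fit."""
    group = synthetic.default_group_parameters()
    design = synthetic.StudyDesign(n_participants=8)
    trials, participants, info = synthetic.simulate_dataset(group, design, seed=555)
    return {"group": group, "design": design, "trials": trials,
            "participants": participants, "info": info}


@pytest.fixture(scope="session")
def tiny_fit():
    """A fast end-to-end fit on a reduced design for structural tests."""
    group = synthetic.default_group_parameters()
    design = synthetic.StudyDesign(n_participants=4, items_per_cell=8)
    trials, _, _ = synthetic.simulate_dataset(group, design, seed=77)
    cfg = hdm.MCMCConfig(n_chains=2, n_samples=300, n_burnin=150, seed=88)
    return {"trials": trials, "config": cfg, "fit": hdm.run_mcmc(trials, cfg)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
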