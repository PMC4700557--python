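"""End-to-end orchestration: simulate -> preprocess -> fit -> ppc -> infer.

Every stage persists its inputs and outputs as delimited text in the output
directory; a single global seed deterministically derives all module seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hdm, inference, preprocess, synthetic

log = logging.getLogger("lexhdm")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 1
    design: synthetic.StudyDesign = field(default_factory=synthetic.StudyDesign)
    group: synthetic.GroupParameters = field(default_factory=synthetic.default_group_parameters)
    n_chains: int = 2
    n_samples: int = 10_000
    n_burnin: int = 1_000
    run_preprocess: bool = True


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "fit", "ppc")
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        for n, c in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of the key artifacts in memory.

    Stage failures propagate after the preceding stages' outputs have been
    written, so partial results remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    t0 = time.time()

    stage = "simulate"
    try:
        trials, participants, info = synthetic.simulate_dataset(
            config.group, config.design, seed=seeds["simulate"]
        )
        synthetic.write_trials(trials, out / "trials.tsv")
        synthetic.write_participants(participants, out / "ground_truth.tsv")
        log.info(
            "simulated %d trials (%d censored, %.2f%%)",
            len(trials), info["n_censored"], 100 * info["censored_fraction"],
        )

        stage = "preprocess"
        if config.run_preprocess:
            clean, report = preprocess.apply_exclusions(trials)
            report.write(out / "exclusions.txt")
        else:
            clean, report = trials, None
        synthetic.write_trials(clean, out / "trials_clean.tsv")
        summary_tab = preprocess.condition_summary(clean)
        summary_tab.to_csv(out / "condition_summary.tsv", sep="\t", index=False, float_format="%.6f")

        stage = "fit"
        cfg = hdm.MCMCConfig(
            n_chains=config.n_chains,
            n_samples=config.n_samples,
            n_burnin=config.n_burnin,
            seed=seeds["fit"],
        )
        fit = hdm.run_mcmc(clean, cfg)
        fit.save(out)
        log.info("max R-hat %.4f", fit.max_rhat())

        stage = "ppc"
        emp_q = hdm.empirical_quantiles(clean)
        pred_q = hdm.posterior_predictive_quantiles(fit, config.design, seed=seeds["ppc"])
        emp_q.to_csv(out / "quantiles_empirical.tsv", sep="\t", index=False, float_format="%.6f")
        pred_q.to_csv(out / "quantiles_predicted.tsv", sep="\t", index=False, float_format="%.6f")
        r = hdm.quantile_agreement(emp_q, pred_q)

        stage = "infer"
        effects = inference.posterior_inference(fit.participant_frame())
        effects.to_csv(out / "effects.tsv", sep="\t", index=False, float_format="%.6g")
    except Exception:
        log.error("pipeline failed during stage %r", stage)
        raise

    run_log = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_trials": len(trials),
        "n_trials_clean": len(clean),
        "censored_fraction": info["censored_fraction"],
        "max_rhat": fit.max_rhat(),
        "min_accept_rate": float(np.min(fit.accept_rates)),
        "quantile_agreement_r": r,
        "runtime_s": time.time() - t0,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)

    return {
        "trials": trials,
        "clean": clean,
        "ground_truth": synthetic.participants_to_frame(participants),
        "exclusion_report": report,
        "fit": fit,
        "empirical_quantiles": emp_q,
        "predicted_quantiles": pred_q,
        "quantile_agreement_r": r,
        "effects": effects,
        "run_log": run_log,
    }
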