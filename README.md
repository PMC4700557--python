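# lexhdm

Hierarchical diffusion-model analysis of word-length effects in bilingual
lexical decision.

Mean RTs in lexical decision often show no word-length effect for real
words, yet robust slowing for pseudo-words. A drift-diffusion decomposition
can explain such null results as two opposing sub-process effects:
perceptual encoding (non-decision time τ) slows with length while evidence
accumulation (drift rate ν) speeds up with length for words and slows for
pseudo-words. This package implements that analysis as a tested,
reproducible pipeline for German–English bilingual data: a synthetic-data
generator for the study design (no behavioral data were deposited), the
exclusion rules, a hierarchical Bayesian Wiener-diffusion fit, and the
posterior-based inference.

## Model

Each trial is a Wiener first passage between absorbing boundaries 0 and α,
start point β·α with β = 0.5, drift ν, unit diffusion (s = 1), plus
non-decision time τ; the upper boundary codes the correct response. Length
enters through linear links per language g × stimulus-type w condition:

    τ_pgw(length) = t⁰_pgw + t¹_pgw · (length − 4.5)
    ν_pgw(length) = v⁰_pgw + v¹_pgw · (length − 4.5)

so each participant p has 18 parameters (8 non-decision, 8 drift, 2
boundary), drawn from condition-specific normal population laws with SDs
shared across conditions. Group means and SDs carry uniform priors and are
estimated by Metropolis-within-Gibbs MCMC (adaptive scalar updates, exact
Gibbs for group means, interweaved non-centered moves for the hierarchy;
EZ-diffusion starting values; Gelman–Rubin convergence checks). See
`docs/methods.md` for the full account.

## Worked example

The numbered drivers under `analysis/` run the pipeline stage by stage and
write all tables to `results/`:

```
python analysis/01_simulate.py  --seed 1
python analysis/02_preprocess.py
python analysis/03_fit_hdm.py   --seed 2
python analysis/04_posterior_predictive.py
python analysis/05_inference.py
```

With `--seed 1`, `01_simulate.py` prints:

```
wrote 13872 trials for 28 participants -> results/trials.tsv
trials per block: 245..248 (248 scheduled)
omissions (deadline reached): 16 (0.12%)
```

i.e. the full design is 28 participants × 2 language blocks × 248 trials,
minus the handful of trials that reach the 2 s deadline. `02_preprocess.py`
reports

```
excluded 2.8% of trials (386 RT outliers, 0 items)
max per-participant exclusion: 3.6%
```

plus the condition summary (mean correct RTs 611/650/682/734 ms for German
words/German pseudo-words/English words/English pseudo-words — pseudo-words
slower than words, English slower than German). `03_fit_hdm.py` (seed 2,
~4 min) ends with

```
max R-hat over all 527 parameters: 1.0202
```

and the group-level posterior table: the English word drift slope
`mu_v1[english,word]` comes back 0.171 [0.106; 0.236] evidence units per
letter (accumulation speeds up for longer words; generating value 0.17),
the English pseudo-word non-decision slope 0.0129 [0.0102; 0.0155] s per
letter (encoding slows with length; generating value 0.013), and the German
pseudo-word drift slope −0.260 [−0.331; −0.189] (generating value −0.19 —
drift intercepts and slopes carry the trimming caveat below).
`04_posterior_predictive.py` prints

```
empirical vs model quantiles over 80 cells: r = 0.9918
```

and `05_inference.py` prints the effect table: non-decision slopes
significantly positive in all four conditions (e.g. English pseudo-words
t(27) = 69.2, p < .001), drift slopes negative for German pseudo-words and
positive for words, and no boundary difference between language blocks
(t(27) = 0.87, p = 0.39) — decision caution, not evidence quality, is what
does *not* differ between a bilingual's languages here.

The same stages are available as a console tool
(`lexhdm simulate|preprocess|fit|ppc|infer|all`) and as library calls
(`lexhdm.synthetic`, `lexhdm.preprocess`, `lexhdm.hdm`,
`lexhdm.inference`, `lexhdm.pipeline`).

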