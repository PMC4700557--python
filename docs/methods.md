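# Methods

## The model

Lexical decision is modeled as a two-boundary Wiener diffusion: evidence
accumulates at mean rate ν (drift, evidence units/s) with unit diffusion
coefficient (s = 1, the scaling convention) between absorbing boundaries at
0 and α; the process starts at β·α with β fixed to 0.5 (no response bias;
the blocks contain equal numbers of words and pseudo-words), and observed
RT adds a non-decision time τ (s) for encoding and motor preparation.
Responses are accuracy-coded: the upper boundary is the correct response
for both stimulus types, so ν is positive toward correct. Inter-trial
variabilities of ν and τ are fixed to 0. The trial likelihood is the joint
Wiener first-passage density over (RT, boundary).

Word length acts through linear link functions per language × stimulus-type
condition:

    τ(length) = t0 + t1 · (length − 4.5)
    ν(length) = v0 + v1 · (length − 4.5)

Lengths run 3–6 letters; centering at their mean (4.5) makes each intercept
the across-length average of its parameter and decorrelates intercepts and
slopes during sampling. Each participant thus carries 18 parameters: 4 × t0,
4 × t1, 4 × v0, 4 × v1 (one per condition) and 2 × α (one per language
block). Participant parameters are draws from condition-specific normal
population laws; the population SD of each parameter type (σ_t0, σ_t1,
σ_v0, σ_v1, σ_α) is shared across conditions, which stabilizes variance
estimation. Group means and SDs carry uniform priors:
t0 ∈ (0.05, 1), t1 ∈ (−0.2, 0.2), v0 ∈ (−7, 7), v1 ∈ (−2, 2),
α ∈ (0.3, 4), all SDs ∈ (0.001, 2). The ranges are config-overridable
(`HDMSpec`), as is the length center, so sensitivity to either choice can
be checked.

## Likelihood evaluation

The first-passage density uses the standard dual-regime series: the
small-time expansion in (w + 2k)·exp(−(w+2k)²/2u) and the large-time sine
series, with the regime chosen per evaluation by comparing the number of
terms each needs for an absolute truncation error ≤ 1e−10. The
log-likelihood of a trial is floored at −700 where the density vanishes or
underflows (e.g. RT ≤ τ under a proposed state), so the sampler can always
evaluate and recover from bad proposals. The 2 s response deadline is not
modeled in the likelihood: omissions never enter the data, and observed RTs
are treated as uncensored (at the generating parameters fewer than 0.1% of
trials reach the deadline).

## Sampler

Estimation is Metropolis-within-Gibbs, with all randomness derived from a
single seed:

* every participant-level parameter: scalar Gaussian random-walk
  Metropolis, with per-parameter proposal scales adapted toward 0.44
  acceptance during burn-in only and frozen afterward (preserving detailed
  balance for retained samples);
* group means: exact Gibbs draws (truncated normal; conjugate given the
  participant values, uniform prior box);
* group SDs: scalar random-walk Metropolis;
* two interweaving moves per sweep, in the spirit of
  ancillarity–sufficiency interweaving: (a) per SD, a non-centered
  rescaling — the SD is proposed while all standardized participant
  deviations are held fixed, so participant values rescale jointly; (b) per
  group mean, a translation — the mean and all its participant values shift
  together, hierarchy terms cancelling, so acceptance depends only on the
  trial likelihood.

The interweaving moves matter because the slope hierarchies are funnels:
the true between-participant SD of the drift slopes (~0.02) is far below
per-participant measurement noise, and a purely centered sampler shows
R-hat ≈ 2 on σ_v1 at this design. With both moves the maximum split-free
Gelman–Rubin statistic over all 527 sampled parameters is ≈ 1.01–1.02 at
2 chains × 3000 retained samples.

Starting values come from the EZ-diffusion closed forms applied per
participant × condition with lengths pooled (slopes start at 0); accuracy
exactly 1 is edge-corrected to 1 − 1/(2n). Chains beyond the first get 5%
multiplicative jitter. Convergence is monitored with the basic
potential-scale-reduction statistic sqrt(((n−1)/n · W + B/n) / W).

## Synthetic data generator

The generator emulates the study design exactly: 28 participants × 2
language blocks (German, English) × {word, pseudo-word} × lengths 3–6 with
31 items per length × type cell (248 trials/block), 2 s deadline, item
order shuffled per participant. Ground-truth group means are the reported
group-level posterior estimates for this design; the between-participant
SDs are not reported and are fixed at σ_t0 = 0.03, σ_t1 = 0.002,
σ_v0 = 0.30, σ_v1 = 0.02, σ_α = 0.10 — values that put the implied
between-participant spread of condition means and error rates in the range
descriptive tables of such experiments show. Boundary draws are redrawn
below 0.2, and a participant is redrawn if any implied τ at a design length
falls below 0.05 s.

Trials are simulated by Euler–Maruyama with dt = 0.5 ms. Plain Euler
first-passage sampling overestimates passage times by O(√dt) (missed
within-step crossings) — about +2% on mean decision time here, which is
material for moment-level checks — so the standard continuity correction is
applied (absorbing boundaries moved inward by 0.5826·s·√dt). After the
correction, simulated choice probabilities and correct-RT means/variances
match the closed forms to Monte-Carlo error at n = 4 × 10⁵. Trials that
reach the deadline are recorded as omissions and dropped (<0.1% at the
default parameters).

What the generator deliberately does not emulate: real stimulus properties
(frequency, neighborhood, bigram structure — items are exchangeable and
carry no item effects), anticipatory or contaminant RTs, fatigue or
practice drift, and response bias. Passing recovery tests therefore show
that the pipeline recovers diffusion parameters from data that obey the
model, not that the model describes real readers.

## Exclusion rules

Two rules mirror the study's cleaning: (1) within each participant's
design cell, raw RTs beyond 2.5 sample SDs of the cell mean are removed in
a single pass (correct and error trials pooled); (2) items answered
incorrectly by strictly more than 40% of the participants who saw them are
dropped entirely, with item error fractions computed on pre-trimming data
(item difficulty is a stimulus property). Both removal sets are computed
on the raw table and unioned.

The outlier cell defaults to the full design cell (language × type ×
length). The coarser reading (language × type, lengths pooled) is
available as an option but is not the default for a statistical reason:
with one pooled cutoff, intrinsically slower cells — long pseudo-words —
lose systematically more of their slow tail, and this length-correlated
selection attenuates recovered length slopes by roughly twice the
tolerance the recovery experiment allows, even with a perfectly converged
sampler. Per-cell cutoffs trim every design cell symmetrically.

## Known limitation: trimming bias on drift

A 2.5 SD trim removes ~2.5–3% of contaminant-free Wiener data — almost all
from the slow tail. Fitting the untruncated Wiener density to such trimmed
samples biases drift upward: in a direct maximum-likelihood experiment
(10⁴ trials at α = 1.55, τ = 0.37, ν = 3.05) trimming moves the drift
estimate from 3.045 to 3.300 while α and τ move by less than 0.02. The
hierarchical recovery reproduces this: drift intercepts come back ~+0.1 to
+0.35 high while non-decision and boundary parameters are essentially
unbiased. On real data the same rule removes genuine non-diffusion
contaminants (anticipations, lapses), which is why it is standard practice
there; on synthetic data it is purely a selection artifact. Recovery
checks on drift intercepts consequently sit at or beyond their tolerance
by construction; this is documented rather than compensated, because the
pipeline's cleaning step is part of the procedure being emulated.

## Second-stage inference

Participant-level posterior means are treated as observations:
2 × 2 within-subject ANOVAs (language × stimulus type) per parameter,
computed by explicit sums of squares with each effect tested against its
own effect-by-subject interaction; generalized eta squared uses all
subject-involving SS terms in the denominator. Length slopes get two-sided
one-sample t-tests against 0 per condition; the boundary gets a paired
t-test between language blocks. No multiple-testing correction is applied.
Degenerate inputs (zero-variance slopes, constant paired differences) are
reported with flags rather than raised.

## Problem sizes and determinism

The recovery experiment runs the full design (≈13,900 trials) with
2 chains × (1000 burn-in + 3000 retained) sweeps, about 4 minutes on one
CPU with the numba-compiled kernels; the test suite's smoke profiles use
3–8 participants and short chains. Every stage derives its seed from one
`numpy.random.SeedSequence`, and equal seeds reproduce byte-identical
trial tables and bit-identical chains.
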