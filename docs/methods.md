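# Methods

## The model

Each two-choice trial is modelled as a Wiener diffusion: evidence starts at
`z_rel * a`, drifts at rate `v` with unit diffusion coefficient (`s = 1`),
and a response is produced when it first reaches 0 or `a`, plus a
non-decision offset `t` (stimulus encoding and motor preparation).  Under
accuracy coding the upper boundary is the correct response.  The trial
likelihood is the defective first-passage-time density

    f_upper(rt | t, a, v) ,  f_lower(rt | t, a, v),

evaluated at decision time `rt − t`.  We compute it with the standard pair
of series expansions of the normalized (a = 1, v = 0) density — a sum of
Gaussian terms that converges quickly at short times and a sine series that
converges quickly at long times — switching wherever fewer terms are needed
for a truncation error below `tol` (default 1e-7, inflated/deflated to keep
the error bound on the *unnormalized* density after the exponential drift
factor is applied).  Closed forms used as oracles throughout the tests:

* absorption probability `P(upper) = (1 − e^{−2 v z}) / (1 − e^{−2 v a})`,
  which reduces to `1 / (1 + e^{−a v})` at `z_rel = 0.5`;
* unbiased mean decision time `(a / 2v) · tanh(a v / 2)` (limit `a²/4`).

The scaling constant is `s = 1`; with `s = 0.1` the fitted parameter
magnitudes (a ≈ 1.6–2.2, v ≈ 1.1–3.6) would imply mean RTs an order of
magnitude away from the observed 0.6–1.4 s range, so the choice is forced
by the published values themselves (the forward-consistency tests verify
this: the letter-identification parameter set reproduces a ~601 ms mean RT
against the published 599 ms).

## Hierarchy

One independent model per task.  For each age group g and parameter
p ∈ {t, a, v}, subjects' values are drawn from Normal(mu_{g,p},
sigma_{g,p}), truncated to (0, ∞) for t and a.  The start point is fixed at
`z_rel = 0.5` (equal target/non-target frequencies) and all inter-trial
variabilities at 0.  The "36 parameters" of the full 4-task × 3-group
design count the group locations (4 × 3 × 3); spreads are estimated but not
counted.  Priors (weakly informative; the source analysis does not state
its priors, so these are a design choice):

| quantity  | prior                          |
|-----------|--------------------------------|
| mu_t      | Normal(0.4, 0.3) on [0, ∞)     |
| mu_a      | Normal(2.0, 1.5) on (0, ∞)     |
| mu_v      | Normal(2.0, 3.0)               |
| sigma_*   | Half-Normal(1)                 |

All prior scales are wide relative to the posterior spread of desk-scale
fits (posterior SDs of locations are ~0.005–0.1), so the priors contribute
little beyond domain support; moving the location centers by ±50% moves
desk-run posterior means by well under one posterior SD.

## Sampling

MAP initialization: per-subject method-of-moments (EZ-style) estimates from
accuracy and correct-RT mean/variance, refined by Nelder–Mead coordinate
ascent alternating with group-level updates; chains start from the MAP with
1% multiplicative jitter.

The sampler is adaptive Metropolis-within-Gibbs, fully jit-compiled.  Per
iteration:

1. scalar random-walk updates of every subject's t, a, v;
2. a per-subject joint move scaling a and v by a common factor `e^ε`
   (with the `2ε` Jacobian) — the weakly identified ridge when accuracy is
   at ceiling, where the data pin the ratio a/v (timing) much harder than
   the product a·v (error rate);
3. scalar updates of each group location and log-scale updates of each
   spread;
4. a translation move shifting a location together with all its subjects'
   values (decouples mu from theta);
5. a funnel move scaling a spread together with its subjects' deviations
   from the location, `σ' = cσ, θ' = μ + c(θ − μ)` (for a and v; spreads of
   t are data-dominated and need none);
6. a group-level joint move scaling mu_a, mu_v, sigma_a, sigma_v and all
   subjects' a, v by a common factor — the slowest collective mode of the
   ceiling-accuracy ridge.

Moves 2, 4, 5 and 6 are what make desk-scale runs satisfy the R-hat ≤ 1.02
criterion; with scalar updates alone R-hat stalls at 1.1–1.4.  All proposal
scales adapt toward 0.3 acceptance in windows of 25 iterations during
burn-in only and are frozen afterward, preserving detailed balance for the
retained draws.  Correctness check: with zero trials the sampler must
reproduce the prior exactly (locations marginally truncated-normal, spreads
half-normal); this is asserted in the test suite and validates every move
type including Jacobians and truncation normalizers.

Presets: `full` = 3 chains × 15,000 draws, 5,000 burn-in (the original
profile); `desk` = 3 × 10,000 / 3,000, sized so that desk-scale recovery
runs meet the same R-hat ≤ 1.02 criterion in ≈5 min per task on one CPU.

## Diagnostics, PPC, group comparison

Convergence uses the classic (non-split, non-rank-normalized) Gelman–Rubin
statistic, `sqrt(((n−1)/n·W + B/n)/W)`, on retained draws, threshold 1.02 —
matching the criterion used with the original toolchain.  Posterior
summaries are means with equal-tailed 95% intervals.

Posterior-predictive checks simulate replicate datasets (default 500; 150
in the test suite) drawing one retained posterior draw per subject per
replicate and re-simulating that subject's full trial set under the 3 s
deadline, then comparing RT quantiles (0.1, 0.3, 0.5, 0.7, 0.9) of correct
responses: Pearson r between observed and replicate-mean quantiles pooled
over (subject, quantile) pairs within task, plus the coverage of the
equal-tailed 95% replicate band.  Group panels average subject quantiles
within group.

Group differences are posterior exceedance probabilities: the fraction of
aligned (same chain, same iteration) draws in which one group's location
exceeds another's, ties counting ½, so P(A>B) = 1 − P(B>A) exactly.  A
histogram overlap coefficient is reported as a secondary descriptive.
Probabilities are printed to 3 decimals and shown as ">0.999" unless every
draw agrees.

## Synthetic cohorts

The generator emulates the study design: groups young / high-performing
older / low-performing older (full-scale 384/384/1039), four tasks, 80
trials per task (40 targets, 40 non-targets), 3 s deadline.  Group-mean
(t, a, v) default to the published group-level posterior means; each
subject's values are truncated-normal draws around them.  The
between-subject SD (10% of the group mean) is a synthetic assumption — the
publication reports only group-level posteriors, so recovery exercises test
the artifact's self-consistency, not the study's unpublished spreads.
Deadline hits are emitted with missing RT/correctness and dropped by
preprocessing; optional contaminant trials are uniform-RT guesses on
[200 ms, deadline] with random correctness.  Trials are simulated by
Euler–Maruyama with a 1e-4 s step; at that step the discretization bias is
~+0.4% in mean RT and < 0.0005 in choice probability against the closed
forms (asserted in tests).  Item-level structure (frequency, neighborhood)
is not modelled; stimulus type is a label only, matching the fitted model,
which uses one drift per subject per task.

## Preprocessing

Two rules, in the narrated order: drop RTs below 300 ms (strict; a 300 ms
trial survives), then remove trials deviating more than 2.5 *sample* SDs
(ddof = 1; a fixed choice, the source is silent) from the subject's mean
within each task × stimulus-type cell, in a single pass with the cell
statistics computed once.  Non-responses are dropped first and logged.

## Known limitation: the truncate-and-refit ratchet

A finding of this implementation, documented because it bounds what the
recovery loop can show.  The first-passage RT distribution is right-skewed,
so the 2.5-SD rule applied to *clean model-generated* data still removes
~2.5–3% of trials, almost all from the slow tail.  Fitting the plain WFPT
likelihood to tail-truncated data systematically overestimates boundary
separation (≈ +5–15%) and drift rate (≈ +6–17%) in tasks whose accuracy is
near ceiling (letter identification, lexical decision), while non-decision
time stays within ~3%.  Single-subject maximum-likelihood experiments
isolate the mechanism: the same simulated data recover the generating
values within 1% untruncated, and shift by a ≈ +5%, v ≈ +10% after a single
2.5-SD pass.  Consequently the generate → preprocess → fit loop cannot
return the generating a and v within 5% under these conditions; the
recovery tests for those parameters document the bias rather than hide it
(the t recovery, convergence, directional-inference and forward-consistency
checks are unaffected).  In the original analysis the exclusion was applied
once to raw empirical data (which contains genuine non-diffusion outliers),
so its published estimates carry this truncation compromise exactly once;
re-applying the rule to data simulated from those estimates compounds it.

## Problem sizes

Desk-scale runs use 30 subjects per group (top of the 15–30 desk range, so
cohort-mean sampling error ≈ cv/√n ≈ 1.8% stays small against the 5%
recovery band) with 80 trials per subject; forward-consistency checks use
10⁵ simulated trials (Monte-Carlo SE ≈ 0.4 ms on the mean RT).
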