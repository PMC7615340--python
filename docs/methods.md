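# Methods

## The allocation model

Each patient `n` has biomarkers `x_n` and, for each arm `k`, a latent
outcome `Y_{n,k}`.  The design's allocation rule is:

* patients `1 … L·K` (default `L = 5` per arm): equal randomization.  Two
  burn-in variants are provided; the default draws a random permutation of
  a block containing exactly `L` patients per arm, which guarantees every
  arm has `L` observations before the first model fit (pure Bernoulli
  randomization is available via `balanced_burn_in=False`, but can leave
  an arm empty and abort the first fit — the engine raises a state error
  in that case rather than guessing).
* patients `L·K + 1 … N`: refit one regression per arm on the information
  available at the patient's arrival, predict each arm's outcome at
  `x_n`, take the argmax (ties broken uniformly at random, avoiding a
  systematic bias toward low arm indices), and assign the argmax arm with
  probability `1 − (K−1)·π_n`, each other arm with probability `π_n`.

`π_n` is affine in the enrollment index, anchored at `π_{L·K} = π_start`
(default `1/K`) and `π_N = π_end` (default 0.1), so the randomization
floor never vanishes unless `π_end = 0` is requested explicitly.  The
same anchoring is used at every trial size, including `N = 233`.
Formulas are written for general `K`; the shipped scenarios have `K = 2`
with arm 1 the control and arm 2 the experimental treatment.

## Outcome models

**Continuous scenarios** (`s1`–`s6`): `Y_{n,k} = f_k(x_n) + ε_{n,k}` with
`x_n ~ U[−100, 100]` and `ε_{n,k} ~ N(0, σ_k(x_n)²)`,
`σ_k(x) = c·|f_k(x)|` (default `c = 0.1`), so the noise scales with the
magnitude of the mean outcome.  If an arm's `f_k` is constant in `x`, its
σ is frozen at `c·|f_other(X)|`, the varying arm's noise level at the
crossing point `X`, so the flat arm is not artificially easy to estimate.
In `s6` the varying arm is discontinuous at `X`; the right-continuous
branch is used, a convention fixed once.

The six mean-function pairs are package choices designed to realise the
qualitative structure of a null (`s1`: `f1 = f2 = 10`), a prognostic
biomarker (`s2`: parallel slopes, arm 2 uniformly 3 better), a predictive
biomarker with the control best for the 54% majority (`s3`: flat control,
arm-2 slope −0.25 crossing at `X = −8`), a weakly predictive-and-
prognostic pair with a small gap (`s4`: slopes 0.06 / 0.07 crossing at
`X = −11`), a moderate predictive effect (`s5`: flat control vs. slope
0.06 crossing at `−8`) and a step-function effect (`s6`: 16 below `−8`,
9 above, vs. flat 10).  All forms are replaceable by constructing a
custom `ScenarioSpec`.

**Survival case study** (`cs1`–`cs4`): overall survival is exponential
with per-cell means (days), two independent binary biomarkers coded
{1, 2} with prevalences P(RLC > 13%) = 0.6824 and P(KI ≥ 70%) = 0.8584.
The control mean is 98 days in every cell (68-day median / ln 2); the
experimental means derive from hazard ratios (98/0.695 ≈ 141,
98/0.518 ≈ 189 for the RLC split in `cs3`; 90/160/170/200 across the four
cells in `cs4`, with the best outcome in the doubly-favourable cell).
`cs1`/`cs2` are null (equal means); `cs2` keeps the differential dropout
of the effect scenarios (20% control / 8% experimental) while `cs1` uses
20%/20%.  Draws are rounded **up** to integer days so all times are ≥ 1.

Calendar time: inter-arrival gaps are Poisson(5) (mean accrual
1250/233 ≈ 5.36 days rounded to 5); same-day arrivals are legal and keep
enrollment order.  A dropout's censoring day is uniform on the integers
`1..T` of their latent survival `T` (a dropout is censored even when the
drawn day equals `T`).  After the last arrival every patient is followed
up 180 more days ("six months"); deaths beyond that are administratively
censored.  At each allocation the learners see the *interim* view: deaths
are only observed if they precede both the current calendar day and the
patient's dropout day; everyone else is censored at follow-up-so-far.

## Learners

Continuous families (defaults exposed in `learner_kwargs`): polynomial
least squares (degree 3, auto-reduced on degenerate support), k-nearest
neighbour (`k = max(3, ⌈√n⌉)`, distance ties include all tied points),
Gaussian process (RBF + white noise, marginal-likelihood maximization
with 5 restarts; inside the trial loop hyperparameters are re-optimized
every 5th fit per arm and the posterior refit exactly in between — a
speed/fidelity trade-off that changes allocations negligibly), cubic
smoothing spline (GCV; needs 4 distinct x, else polynomial fallback) and
random forest (100 trees; continuous setting only).  A degenerate-data
fallback ladder (family → reduced-degree polynomial → arm mean) keeps
predictions defined after any burn-in.

Survival families work on censored data over the 4 biomarker cells and
predict **mean survival time**, so the argmax maximizes predicted mean
OS (under exponential models the mean and median orderings agree):

* `cellwise` (the flexible/saturated analogue, aliased from `spline`,
  `gp`, `nearest`): per-cell exponential MLE `Σt/Σδ`; zero-event cells
  shrink to the arm-pooled exponential mean, and an arm with no events
  anywhere uses its total observed time, a conservative lower bound that
  keeps prediction defined under heavy interim censoring.
* `main_effects` (the low-order-polynomial analogue): log-link
  exponential (constant-hazard) regression with additive biomarker main
  effects, fitted by damped Newton iteration on the cell-aggregated
  likelihood (equivalent to a Poisson GLM with log-time offset, which the
  test suite uses as an independent cross-check); non-convergence falls
  back to `cellwise`.

Random forest is excluded from the survival setting: with two binary
predictors the trees have almost no structure to exploit.

## Evaluation

"Individually best arm" defaults to the arm with the larger latent
*draw*: every arm's latent outcome is simulated for every patient
(counterfactuals included), each patient's outcome noise being drawn
independently across arms from the patient's own substream.  Under this
definition even an oracle allocator scores well below 1.0 with
exponential outcomes — the control draw often beats the experimental draw
despite a worse mean — which is the phenomenon the case-study results
display.  The latent-*mean* definition (oracle score exactly 1.0) is
available via `definition="latent_mean"`.  Because each replicate's
population (biomarkers, latent outcomes, arrivals, censoring) is drawn
from substreams independent of the allocation stream, two designs run on
the same root seed face identical patients, which sharpens RAR-vs-FR
comparisons.

Continuous endpoints are compared with Welch's unequal-variance test
(the generative noise is heteroscedastic by construction; pooled-variance
Student's t via `equal_var=True`), one-sided alternative "experimental
mean greater", at levels 0.025/0.05 overall and 0.0125/0.025 in the four
biomarker subgroups (split at 0 and at the true crossing `X`; scenarios
without a crossing simply omit the X-splits).  A subgroup that leaves an
arm with fewer than two observations counts as a non-rejection with a
warning.  Survival endpoints use the logrank test on the administrative-
censoring-date data; the statistic is the standard risk-set tabulation
with the multi-death variance correction, implemented directly so the
signed deviate is available for one-sided testing, and verified in tests
against both lifelines and an exhaustive hypergeometric oracle.

Monte-Carlo standard errors are `√(p(1−p)/reps)` for rates; the
proportion-best uses the empirical standard error across replicates.

## Problem sizes and reproducibility

Default study sizes follow the two simulation studies (continuous:
`N ∈ {40, 80, 120}`, burn-in 10; survival: `N ∈ {40, 80, 233}`).  The
shipped test battery and `scripts/acceptance.py` use 40–1000 replicates
per cell — sizes chosen so the whole battery runs in minutes on a single
CPU — with all tolerances expressed as exact values, stated constants, or
3 Monte-Carlo standard errors so they remain honest at any replication
count.  Larger runs (e.g. 10⁴ replicates) are available through the CLI.

Randomness: one root seed per run; replicate `i` uses
`SeedSequence(root, spawn_key=(i,))`, split further into named substreams
(biomarkers, outcomes, arrivals, censoring, allocation, learner seeding).
Identical seed + configuration reproduces results bit-identically, and
any single replicate can be re-simulated in isolation.

## What the generator does and does not emulate

The synthetic scenarios reproduce the *statistical structure* of the two
studies — biomarker laws, mean/hazard patterns, heteroscedasticity,
staggered arrivals, dropout and administrative censoring — not real
patient data.  Passing tests therefore demonstrate the design's behaviour
under correctly specified generative models: exponential survival with
exactly two relevant binary biomarkers, independent arrivals, and
non-informative dropout.  They do not speak to model misspecification,
time trends in enrollment, informative censoring, or biomarkers measured
with error.  Inference is the naive end-of-trial test; no correction for
the adaptive allocation (randomization tests, bias-adjusted estimators)
is attempted, and the null calibration results show the naive tests hold
their level under these generative models, not universally.

## Known limitations

* The continuous mean functions and learner hyperparameters are package
  choices satisfying the scenarios' qualitative structure; quantities
  that depend on their exact shapes (e.g. scenario-specific power values)
  are design-specific and should be read as properties of *these*
  choices.
* Survival learners are restricted to binary-coded biomarkers (4 cells);
  continuous-biomarker survival learners are not implemented.
* `K > 2` is supported by the engine but the shipped scenarios are all
  two-armed.
* Interim estimation treats censoring as non-informative; dropout is
  independent of the latent outcome by construction.
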