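# carasim

Simulation toolkit for a **biomarker-guided covariate-adjusted
response-adaptive randomization (CARA)** clinical-trial design, aimed at
trial statisticians studying rare-disease settings where most of the
patient population is *inside* the trial and ethical allocation matters as
much as power.

## The design

A trial with `K ≥ 2` arms enrolls `N` patients sequentially; patient `n`
presents a biomarker vector `x_n` at baseline.

1. **Burn-in** — the first `L × K` patients are randomized equally across
   arms (by default as a balanced block with exactly `L` per arm).
2. **Prediction** — for each later patient, a regression learner
   `f̂_k(x)` is refit per arm on all outcome information available at that
   moment, and the arm with the best predicted outcome at `x_n` is
   identified.
3. **Probabilistic assignment** — the estimated best arm is given with
   probability `1 − (K−1)·π_n`, every other arm with probability `π_n`,
   where `π_n` decreases linearly from `π_{LK} = 1/K` to `π_N = 0.1`.

Operating characteristics are estimated by Monte-Carlo against equal fixed
randomization (FR): the proportion of patients allocated to their
*individually* best arm, the performance ratio
`R(A) = Σ f_{I_j}(x_j) / Σ f_{k*(x_j)}(x_j)`, and type I error / power of
the end-of-trial analysis (Welch test for continuous outcomes, logrank for
survival), overall and within biomarker subgroups.

Two scenario families ship with the package:

* `s1`–`s6` — continuous outcomes, one continuous biomarker
  `x ~ U[−100, 100]`, heteroscedastic noise, covering null, prognostic,
  predictive and mixed biomarker effects.
* `cs1`–`cs4` — a two-arm survival case study (control vs. catumaxomab)
  with two binary biomarkers (relative lymphocyte count, Karnofsky index),
  exponential survival times, Poisson(5)-gap staggered arrivals, dropout,
  and administrative censoring 180 days after the last arrival.  Learners
  here are censoring-aware exponential regressions on the four biomarker
  cells.

## Worked example

```python
from carasim import TrialConfig, get_scenario, run_replicates, aggregate

spec = get_scenario("cs3")                    # RLC-predictive survival scenario
conf = TrialConfig(N=233, learner_family="cellwise")
results = run_replicates(spec, conf, replicates=200, seed=11)
oc = aggregate(results, spec)
print(f"proportion on best arm : {oc.proportion_best:.3f}")
print(f"proportion on arm 2    : {oc.proportion_on_arm['arm2']:.3f}")
print(f"two-sided logrank power: {oc.rejection_rates['two_sided[all]']['rate']:.3f}")
```

prints

```
proportion on best arm : 0.543
proportion on arm 2    : 0.651
two-sided logrank power: 0.920
```

i.e. the adaptive design sends ~65% of patients to the experimental arm
(which is better on average for everyone in this scenario) while retaining
>0.9 power; only ~55% of patients end up on their *individually* best arm
because with exponential outcomes the control draw frequently beats the
experimental draw even when the experimental mean is higher.

The same machinery is exposed on the command line:

```bash
carasim run --scenario s2 --learner gp --n 80 --reps 1000 --seed 7 --out results/
carasim sweep --scenarios cs1,cs2,cs3,cs4 --learners cellwise,polynomial \
              --sizes 40,80,233 --reps 1000 --out results/
carasim fixtures --scenario cs3 --learner cellwise --n 40 --out demo/
```

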