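"""Sequential CARA trial engine.

The design: an initial burn-in allocates ``L`` patients per arm by equal
randomization; afterwards, for each arriving patient the per-arm learners
are refit on the data available at that moment, the arm with the best
predicted outcome for the patient's biomarkers is identified, and the
patient receives that arm with probability ``1 - (K - 1) * pi_n`` (each
other arm with probability ``pi_n``), where ``pi_n`` decays linearly from
``pi_start`` at the end of burn-in to ``pi_end`` at the final patient.

Continuous outcomes are observed immediately; survival outcomes accrue in
calendar time, so each refit sees the interim-censored snapshot of the
data (dropout censoring plus not-yet-observed deaths).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import learners as L
from . import scenarios as sc

__all__ = [
    "Patient",
    "TrialConfig",
    "TrialResult",
    "pi_sequence",
    "assignment_probabilities",
    "burn_in_assign",
    "burn_in_sequence",
    "allocate_next",
    "run_trial",
]

#: learner_family values handled by the engine rather than by a fitted learner
SPECIAL_FAMILIES = ("fixed", "oracle")


@dataclass(frozen=True)
class TrialConfig:
    """Design parameters of one simulated trial."""

    N: int
    K: int = 2
    L: int = 5
    pi_start: float | None = None  # defaults to 1/K
    pi_end: float = 0.1
    learner_family: str = "polynomial"
    balanced_burn_in: bool = True
    alpha_one_sided: float = 0.025
    alpha_two_sided: float = 0.05
    alpha_one_sided_subgroup: float = 0.0125
    alpha_two_sided_subgroup: float = 0.025
    seed: int | None = None
    learner_kwargs: dict = field(default_factory=dict)
    gp_refit_every: int = 5

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("need at least two arms")
        if self.L < 1:
            raise ValueError("burn-in size per arm must be positive")
        if self.L * self.K >= self.N:
            raise ValueError("burn-in (L*K) must be smaller than the trial size N")
        if self.pi_start is None:
            object.__setattr__(self, "pi_start", 1.0 / self.K)
        if not 0.0 <= self.pi_end <= self.pi_start <= 1.0 / self.K + 1e-12:
            raise ValueError("need 0 <= pi_end <= pi_start <= 1/K")
        for a in (self.alpha_one_sided, self.alpha_two_sided,
                  self.alpha_one_sided_subgroup, self.alpha_two_sided_subgroup):
            if not 0.0 < a < 1.0:
                raise ValueError("significance levels must lie in (0, 1)")


@dataclass
class Patient:
    """One enrolled subject."""

    index: int                   # 1-based enrollment order
    biomarkers: np.ndarray
    arrival_day: int
    arm: int                     # 1-based
    latent_outcome: float
    observed_time: float | None = None   # survival setting only
    event: bool | None = None            # survival setting only
    pi: float | None = None


@dataclass
class TrialResult:
    """Complete allocation and outcome trajectory of one simulated trial.

    ``latent_all`` and ``mean_all`` hold each patient's latent outcome and
    true mean outcome under *every* arm (counterfactuals included), which
    the evaluation module uses to decide each patient's individually best
    treatment.
    """

    scenario_id: str
    learner_family: str
    seed: int | None
    setting: str
    config: TrialConfig
    biomarkers: np.ndarray       # (N, d)
    arrival_day: np.ndarray      # (N,) int
    arm: np.ndarray              # (N,) 1-based
    latent_all: np.ndarray       # (N, K)
    mean_all: np.ndarray         # (N, K)
    pi: np.ndarray               # (N,)
    observed_time: np.ndarray | None = None  # (N,) survival only
    event: np.ndarray | None = None          # (N,) bool, survival only
    dropout_day: np.ndarray | None = None    # (N,) inf = no dropout
    final_day: int | None = None

    @property
    def N(self) -> int:
        return len(self.arm)

    @property
    def latent_outcome(self) -> np.ndarray:
        """Latent outcome of the assigned arm."""
        return self.latent_all[np.arange(self.N), self.arm - 1]

    @property
    def observed_outcome(self) -> np.ndarray:
        """Outcome used for analysis: continuous outcomes are known
        immediately; survival outcomes are follow-up times at the
        administrative-censoring date."""
        if self.setting == "continuous":
            return self.latent_outcome
        return self.observed_time

    def best_arm_indicator(self, definition: str = "latent_draw") -> np.ndarray:
        """Whether each patient's assigned arm attains their best latent
        outcome (``latent_draw``) or best true mean (``latent_mean``)."""
        mat = {"latent_draw": self.latent_all, "latent_mean": self.mean_all}[definition]
        best = mat.max(axis=1)
        assigned = mat[np.arange(self.N), self.arm - 1]
        return assigned >= best - 1e-12

    @property
    def patients(self) -> list[Patient]:
        out = []
        for i in range(self.N):
            out.append(Patient(
                index=i + 1,
                biomarkers=self.biomarkers[i],
                arrival_day=int(self.arrival_day[i]),
                arm=int(self.arm[i]),
                latent_outcome=float(self.latent_outcome[i]),
                observed_time=None if self.observed_time is None
                else float(self.observed_time[i]),
                event=None if self.event is None else bool(self.event[i]),
                pi=float(self.pi[i]),
            ))
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per patient (the package's per-patient CSV schema)."""
        data = {"n": np.arange(1, self.N + 1), "arrival_day": self.arrival_day}
        for j in range(self.biomarkers.shape[1]):
            data[f"x{j + 1}"] = self.biomarkers[:, j]
        data["arm"] = self.arm
        data["latent_outcome"] = self.latent_outcome
        if self.setting == "survival":
            data["observed_time"] = self.observed_time
            data["event"] = self.event
        else:
            data["observed_time"] = np.full(self.N, np.nan)
            data["event"] = np.full(self.N, np.nan)
        data["best_arm"] = self.best_arm_indicator()
        data["pi_n"] = self.pi
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Design primitives
# ---------------------------------------------------------------------------

def pi_sequence(n: int, config: TrialConfig) -> float:
    """Linearly decaying non-best-arm probability at enrollment position n.

    Anchored at ``pi_start`` for the last burn-in patient (n = L*K) and at
    ``pi_end`` for the final patient (n = N).
    """
    lk = config.L * config.K
    if not lk <= n <= config.N:
        raise ValueError(f"pi_sequence defined for {lk} <= n <= {config.N}, got {n}")
    frac = (n - lk) / (config.N - lk)
    return config.pi_start + (config.pi_end - config.pi_start) * frac


def assignment_probabilities(best_arm: int, pi_n: float, K: int) -> np.ndarray:
    """Allocation probabilities: the estimated best arm gets
    ``1 - (K - 1) * pi_n``, every other arm ``pi_n``."""
    if not 1 <= best_arm <= K:
        raise ValueError("best_arm out of range")
    if not -1e-12 <= pi_n <= 1.0 / K + 1e-12:
        raise ValueError("pi_n must lie in [0, 1/K]")
    pi_n = min(max(pi_n, 0.0), 1.0 / K)
    p = np.full(K, pi_n)
    p[best_arm - 1] = 1.0 - (K - 1) * pi_n
    return p


def burn_in_assign(n: int, K: int, rng: np.random.Generator,
                   L: int | None = None) -> int:
    """Equal-probability (Bernoulli) burn-in assignment for patient n."""
    if L is not None and n > L * K:
        raise ValueError("patient beyond the burn-in phase")
    return int(rng.integers(1, K + 1))


def burn_in_sequence(L: int, K: int, rng: np.random.Generator,
                     balanced: bool = True) -> np.ndarray:
    """Arms for the L*K burn-in patients.

    Balanced mode (default) randomizes the order of a block with exactly L
    patients per arm, guaranteeing every arm L observations before the
    first model fit; Bernoulli mode draws each arm independently.
    """
    if balanced:
        return rng.permutation(np.repeat(np.arange(1, K + 1), L))
    return rng.integers(1, K + 1, size=L * K)


def _argmax_with_ties(values: np.ndarray, rng: np.random.Generator) -> int:
    """1-based argmax, ties broken uniformly at random."""
    values = np.asarray(values, dtype=float)
    top = np.flatnonzero(values >= values.max() - 1e-12)
    return int(top[rng.integers(len(top))]) + 1 if len(top) > 1 else int(top[0]) + 1


def allocate_next(x, predictors: Sequence, pi_n: float,
                  rng: np.random.Generator) -> tuple[int, int, np.ndarray]:
    """Predict each arm's outcome at ``x``, pick the argmax (random
    tie-break), and sample the assigned arm.

    Returns ``(assigned arm, estimated best arm, predictions)``.
    """
    preds = np.array([p.predict(x) for p in predictors], dtype=float)
    if not np.all(np.isfinite(preds)):
        raise RuntimeError("non-finite learner prediction")
    best = _argmax_with_ties(preds, rng)
    probs = assignment_probabilities(best, pi_n, len(predictors))
    arm = int(rng.choice(len(predictors), p=probs)) + 1
    return arm, best, preds


# ---------------------------------------------------------------------------
# Trial execution
# ---------------------------------------------------------------------------

def _streams(seed) -> dict[str, np.random.Generator]:
    """Independent substreams so the simulated patient population is
    identical across allocation rules sharing a root seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = ("biomarker", "outcome", "arrival", "censor", "alloc", "learner")
    return {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(names, ss.spawn(len(names)))}


def run_trial(scenario: sc.ScenarioSpec, config: TrialConfig,
              seed=None) -> TrialResult:
    """Simulate one complete trial under the given scenario and design."""
    if seed is None:
        seed = config.seed
    rngs = _streams(seed)
    N, K, lk = config.N, config.K, config.L * config.K
    fam = config.learner_family
    if scenario.setting == "survival" and fam == "random_forest":
        raise ValueError("random forest is not supported in the survival setting")

    x = np.atleast_2d(sc.draw_biomarker(scenario, rngs["biomarker"], size=N))
    mean_all = np.column_stack(
        [np.asarray(sc.mean_outcome(scenario, k + 1, x)) for k in range(K)])

    if scenario.setting == "continuous":
        sd_all = np.column_stack(
            [np.asarray(sc.noise_sd(scenario, k + 1, x)) for k in range(K)])
        latent_all = mean_all + sd_all * rngs["outcome"].standard_normal((N, K))
        arrival = np.zeros(N, dtype=int)
        dropout_day = None
    else:
        u = rngs["outcome"].random((N, K))
        latent_all = np.maximum(np.ceil(-mean_all * np.log(u)), 1.0)
        arrival = sc.draw_arrivals(N, rngs["arrival"], scenario.arrival_mean_gap)
        v = rngs["censor"].random(N)
        w = rngs["censor"].random(N)
        probs = np.asarray(scenario.dropout_probs)
        is_dropout = v[:, None] < probs[None, :]                   # (N, K)
        d_times = np.floor(w[:, None] * latent_all) + 1.0          # uniform on 1..T
        dropout_all = np.where(is_dropout, np.minimum(d_times, latent_all), np.inf)

    arm = np.zeros(N, dtype=int)
    pi = np.full(N, 1.0 / K)
    arm[:lk] = burn_in_sequence(config.L, K, rngs["alloc"], config.balanced_burn_in)

    fitter = None
    if fam not in SPECIAL_FAMILIES:
        learner_seed = int(rngs["learner"].integers(2**31))
        fitter = L.make_learner(fam, scenario.setting, seed=learner_seed,
                                **config.learner_kwargs)
    gp_cache: dict[int, tuple] = {}  # arm -> (fitted kernel, n_obs at last hyperfit)

    def fit_arm(k: int, xs, *ys) -> L.FittedPredictor:
        if len(xs) == 0:
            raise RuntimeError(
                f"arm {k + 1} has no usable observations at an allocation step; "
                "increase the burn-in or use balanced burn-in")
        if fam == "gp" and scenario.setting == "continuous":
            cached = gp_cache.get(k)
            if cached is not None and len(xs) - cached[1] < config.gp_refit_every:
                return fitter(xs, *ys, fixed_kernel=cached[0])
            fp = fitter(xs, *ys)
            gp_cache[k] = (fp.state.kernel_, len(xs))
            return fp
        return fitter(xs, *ys)

    assigned_latent = None
    if scenario.setting == "survival":
        assigned_latent = np.zeros(N)
        assigned_dropout = np.zeros(N)
        assigned_latent[:lk] = latent_all[np.arange(lk), arm[:lk] - 1]
        assigned_dropout[:lk] = dropout_all[np.arange(lk), arm[:lk] - 1]

    for i in range(lk, N):
        pi_i = pi_sequence(i + 1, config)
        if fam == "fixed":
            pi[i] = 1.0 / K
            arm[i] = int(rngs["alloc"].integers(1, K + 1))
        else:
            pi[i] = pi_i
            if fam == "oracle":
                best = _argmax_with_ties(mean_all[i], rngs["alloc"])
                p = assignment_probabilities(best, pi_i, K)
                arm[i] = int(rngs["alloc"].choice(K, p=p)) + 1
            else:
                if scenario.setting == "continuous":
                    y_obs = latent_all[np.arange(i), arm[:i] - 1]
                    predictors = [
                        fit_arm(k, x[:i][arm[:i] == k + 1],
                                y_obs[arm[:i] == k + 1])
                        for k in range(K)
                    ]
                else:
                    view = sc.interim_view(
                        x[:i], arm[:i], arrival[:i], assigned_latent[:i],
                        assigned_dropout[:i], current_day=int(arrival[i]))
                    predictors = [
                        fit_arm(k, view.biomarkers[view.arms == k + 1],
                                view.observed[view.arms == k + 1],
                                view.events[view.arms == k + 1])
                        for k in range(K)
                    ]
                arm[i], _, _ = allocate_next(x[i], predictors, pi_i, rngs["alloc"])
        if scenario.setting == "survival":
            assigned_latent[i] = latent_all[i, arm[i] - 1]
            assigned_dropout[i] = dropout_all[i, arm[i] - 1]

    result = TrialResult(
        scenario_id=scenario.id, learner_family=fam,
        seed=seed if isinstance(seed, int) else None,
        setting=scenario.setting, config=config,
        biomarkers=x, arrival_day=arrival, arm=arm,
        latent_all=latent_all, mean_all=mean_all, pi=pi,
    )
    if scenario.setting == "survival":
        final_day = int(arrival[-1] + scenario.followup_days)
        # Dropout censoring first (a dropout is censored even if their
        # censoring day ties with the death day), then the administrative
        # cut-off.
        events = assigned_latent < assigned_dropout
        observed = np.minimum(assigned_latent, assigned_dropout)
        observed, events = sc.administrative_censor(arrival, observed, events, final_day)
        result.observed_time = observed
        result.event = events
        result.dropout_day = assigned_dropout
        result.final_day = final_day
    return result
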