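"""Synthetic trial scenarios: outcome models, biomarkers, arrivals and censoring.

Two families of scenarios are provided:

* ``s1``–``s6`` — continuous outcomes.  A single continuous biomarker
  ``x ~ Uniform[-100, 100]`` and per-arm mean functions ``f_k(x)`` with
  heteroscedastic Gaussian noise whose standard deviation is proportional
  to the magnitude of the mean outcome, ``sigma_k(x) = c * |f_k(x)|``.
  For an arm whose mean function does not depend on the biomarker, the
  noise level is frozen at the other arm's noise level evaluated at the
  crossing point, so a flat arm is not artificially easy to estimate.

* ``cs1``–``cs4`` — survival outcomes emulating a two-arm cancer trial
  (control vs. catumaxomab).  Two independent binary biomarkers, coded
  on levels {1, 2}: relative lymphocyte count (RLC > 13% -> 2) with
  prevalence 0.6824, and Karnofsky index (KI >= 70% -> 2) with
  prevalence 0.8584.  Overall survival is exponential with per-cell
  means (days); patients arrive with Poisson(5) inter-arrival gaps, may
  drop out (uniform censoring over their latent survival time), and are
  administratively censored 180 days after the last arrival.

All times are integer days >= 1 (exponential draws are rounded up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "ScenarioSpec",
    "InterimView",
    "get_scenario",
    "CONTINUOUS_IDS",
    "SURVIVAL_IDS",
    "draw_biomarker",
    "mean_outcome",
    "noise_sd",
    "draw_continuous_outcome",
    "draw_survival_outcome",
    "draw_arrivals",
    "dropout_indicator",
    "apply_dropout",
    "administrative_censor",
    "interim_view",
    "hr_to_mean",
    "median_to_mean_exponential",
]

# Case-study constants
RLC_PREVALENCE = 0.6824  # P(RLC > 13%), biomarker 1 coded 2
KI_PREVALENCE = 0.8584   # P(KI >= 70%), biomarker 2 coded 2
CONTROL_MEAN_DAYS = 98.0  # exponential mean implied by median OS of 68 days
ARRIVAL_MEAN_GAP = 5.0
FOLLOWUP_DAYS = 180


def median_to_mean_exponential(median: float) -> float:
    """Mean of an exponential distribution with the given median (median / ln 2)."""
    if median <= 0:
        raise ValueError("median must be positive")
    return median / math.log(2.0)


def hr_to_mean(control_mean: float, hazard_ratio: float) -> float:
    """Exponential mean implied by a hazard ratio against a control mean.

    Exponential hazards are reciprocal means, so HR = mean_control / mean_treated
    and the treated mean is ``control_mean / hazard_ratio``.
    """
    if control_mean <= 0 or hazard_ratio <= 0:
        raise ValueError("control_mean and hazard_ratio must be positive")
    return control_mean / hazard_ratio


@dataclass(frozen=True)
class ScenarioSpec:
    """Full generative description of one simulated trial scenario.

    For continuous scenarios ``mean_fns`` holds one vectorized ``f_k(x)``
    per arm and ``noise_scale`` the proportionality constant ``c``.  For
    survival scenarios ``cell_means[k]`` is a (2, 2) array of exponential
    means indexed by the zero-based biomarker codes ``(x1-1, x2-1)``.
    ``crossing`` is the biomarker value where the identity of the better
    arm changes (None when one arm is uniformly best or under the null).
    """

    id: str
    setting: str  # "continuous" | "survival"
    n_arms: int = 2
    mean_fns: tuple[Callable, ...] | None = None
    noise_scale: float = 0.1
    flat_arm_sd: tuple[float | None, ...] | None = None  # frozen sd per arm, or None
    crossing: float | None = None
    cell_means: tuple[np.ndarray, ...] | None = None
    dropout_probs: tuple[float, ...] | None = None
    biomarker_prevalences: tuple[float, ...] = (RLC_PREVALENCE, KI_PREVALENCE)
    followup_days: int = FOLLOWUP_DAYS
    arrival_mean_gap: float = ARRIVAL_MEAN_GAP

    @property
    def n_biomarkers(self) -> int:
        return 1 if self.setting == "continuous" else len(self.biomarker_prevalences)

    def with_noise_scale(self, c: float) -> "ScenarioSpec":
        spec = replace(self, noise_scale=c)
        if self.flat_arm_sd is not None:
            scaled = tuple(
                None if s is None else s * c / self.noise_scale for s in self.flat_arm_sd
            )
            spec = replace(spec, flat_arm_sd=scaled)
        return spec


# ---------------------------------------------------------------------------
# Continuous scenarios (single biomarker on [-100, 100])
# ---------------------------------------------------------------------------

def _s2_f1(x):
    return 10.0 + 0.05 * np.asarray(x, dtype=float)


def _s2_f2(x):
    return 13.0 + 0.05 * np.asarray(x, dtype=float)


def _s3_f2(x):
    return 10.0 - 0.25 * (np.asarray(x, dtype=float) + 8.0)


def _s4_f1(x):
    return 10.0 + 0.06 * np.asarray(x, dtype=float)


def _s4_f2(x):
    return 10.11 + 0.07 * np.asarray(x, dtype=float)


def _s5_f2(x):
    return 10.0 + 0.06 * (np.asarray(x, dtype=float) + 8.0)


def _s6_f2(x):
    # Step function: jumps across the crossing at x = -8 (right-continuous).
    return np.where(np.asarray(x, dtype=float) < -8.0, 16.0, 9.0)


def _const(value: float) -> Callable:
    def f(x):
        return np.full_like(np.asarray(x, dtype=float), value)

    return f


def _continuous_catalogue(c: float) -> dict[str, ScenarioSpec]:
    # Flat-arm noise freeze: sd = c * |f_other(X)| at the crossing point.
    return {
        "s1": ScenarioSpec(
            id="s1", setting="continuous", mean_fns=(_const(10.0), _const(10.0)),
            noise_scale=c, crossing=None,
        ),
        "s2": ScenarioSpec(
            id="s2", setting="continuous", mean_fns=(_s2_f1, _s2_f2),
            noise_scale=c, crossing=None,
        ),
        "s3": ScenarioSpec(
            id="s3", setting="continuous", mean_fns=(_const(10.0), _s3_f2),
            noise_scale=c, crossing=-8.0,
            flat_arm_sd=(c * abs(float(_s3_f2(-8.0))), None),
        ),
        "s4": ScenarioSpec(
            id="s4", setting="continuous", mean_fns=(_s4_f1, _s4_f2),
            noise_scale=c, crossing=-11.0,
        ),
        "s5": ScenarioSpec(
            id="s5", setting="continuous", mean_fns=(_const(10.0), _s5_f2),
            noise_scale=c, crossing=-8.0,
            flat_arm_sd=(c * abs(float(_s5_f2(-8.0))), None),
        ),
        "s6": ScenarioSpec(
            id="s6", setting="continuous", mean_fns=(_const(10.0), _s6_f2),
            noise_scale=c, crossing=-8.0,
            flat_arm_sd=(c * abs(float(_s6_f2(-8.0))), None),
        ),
    }


# ---------------------------------------------------------------------------
# Survival case-study scenarios (two binary biomarkers)
# ---------------------------------------------------------------------------

def _cells(m11: float, m12: float, m21: float, m22: float) -> np.ndarray:
    """(2,2) cell-mean array indexed by zero-based (x1-1, x2-1)."""
    return np.array([[m11, m12], [m21, m22]], dtype=float)


def _survival_catalogue() -> dict[str, ScenarioSpec]:
    ctrl = _cells(98.0, 98.0, 98.0, 98.0)
    # cs3: RLC predictive, KI inert; treated means from HR 0.695 / 0.518.
    cs3_trt = _cells(141.0, 141.0, 189.0, 189.0)
    # cs4: both predictive; the doubly favourable cell has the best outcome.
    cs4_trt = _cells(90.0, 160.0, 170.0, 200.0)
    common = dict(setting="survival")
    return {
        "cs1": ScenarioSpec(id="cs1", cell_means=(ctrl, ctrl),
                            dropout_probs=(0.20, 0.20), **common),
        "cs2": ScenarioSpec(id="cs2", cell_means=(ctrl, ctrl),
                            dropout_probs=(0.20, 0.08), **common),
        "cs3": ScenarioSpec(id="cs3", cell_means=(ctrl, cs3_trt),
                            dropout_probs=(0.20, 0.08), **common),
        "cs4": ScenarioSpec(id="cs4", cell_means=(ctrl, cs4_trt),
                            dropout_probs=(0.20, 0.08), **common),
    }


CONTINUOUS_IDS = ("s1", "s2", "s3", "s4", "s5", "s6")
SURVIVAL_IDS = ("cs1", "cs2", "cs3", "cs4")


def get_scenario(scenario_id: str, noise_scale: float = 0.1) -> ScenarioSpec:
    """Look up a scenario by id (``s1``–``s6`` or ``cs1``–``cs4``)."""
    if scenario_id in CONTINUOUS_IDS:
        return _continuous_catalogue(noise_scale)[scenario_id]
    if scenario_id in SURVIVAL_IDS:
        return _survival_catalogue()[scenario_id]
    raise KeyError(f"unknown scenario id: {scenario_id!r}")


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------

def draw_biomarker(spec: ScenarioSpec, rng: np.random.Generator, size: int | None = None):
    """Draw biomarker vectors for one patient (``size=None``) or ``size`` patients."""
    n = 1 if size is None else size
    if spec.setting == "continuous":
        x = rng.uniform(-100.0, 100.0, size=n)[:, None]
    else:
        p = np.asarray(spec.biomarker_prevalences)
        x = 1 + (rng.random((n, len(p))) < p).astype(float)
    return x[0] if size is None else x


def mean_outcome(spec: ScenarioSpec, arm: int, x) -> np.ndarray | float:
    """True mean outcome ``f_k(x)`` (continuous) or the cell's exponential mean."""
    if not 1 <= arm <= spec.n_arms:
        raise ValueError(f"arm must be in 1..{spec.n_arms}")
    xa = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.setting == "continuous":
        out = spec.mean_fns[arm - 1](xa[:, 0])
    else:
        i = xa[:, 0].astype(int) - 1
        j = xa[:, 1].astype(int) - 1
        out = spec.cell_means[arm - 1][i, j]
    out = np.asarray(out, dtype=float)
    return float(out[0]) if np.asarray(x).ndim <= 1 else out


def noise_sd(spec: ScenarioSpec, arm: int, x) -> np.ndarray | float:
    """Heteroscedastic noise sd for a continuous scenario: ``c * |f_k(x)|``,
    frozen for flat arms at the other arm's sd at the crossing point."""
    if spec.setting != "continuous":
        raise ValueError("noise_sd is defined for continuous scenarios only")
    frozen = None if spec.flat_arm_sd is None else spec.flat_arm_sd[arm - 1]
    n_rows = np.atleast_2d(np.asarray(x, dtype=float)).shape[0]
    if frozen is not None:
        out = np.full(n_rows, frozen)
    else:
        out = spec.noise_scale * np.abs(
            np.atleast_1d(np.asarray(mean_outcome(spec, arm, np.atleast_2d(x))))
        )
    return float(out[0]) if np.asarray(x).ndim <= 1 else out


def draw_continuous_outcome(spec: ScenarioSpec, arm: int, x, rng: np.random.Generator):
    """One outcome ``f_k(x) + eps`` with ``eps ~ N(0, sigma_k(x)^2)``."""
    f = mean_outcome(spec, arm, x)
    if not np.all(np.isfinite(f)):
        raise ValueError("mean outcome is not finite")
    s = noise_sd(spec, arm, x)
    return f + s * rng.standard_normal(np.shape(f) if np.ndim(f) else None)


def _exp_to_days(mean: np.ndarray | float, u: np.ndarray | float):
    """Invert the exponential CDF at uniform ``u`` and round up to integer days."""
    t = np.ceil(-np.asarray(mean, dtype=float) * np.log(u))
    return np.maximum(t, 1.0)


def draw_survival_outcome(spec: ScenarioSpec, arm: int, x, rng: np.random.Generator):
    """Integer survival days drawn from the cell's exponential distribution."""
    m = mean_outcome(spec, arm, x)
    u = rng.random(np.shape(m) if np.ndim(m) else None)
    t = _exp_to_days(m, u)
    return float(t) if np.ndim(t) == 0 else t


def draw_arrivals(n_patients: int, rng: np.random.Generator,
                  mean_gap: float = ARRIVAL_MEAN_GAP) -> np.ndarray:
    """Arrival days: first patient at day 0, then i.i.d. Poisson(mean_gap) gaps."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    gaps = rng.poisson(mean_gap, size=n_patients)
    gaps[0] = 0
    return np.cumsum(gaps)


def dropout_indicator(spec: ScenarioSpec, arm: int, rng: np.random.Generator) -> bool:
    """Bernoulli dropout flag with the scenario's per-arm probability."""
    if spec.dropout_probs is None:
        raise ValueError("scenario has no dropout model")
    return bool(rng.random() < spec.dropout_probs[arm - 1])


def apply_dropout(latent_os: int, is_dropout: bool,
                  rng: np.random.Generator) -> tuple[int, bool]:
    """Observed time and event flag after (possible) dropout censoring.

    A dropout's censored time is uniform on the integers ``1..latent_os``;
    a non-dropout dies at the latent time (subject to later administrative
    censoring).
    """
    if latent_os < 1:
        raise ValueError("latent_os must be >= 1")
    if not is_dropout:
        return int(latent_os), True
    return int(rng.integers(1, latent_os + 1)), False


def administrative_censor(arrival_days: np.ndarray, observed: np.ndarray,
                          events: np.ndarray, final_day: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Censor any follow-up extending beyond the trial's final day."""
    arrival_days = np.asarray(arrival_days)
    observed = np.asarray(observed, dtype=float).copy()
    events = np.asarray(events, dtype=bool).copy()
    over = arrival_days + observed > final_day
    observed[over] = final_day - arrival_days[over]
    events[over] = False
    return observed, events


@dataclass
class InterimView:
    """The censored snapshot of the data available at a given calendar day."""

    biomarkers: np.ndarray   # (m, n_biomarkers)
    arms: np.ndarray         # (m,) 1-based
    observed: np.ndarray     # (m,) days observed so far
    events: np.ndarray       # (m,) bool
    current_day: int


def interim_view(biomarkers: np.ndarray, arms: np.ndarray, arrival_days: np.ndarray,
                 latent_os: np.ndarray, dropout_days: np.ndarray,
                 current_day: int) -> InterimView:
    """Interim (calendar-time) view of enrolled patients' survival data.

    ``dropout_days`` holds each patient's dropout-censoring day on their own
    time scale, ``inf`` for non-dropouts.  A patient counts as an event only
    if their death day precedes both the current calendar day and their
    dropout day; otherwise they are censored at the earlier of follow-up so
    far and dropout.
    """
    arrival_days = np.asarray(arrival_days)
    if np.any(arrival_days > current_day):
        raise ValueError("current_day precedes an included arrival")
    latent_os = np.asarray(latent_os, dtype=float)
    dropout_days = np.asarray(dropout_days, dtype=float)
    avail = (current_day - arrival_days).astype(float)
    # Strict inequality against the dropout day: a dropout is censored even
    # when the censoring day coincides with the (unobserved) death day.
    events = (latent_os <= avail) & (latent_os < dropout_days)
    observed = np.where(events, latent_os, np.minimum(avail, dropout_days))
    return InterimView(
        biomarkers=np.asarray(biomarkers, dtype=float),
        arms=np.asarray(arms, dtype=int),
        observed=observed,
        events=events,
        current_day=int(current_day),
    )
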