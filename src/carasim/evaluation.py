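"""Operating characteristics: ethical allocation measures, hypothesis
tests, and replicate-level aggregation.

The ethical measures are the proportion of patients allocated to their
individually best treatment and the performance ratio R(A): the total
achieved mean outcome divided by the total under the oracle rule that
gives every patient their best arm.  "Individually best" defaults to the
arm with the larger *latent outcome draw* for that patient (counterfactual
draws are simulated for every arm), so under a null scenario it is a coin
flip even for a perfect learner; the latent-*mean* definition is also
available.

Inference: continuous outcomes are compared between arms with a Welch
two-sample test (the generative noise is heteroscedastic by construction;
a pooled-variance Student test is available), overall and within biomarker
subgroups.  Survival outcomes are compared with the logrank test at the
administrative-censoring date.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import scenarios as sc
from .trial import TrialResult

__all__ = [
    "TestSpec",
    "OperatingCharacteristics",
    "proportion_best",
    "proportion_on_arm",
    "performance_ratio",
    "continuous_endpoint_test",
    "logrank_test",
    "LogrankResult",
    "default_test_specs",
    "aggregate",
]


# ---------------------------------------------------------------------------
# Ethical measures
# ---------------------------------------------------------------------------

def proportion_best(result: TrialResult, definition: str = "latent_draw") -> float:
    """Fraction of patients whose assigned arm attains their best latent
    outcome (default) or best latent mean."""
    return float(result.best_arm_indicator(definition).mean())


def proportion_on_arm(result: TrialResult, arm: int) -> float:
    """Fraction of patients allocated to the given (1-based) arm."""
    return float(np.mean(result.arm == arm))


def performance_ratio(result: TrialResult, scenario: sc.ScenarioSpec) -> float:
    """R(A): achieved total mean outcome over the oracle policy's total."""
    achieved = result.mean_all[np.arange(result.N), result.arm - 1].sum()
    optimal = result.mean_all.max(axis=1).sum()
    if optimal == 0:
        raise ZeroDivisionError("oracle total mean outcome is zero")
    return float(achieved / optimal)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestSpec:
    """One hypothesis test: sidedness, analysis subgroup, nominal level.

    Subgroups restrict the analysis population by the first biomarker:
    ``all``, ``x>=0`` / ``x<0`` (prior guess that the better arm changes
    at zero), or ``x>=X`` / ``x<X`` (the scenario's true crossing point).
    """

    sidedness: str = "two"        # "one" | "two"
    subgroup: str = "all"         # "all" | "x>=0" | "x<0" | "x>=X" | "x<X"
    level: float = 0.05

    def __post_init__(self):
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")
        if self.subgroup not in ("all", "x>=0", "x<0", "x>=X", "x<X"):
            raise ValueError(f"unknown subgroup rule: {self.subgroup!r}")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")

    @property
    def name(self) -> str:
        return f"{self.sidedness}_sided[{self.subgroup}]"

    def mask(self, result: TrialResult, scenario: sc.ScenarioSpec) -> np.ndarray:
        x1 = result.biomarkers[:, 0]
        if self.subgroup == "all":
            return np.ones(result.N, dtype=bool)
        if self.subgroup in ("x>=X", "x<X"):
            if scenario.crossing is None:
                raise ValueError(
                    f"subgroup {self.subgroup!r} needs a scenario with a crossing point")
            cut = scenario.crossing
            return x1 >= cut if self.subgroup == "x>=X" else x1 < cut
        return x1 >= 0 if self.subgroup == "x>=0" else x1 < 0


def continuous_endpoint_test(result: TrialResult, spec: TestSpec,
                             scenario: sc.ScenarioSpec,
                             equal_var: bool = False) -> tuple[bool, float]:
    """Two-sample comparison of observed outcomes between arms 1 (control)
    and 2 (experimental) inside the spec's subgroup.

    Welch's unequal-variance statistic by default.  One-sided alternative:
    the experimental mean is greater.  A subgroup leaving either arm empty
    (or a single observation, so no variance estimate) counts as a
    non-rejection with a warning.
    """
    mask = spec.mask(result, scenario)
    y = result.observed_outcome
    y1 = y[mask & (result.arm == 1)]
    y2 = y[mask & (result.arm == 2)]
    if len(y1) < 2 or len(y2) < 2:
        warnings.warn(f"subgroup {spec.subgroup!r} leaves an arm (nearly) empty; "
                      "counted as non-rejection")
        return False, 1.0
    alternative = "greater" if spec.sidedness == "one" else "two-sided"
    res = stats.ttest_ind(y2, y1, equal_var=equal_var, alternative=alternative)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both arms
        return False, 1.0
    return p < spec.level, p


@dataclass
class LogrankResult:
    """Logrank comparison of two survival curves."""

    z: float            # signed (observed - expected) / sqrt(var) for group 2
    chi_sq: float
    p_two_sided: float
    p_one_sided: float  # alternative: group 2 (experimental) survives longer
    n_events: int


def logrank_test(times, events, arms, sidedness: str = "two",
                 level: float = 0.05) -> tuple[bool, float, LogrankResult]:
    """Standard logrank test between arms 1 and 2.

    At each distinct event time the observed events in arm 2 are compared
    with their hypergeometric expectation given the risk sets, with the
    usual multi-death (tie) variance correction.  Two-sided p from the
    chi-square with 1 df; one-sided from the signed normal deviate (the
    alternative being that the experimental arm survives longer, i.e.
    fewer events than expected).  Returns (reject, p, details).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    arms = np.asarray(arms, dtype=int)
    n_events = int(events.sum())
    if n_events == 0:
        warnings.warn("no events observed; logrank test counted as non-rejection")
        res = LogrankResult(0.0, 0.0, 1.0, 1.0, 0)
        return False, 1.0, res

    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        n2_j = (at_risk & (arms == 2)).sum()
        dying = events & (times == t)
        d_j = dying.sum()
        d2_j = (dying & (arms == 2)).sum()
        o_minus_e += d2_j - d_j * n2_j / n_j
        if n_j > 1:
            var += d_j * (n2_j / n_j) * (1 - n2_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var <= 0:
        res = LogrankResult(0.0, 0.0, 1.0, 1.0, n_events)
        return False, 1.0, res
    z = o_minus_e / math.sqrt(var)
    chi_sq = z * z
    p_two = float(stats.chi2.sf(chi_sq, df=1))
    p_one = float(stats.norm.cdf(z))  # fewer events in arm 2 => z < 0
    res = LogrankResult(float(z), float(chi_sq), p_two, p_one, n_events)
    p = p_two if sidedness == "two" else p_one
    return p < level, p, res


def _survival_test(result: TrialResult, spec: TestSpec) -> tuple[bool, float]:
    reject, p, _ = logrank_test(result.observed_time, result.event, result.arm,
                                sidedness=spec.sidedness, level=spec.level)
    return reject, p


def run_test(result: TrialResult, spec: TestSpec, scenario: sc.ScenarioSpec,
             equal_var: bool = False) -> tuple[bool, float]:
    """Dispatch one TestSpec against one trial's final data."""
    if result.setting == "continuous":
        return continuous_endpoint_test(result, spec, scenario, equal_var=equal_var)
    if spec.subgroup != "all":
        raise ValueError("survival analysis supports the overall population only")
    return _survival_test(result, spec)


def default_test_specs(config, scenario: sc.ScenarioSpec) -> list[TestSpec]:
    """The design's standard battery: overall one- and two-sided tests,
    plus the four biomarker-subgroup splits for continuous scenarios
    (X-splits only when the scenario declares a crossing point)."""
    specs = [
        TestSpec("one", "all", config.alpha_one_sided),
        TestSpec("two", "all", config.alpha_two_sided),
    ]
    if scenario.setting == "continuous":
        for sub in ("x>=0", "x<0"):
            specs.append(TestSpec("one", sub, config.alpha_one_sided_subgroup))
            specs.append(TestSpec("two", sub, config.alpha_two_sided_subgroup))
        if scenario.crossing is not None:
            for sub in ("x>=X", "x<X"):
                specs.append(TestSpec("one", sub, config.alpha_one_sided_subgroup))
                specs.append(TestSpec("two", sub, config.alpha_two_sided_subgroup))
    return specs


# ---------------------------------------------------------------------------
# Aggregation over replicates
# ---------------------------------------------------------------------------

def _mc_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)


@dataclass
class OperatingCharacteristics:
    """Replicate-aggregated design metrics with Monte-Carlo errors."""

    scenario_id: str
    learner_family: str
    N: int
    replicates: int
    proportion_best: float
    proportion_best_se: float
    proportion_best_definition: str
    proportion_on_arm: dict[str, float]
    performance_ratio: float
    rejection_rates: dict[str, dict]   # spec name -> {rate, mc_se, level, sidedness, subgroup}
    is_null_scenario: bool

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, **extra) -> str:
        payload = {**self.to_dict(), **extra}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "OperatingCharacteristics":
        with open(path) as fh:
            payload = json.load(fh)
        fields_ = cls.__dataclass_fields__
        return cls(**{k: v for k, v in payload.items() if k in fields_})

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-metric table for plotting or sweeps."""
        rows = [
            dict(metric="proportion_best", value=self.proportion_best,
                 mc_se=self.proportion_best_se, level=np.nan, test=""),
            dict(metric="performance_ratio", value=self.performance_ratio,
                 mc_se=np.nan, level=np.nan, test=""),
        ]
        for name, p in self.proportion_on_arm.items():
            rows.append(dict(metric=f"proportion_on_{name}", value=p,
                             mc_se=_mc_se(p, self.replicates), level=np.nan, test=""))
        kind = "type_i_error" if self.is_null_scenario else "power"
        for name, rec in self.rejection_rates.items():
            rows.append(dict(metric=kind, value=rec["rate"], mc_se=rec["mc_se"],
                             level=rec["level"], test=name))
        df = pd.DataFrame(rows)
        df.insert(0, "scenario", self.scenario_id)
        df.insert(1, "learner", self.learner_family)
        df.insert(2, "N", self.N)
        df.insert(3, "replicates", self.replicates)
        return df


def is_null(scenario: sc.ScenarioSpec) -> bool:
    """Whether the scenario's two arms share identical mean-outcome models."""
    if scenario.setting == "survival":
        return bool(np.array_equal(scenario.cell_means[0], scenario.cell_means[1]))
    grid = np.linspace(-100.0, 100.0, 2001)[:, None]
    f1 = np.asarray(sc.mean_outcome(scenario, 1, grid))
    f2 = np.asarray(sc.mean_outcome(scenario, 2, grid))
    return bool(np.allclose(f1, f2))


def aggregate(results: list[TrialResult], scenario: sc.ScenarioSpec,
              specs: list[TestSpec] | None = None,
              definition: str = "latent_draw",
              equal_var: bool = False) -> OperatingCharacteristics:
    """Aggregate per-trial metrics and rejection rates over replicates."""
    if not results:
        raise ValueError("no trial results to aggregate")
    first = results[0]
    if any(r.scenario_id != first.scenario_id or r.N != first.N
           or r.learner_family != first.learner_family for r in results):
        raise ValueError("results mix scenarios, learners, or trial sizes")
    if specs is None:
        specs = default_test_specs(first.config, scenario)

    reps = len(results)
    pb = np.array([proportion_best(r, definition) for r in results])
    ratio = np.array([performance_ratio(r, scenario) for r in results])
    on_arm = {
        f"arm{k}": float(np.mean([proportion_on_arm(r, k) for r in results]))
        for k in range(1, first.config.K + 1)
    }
    rejections: dict[str, dict] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for spec in specs:
            rej = np.array([run_test(r, spec, scenario, equal_var=equal_var)[0]
                            for r in results])
            rate = float(rej.mean())
            rejections[spec.name] = dict(
                rate=rate, mc_se=_mc_se(rate, reps), level=spec.level,
                sidedness=spec.sidedness, subgroup=spec.subgroup)
    return OperatingCharacteristics(
        scenario_id=first.scenario_id,
        learner_family=first.learner_family,
        N=first.N,
        replicates=reps,
        proportion_best=float(pb.mean()),
        proportion_best_se=float(pb.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0,
        proportion_best_definition=definition,
        proportion_on_arm=on_arm,
        performance_ratio=float(ratio.mean()),
        rejection_rates=rejections,
        is_null_scenario=is_null(scenario),
    )
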