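"""Replication driver and result I/O.

``run_replicates`` simulates independent trials from one root seed (each
replicate gets its own spawned substream, so any single replicate can be
re-simulated in isolation and execution order is irrelevant);
``run_command`` / ``sweep_command`` wrap it with configuration validation
and on-disk artifacts (operating-characteristics JSON plus a tidy CSV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import evaluation as ev
from . import scenarios as sc
from .trial import TrialConfig, TrialResult, run_trial

__all__ = ["RunConfig", "run_replicates", "run_command", "sweep_command",
           "replicate_seed"]


@dataclass
class RunConfig:
    """User-facing configuration of one simulation run."""

    scenario: str
    learner: str = "polynomial"
    n: int = 80
    replicates: int = 1000
    seed: int = 0
    pi_start: float | None = None
    pi_end: float = 0.1
    burn_in: int = 5
    balanced_burn_in: bool = True
    noise_scale: float = 0.1
    followup_days: int | None = None
    definition: str = "latent_draw"
    equal_var: bool = False
    learner_kwargs: dict = field(default_factory=dict)
    out: str | None = None
    save_trials: int = 0          # write per-patient CSVs for the first few replicates

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def scenario_spec(self) -> sc.ScenarioSpec:
        spec = sc.get_scenario(self.scenario, noise_scale=self.noise_scale)
        if self.followup_days is not None and spec.setting == "survival":
            from dataclasses import replace
            spec = replace(spec, followup_days=self.followup_days)
        return spec

    def trial_config(self) -> TrialConfig:
        return TrialConfig(
            N=self.n, K=2, L=self.burn_in,
            pi_start=self.pi_start, pi_end=self.pi_end,
            learner_family=self.learner,
            balanced_burn_in=self.balanced_burn_in,
            seed=self.seed, learner_kwargs=dict(self.learner_kwargs),
        )


def replicate_seed(root_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic substream for one replicate of a run."""
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(index,))


def run_replicates(scenario: sc.ScenarioSpec, config: TrialConfig,
                   replicates: int, seed: int) -> list[TrialResult]:
    """Simulate ``replicates`` independent trials from one root seed."""
    return [run_trial(scenario, config, seed=replicate_seed(seed, i))
            for i in range(replicates)]


def run_command(cfg: RunConfig) -> ev.OperatingCharacteristics:
    """Execute one run configuration; write artifacts if ``cfg.out`` is set."""
    spec = cfg.scenario_spec()
    tconf = cfg.trial_config()
    results = run_replicates(spec, tconf, cfg.replicates, cfg.seed)
    oc = ev.aggregate(results, spec, definition=cfg.definition,
                      equal_var=cfg.equal_var)
    if cfg.out is not None:
        outdir = Path(cfg.out)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{cfg.scenario}_{cfg.learner}_n{cfg.n}"
        oc.to_json(outdir / f"{stem}_oc.json", config=asdict(cfg),
                   version=__version__, seed=cfg.seed)
        oc.to_frame().to_csv(outdir / f"{stem}_metrics.csv", index=False)
        for i in range(min(cfg.save_trials, len(results))):
            results[i].to_csv(outdir / f"{stem}_trial{i:04d}.csv")
    return oc


def sweep_command(grid: list[RunConfig], out: str | None = None) -> pd.DataFrame:
    """Run a grid of configurations; return (and optionally write) one
    combined tidy metrics table.  Failures are recorded per cell and do
    not abort the sweep."""
    if not grid:
        raise ValueError("empty sweep grid")
    frames = []
    failures = []
    for cfg in grid:
        try:
            oc = run_command(cfg)
            frames.append(oc.to_frame())
        except Exception as exc:  # noqa: BLE001 - sweep robustness contract
            failures.append(dict(scenario=cfg.scenario, learner=cfg.learner,
                                 N=cfg.n, error=str(exc)))
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out is not None:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        combined.to_csv(outdir / "sweep_metrics.csv", index=False)
        if failures:
            pd.DataFrame(failures).to_csv(outdir / "sweep_failures.csv", index=False)
    return combined
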