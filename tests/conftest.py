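import numpy as np
import pytest

from carasim import evaluation as ev
from carasim import runner
from carasim import scenarios as sc
from carasim import trial as tr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate(scenario_id, learner, n, reps, seed, **cfg_kwargs):
    """Run replicates and aggregate, with one shared code path for tests."""
    spec = sc.get_scenario(scenario_id)
    conf = tr.TrialConfig(N=n, learner_family=learner, **cfg_kwargs)
    results = runner.run_replicates(spec, conf, reps, seed)
    return ev.aggregate(results, spec), results, spec


def three_se_band(level, reps):
    """Half-width of the 3-Monte-Carlo-standard-error calibration band."""
    return 3.0 * np.sqrt(level * (1.0 - level) / reps)


def brute_force_logrank(times, events, arms):
    """Independent logrank oracle: hypergeometric moments from scipy at
    each distinct event time, tabulated directly over the risk sets."""
    from scipy import stats

    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    arms = np.asarray(arms, int)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        risk = times >= t
        n, n2 = risk.sum(), (risk & (arms == 2)).sum()
        d = (events & (times == t)).sum()
        d2 = (events & (times == t) & (arms == 2)).sum()
        # d2 ~ Hypergeometric(population n, successes n2, draws d); scipy's
        # variance already carries the multi-death (tie) correction factor.
        hg = stats.hypergeom(n, n2, d)
        o_minus_e += d2 - hg.mean()
        if n > 1:
            var += hg.var()
    return o_minus_e, var
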