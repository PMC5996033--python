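import numpy as np
import pytest

import plusmaze as pm


def make_protocol(n_days=(2, 1, 2), trials_per_day=40):
    return pm.odor_first_protocol(n_days=n_days, trials_per_day=trials_per_day)


def uniform_params(protocol, alpha=0.3, weights=(0.1, 0.8, 0.1), beta=6.0, wam=True):
    """Same (alpha, weights) every day of every set."""
    w = pm.DecisionWeights(*weights) if wam else None
    return {
        s.set_label: pm.SetParams((pm.DayParams(alpha, w),) * s.n_days, beta)
        for s in protocol.sets
    }


def single_set_protocol(n_days, trials_per_day, dimension="odor", label=None):
    """A protocol whose first set is the one under study; later sets are minimal."""
    if dimension == "odor":
        sets = (
            pm.SetSpec("ODOR1", "odor", 1, n_days, trials_per_day),
            pm.SetSpec("ODOR2", "odor", 1, 1, 2),
            pm.SetSpec("LED", "led", 1, 1, 2),
        )
        return pm.ExperimentProtocol("odor_first", sets)
    sets = (
        pm.SetSpec("LED", "led", 1, n_days, trials_per_day),
        pm.SetSpec("ODOR1", "odor", 1, 1, 2),
    )
    return pm.ExperimentProtocol("led_first", sets)


def simulate_one_set(
    n_days,
    trials_per_day,
    seed,
    model="wam",
    alpha=0.3,
    weights=(0.1, 0.8, 0.1),
    beta=6.0,
    dimension="odor",
):
    """Simulate and return just the first set's log."""
    proto = single_set_protocol(n_days, trials_per_day, dimension)
    params = uniform_params(proto, alpha, weights, beta, wam=(model == "wam"))
    label = proto.sets[0].set_label
    return pm.split_by_set(pm.simulate_agent(proto, model, params, seed=seed))[label], params[label]


@pytest.fixture(scope="session")
def wam_log_3day():
    """A 3-day x 50-trial odor-set log from a known WAM agent (session-wide reuse)."""
    log, params = simulate_one_set(3, 50, seed=42)
    return log, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_log():
    """Five hand-built trials of an odor set (used against the frozen LL oracle)."""
    O = pm.OfferedOption
    mk = lambda a, b, ch, r, t: pm.TrialRecord("ODOR1", 1, t, O(*a), O(*b), ch, r)
    return [
        mk((1, 1, 1), (2, 2, 2), "a", 1, 1),
        mk((3, 2, 1), (4, 1, 2), "a", 0, 2),
        mk((2, 1, 2), (3, 2, 1), "b", 0, 3),
        mk((1, 1, 2), (4, 2, 1), "a", 1, 4),
        mk((2, 2, 2), (1, 1, 1), "b", 1, 5),
    ]
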