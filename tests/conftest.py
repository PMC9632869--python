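import numpy as np
import pandas as pd
import pytest

from riskpol.distributions import make_support
from riskpol.simulator import TabularMDP


@pytest.fixture
def grid51():
    return make_support(-100.0, 100.0, 51)


@pytest.fixture
def grid3():
    return make_support(0.0, 2.0, 3)


def deterministic_chain(length: int, n_actions: int = 1) -> TabularMDP:
    """x0 -> x1 -> ... -> recovered, single deterministic path."""
    K = length
    probs = np.zeros((K, n_actions, K + 2))
    for a in range(n_actions):
        for x in range(K):
            probs[x, a, x + 1 if x < K - 1 else K] = 1.0
    init = np.zeros(K)
    init[0] = 1.0
    return TabularMDP(probs, init)


@pytest.fixture
def chain3():
    return deterministic_chain(3)


def two_point_mdp(p_recover: float) -> TabularMDP:
    """Single state, single action, immediate recovery w.p. p else death."""
    probs = np.zeros((1, 1, 3))
    probs[0, 0, 1] = p_recover
    probs[0, 0, 2] = 1.0 - p_recover
    return TabularMDP(probs, np.array([1.0]))


def toy_trajectory() -> pd.DataFrame:
    """Two patients, hand-written transitions over 2 states / 2 actions."""
    rows = [
        # patient 0: 0 -a0-> 1 -a1-> recovered
        dict(patient_id=0, t=0, state=0, action=0, next_state=1, outcome="recovered"),
        dict(patient_id=0, t=1, state=1, action=1, next_state=-1, outcome="recovered"),
        # patient 1: 0 -a0-> 0 -a0-> died
        dict(patient_id=1, t=0, state=0, action=0, next_state=0, outcome="died"),
        dict(patient_id=1, t=1, state=0, action=0, next_state=-2, outcome="died"),
    ]
    return pd.DataFrame(rows)
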