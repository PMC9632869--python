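"""Empirical-MDP patient simulator.

Discrete trajectories are turned into transition counts over K non-terminal
states plus two absorbing outcomes (recovered, died).  Rewards are terminal
only: +100 on entering the recovered state, -100 on entering the died state,
0 otherwise.  Episodes that hit the horizon cap without absorbing are
flagged censored.

Trajectory tables are pandas frames with columns
``patient_id, t, state, action, next_state, outcome`` where ``next_state``
uses the sentinels RECOVERED_CODE (-1), DIED_CODE (-2) and CENSORED_CODE
(-3, no observed successor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RECOVERED_CODE",
    "DIED_CODE",
    "CENSORED_CODE",
    "TERMINAL_REWARD",
    "TabularMDP",
    "EmpiricalMDP",
    "EpisodeRecord",
    "build_empirical_mdp",
    "reset",
    "step",
    "sample_episode",
    "split_by_patient",
    "as_policy_matrix",
    "TabularEnv",
    "make_chain_mdp",
    "make_random_mdp",
]

RECOVERED_CODE = -1
DIED_CODE = -2
CENSORED_CODE = -3
TERMINAL_REWARD = 100.0


class TabularMDP:
    """Finite MDP with K non-terminal states and 2 absorbing outcomes.

    ``probs`` has shape (K, n_actions, K + 2); the last two successor columns
    are the recovered and died outcomes.  Rows are normalized for valid
    (state, action) pairs and all-zero otherwise.
    """

    def __init__(
        self,
        probs: np.ndarray,
        initial_dist: np.ndarray,
        valid_actions: Optional[Sequence[np.ndarray]] = None,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 3 or probs.shape[2] != probs.shape[0] + 2:
            raise ValueError("probs must have shape (K, A, K + 2)")
        self.n_states, self.n_actions = probs.shape[:2]
        row_sums = probs.sum(axis=2)
        observed = row_sums > 0
        if valid_actions is None:
            valid_actions = [np.where(observed[x])[0] for x in range(self.n_states)]
        bad = np.abs(row_sums[observed] - 1.0) > 1e-9
        if np.any(bad):
            raise ValueError("observed transition rows must sum to 1")
        self.probs = probs
        self.valid_actions = [np.asarray(v, dtype=int) for v in valid_actions]
        initial_dist = np.asarray(initial_dist, dtype=float)
        if initial_dist.shape != (self.n_states,) or abs(initial_dist.sum() - 1) > 1e-9:
            raise ValueError("initial_dist must be a distribution over states")
        self.initial_dist = initial_dist
        self._cum_probs = np.cumsum(probs, axis=2)
        self._cum_init = np.cumsum(initial_dist)

    @property
    def recovered_index(self) -> int:
        return self.n_states

    @property
    def died_index(self) -> int:
        return self.n_states + 1

    def terminal_rewards(self) -> np.ndarray:
        """Reward on *entering* each successor index (length K + 2)."""
        r = np.zeros(self.n_states + 2)
        r[self.recovered_index] = TERMINAL_REWARD
        r[self.died_index] = -TERMINAL_REWARD
        return r

    def valid_pairs(self) -> List[Tuple[int, int]]:
        return [(x, int(a)) for x in range(self.n_states) for a in self.valid_actions[x]]


class EmpiricalMDP(TabularMDP):
    """Transition-frequency MDP estimated from discretized trajectories."""

    def __init__(self, counts: np.ndarray, initial_counts: np.ndarray):
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(totals[..., None] > 0, counts / totals[..., None], 0.0)
        initial_counts = np.asarray(initial_counts, dtype=float)
        if initial_counts.sum() <= 0:
            raise ValueError("no episode starts observed")
        super().__init__(probs, initial_counts / initial_counts.sum())
        self.counts = counts
        self.initial_counts = initial_counts


def build_empirical_mdp(
    traj: pd.DataFrame, n_states: int, n_actions: int = 25
) -> EmpiricalMDP:
    """Accumulate transition counts from a discrete trajectory table.

    Terminal transitions are directed to the absorbing outcome matching the
    sentinel in ``next_state``; censored final rows (no observed successor)
    contribute no transition.  The initial-state distribution is proportional
    to episode-start counts.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory table")
    states = traj["state"].to_numpy(dtype=int)
    if states.min() < 0 or states.max() >= n_states:
        raise ValueError("state ids out of range")
    actions = traj["action"].to_numpy(dtype=int)
    nxt = traj["next_state"].to_numpy(dtype=int)
    counts = np.zeros((n_states, n_actions, n_states + 2))
    keep = nxt != CENSORED_CODE
    succ = nxt[keep].copy()
    succ[succ == RECOVERED_CODE] = n_states
    succ[succ == DIED_CODE] = n_states + 1
    np.add.at(counts, (states[keep], actions[keep], succ), 1.0)
    starts = traj.sort_values(["patient_id", "t"]).groupby("patient_id", sort=False)[
        "state"
    ].first()
    initial = np.zeros(n_states)
    np.add.at(initial, starts.to_numpy(dtype=int), 1.0)
    return EmpiricalMDP(counts, initial)


# ---------------------------------------------------------------------------
# interaction
# ---------------------------------------------------------------------------

def reset(mdp: TabularMDP, rng: np.random.Generator) -> Tuple[int, np.ndarray]:
    """Sample an initial state; returns (state, valid actions)."""
    x = int(np.searchsorted(mdp._cum_init, rng.random(), side="right"))
    x = min(x, mdp.n_states - 1)
    return x, mdp.valid_actions[x]


def step(
    mdp: TabularMDP, state: int, action: int, rng: np.random.Generator
) -> Tuple[int, float, bool, np.ndarray]:
    """One transition; returns (next state, reward, done, next valid actions).

    The next state is an index in [0, K + 1]; indices K and K + 1 are the
    absorbing recovered/died outcomes and carry the +/-100 reward.
    """
    if action not in mdp.valid_actions[state]:
        raise ValueError(
            f"action {action} invalid in state {state}; "
            f"valid: {mdp.valid_actions[state].tolist()}"
        )
    u = rng.random()
    nxt = int(np.searchsorted(mdp._cum_probs[state, action], u, side="right"))
    nxt = min(nxt, mdp.n_states + 1)
    if nxt == mdp.recovered_index:
        return nxt, TERMINAL_REWARD, True, np.empty(0, dtype=int)
    if nxt == mdp.died_index:
        return nxt, -TERMINAL_REWARD, True, np.empty(0, dtype=int)
    return nxt, 0.0, False, mdp.valid_actions[nxt]


@dataclass
class EpisodeRecord:
    """One rollout: visited states, actions, rewards, and the outcome."""

    states: List[int]
    actions: List[int]
    rewards: List[float]
    outcome: str  # 'recovered' | 'died' | 'censored'

    @property
    def length(self) -> int:
        return len(self.actions)

    def discounted_return(self, gamma: float) -> float:
        return float(sum(r * gamma**t for t, r in enumerate(self.rewards)))


def as_policy_matrix(policy, mdp: TabularMDP) -> np.ndarray:
    """Coerce a policy to a (K, A) row-stochastic matrix on valid actions.

    Accepts a dense probability matrix, a deterministic action vector, or any
    object exposing ``.probs``.  Rows with no mass on a state's valid actions
    fall back to uniform-over-valid; rows with partial support are
    renormalized over the valid set.
    """
    if hasattr(policy, "probs"):
        policy = policy.probs
    policy = np.asarray(policy)
    K, A = mdp.n_states, mdp.n_actions
    if policy.ndim == 1:
        if policy.shape != (K,):
            raise ValueError("deterministic policy must have one action per state")
        out = np.zeros((K, A))
        out[np.arange(K), policy.astype(int)] = 1.0
        policy = out
    if policy.shape != (K, A):
        raise ValueError(f"policy shape {policy.shape} incompatible with ({K}, {A})")
    out = np.zeros((K, A))
    for x in range(K):
        va = mdp.valid_actions[x]
        if va.size == 0:
            continue
        row = np.clip(policy[x, va], 0.0, None)
        total = row.sum()
        if total <= 0:
            out[x, va] = 1.0 / va.size
        else:
            out[x, va] = row / total
    return out


def sample_episode(
    mdp: TabularMDP,
    policy,
    h_max: int = 500,
    rng: Optional[np.random.Generator] = None,
    policy_matrix_checked: Optional[np.ndarray] = None,
) -> EpisodeRecord:
    """Roll out one episode until absorption or the horizon cap.

    Entering a state with no valid actions also ends the episode as censored
    (possible when an MDP is built from a small data half).
    """
    if rng is None:
        rng = np.random.default_rng()
    pol = (
        policy_matrix_checked
        if policy_matrix_checked is not None
        else as_policy_matrix(policy, mdp)
    )
    cum_pol = np.cumsum(pol, axis=1)
    x, va = reset(mdp, rng)
    states, actions, rewards = [x], [], []
    outcome = "censored"
    for _ in range(h_max):
        if va.size == 0 or cum_pol[x, -1] <= 0:
            break
        a = int(np.searchsorted(cum_pol[x], rng.random(), side="right"))
        a = min(a, mdp.n_actions - 1)
        nxt, r, done, va = step(mdp, x, a, rng)
        actions.append(a)
        rewards.append(r)
        if done:
            outcome = "recovered" if nxt == mdp.recovered_index else "died"
            break
        states.append(nxt)
        x = nxt
    return EpisodeRecord(states, actions, rewards, outcome)


def split_by_patient(
    traj: pd.DataFrame, train_frac: float = 0.8, seed: Optional[int] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint patient-level train/test split of a trajectory table."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    patients = traj["patient_id"].unique()
    perm = rng.permutation(patients)
    n_train = max(1, int(round(train_frac * len(perm))))
    n_train = min(n_train, len(perm) - 1)
    train_ids = set(perm[:n_train])
    mask = traj["patient_id"].isin(train_ids)
    return traj[mask].copy(), traj[~mask].copy()


class TabularEnv:
    """Gym-style episodic wrapper: ``reset()`` / ``step(action)``.

    ``info['valid_actions']`` carries the valid-action subset of the current
    state; truncation happens at ``h_max`` steps.
    """

    def __init__(self, mdp: TabularMDP, h_max: int = 500, seed: Optional[int] = None):
        self.mdp = mdp
        self.h_max = h_max
        self._rng = np.random.default_rng(seed)
        self._t = 0
        self._state: Optional[int] = None

    def reset(self, seed: Optional[int] = None):
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self._t = 0
        self._state, va = reset(self.mdp, self._rng)
        return self._state, {"valid_actions": va}

    def step(self, action: int):
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        nxt, r, done, va = step(self.mdp, self._state, action, self._rng)
        self._t += 1
        truncated = not done and self._t >= self.h_max
        self._state = None if done else nxt
        return nxt, r, done, truncated, {"valid_actions": va}


# ---------------------------------------------------------------------------
# toy factories (benchmarks / tests)
# ---------------------------------------------------------------------------

def make_chain_mdp(
    length: int,
    p_advance: float = 0.8,
    p_die: float = 0.05,
    n_actions: int = 2,
) -> TabularMDP:
    """A chain of ``length`` states ending in recovery.

    Action 0 advances with probability ``p_advance`` (falling back to the
    chain start otherwise) and carries a small death hazard; further actions
    are strictly worse (halved advance probability, doubled hazard), so the
    optimal policy is action 0 everywhere.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    K = length
    probs = np.zeros((K, n_actions, K + 2))
    for a in range(n_actions):
        adv = p_advance * 0.5**a
        die = min(1.0, p_die * 2.0**a)
        stay = max(0.0, 1.0 - adv - die)
        for x in range(K):
            target = K if x == K - 1 else x + 1  # recovery off the last link
            probs[x, a, target] += adv
            probs[x, a, K + 1] += die
            probs[x, a, 0] += stay
    init = np.zeros(K)
    init[0] = 1.0
    return TabularMDP(probs, init)


def make_random_mdp(
    n_states: int = 10,
    n_actions: int = 3,
    seed: Optional[int] = None,
    absorb_scale: float = 0.15,
) -> TabularMDP:
    """Random absorbing MDP with action-dependent recovery/death hazards."""
    rng = np.random.default_rng(seed)
    K = n_states
    probs = np.zeros((K, n_actions, K + 2))
    for x in range(K):
        for a in range(n_actions):
            h_rec = rng.uniform(0.0, absorb_scale)
            h_die = rng.uniform(0.0, absorb_scale)
            inner = rng.dirichlet(np.ones(K)) * (1.0 - h_rec - h_die)
            probs[x, a, :K] = inner
            probs[x, a, K] = h_rec
            probs[x, a, K + 1] = h_die
    init = rng.dirichlet(np.ones(K))
    return TabularMDP(probs, init)
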