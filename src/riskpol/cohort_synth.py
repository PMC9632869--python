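"""Synthetic-cohort generator with a known ground-truth MDP.

Emulates the statistical shape the pipeline assumes: a latent finite-state
process with absorbing recovery/death outcomes and valid-action subsets per
state, hourly episodes sampled under a behavior policy of tunable quality,
cluster-structured continuous features emitted per visited state, and
missing-completely-at-random masking.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import json
import numpy as np
import pandas as pd

from .imputation import ObservationMatrix
from .simulator import (
    CENSORED_CODE,
    DIED_CODE,
    RECOVERED_CODE,
    TabularMDP,
)
from .state_repr import value_iteration

__all__ = [
    "CohortConfig",
    "GroundTruthMDP",
    "generate_latent_mdp",
    "behavior_policy",
    "sample_trajectories",
    "emit_features",
    "apply_missingness",
    "perturb_kernel",
    "generate_cohort",
]


@dataclass
class CohortConfig:
    """Knobs for the synthetic cohort."""

    n_patients: int = 500
    n_features: int = 53
    k_true: int = 8
    n_iv_bins: int = 5
    n_vaso_bins: int = 5
    missing_rate: float = 0.39
    noise_scale: float = 0.5
    centroid_scale: float = 6.0
    episode_cap: int = 200
    behavior_quality: float = 0.5
    min_valid_actions: int = 3
    recover_hazard_max: float = 0.30
    death_hazard_max: float = 0.08
    gamma: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.behavior_quality <= 1.0:
            raise ValueError("behavior_quality must be in [0, 1]")
        for name in ("n_patients", "n_features", "k_true", "episode_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def n_actions(self) -> int:
        return self.n_iv_bins * self.n_vaso_bins

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


class GroundTruthMDP(TabularMDP):
    """The generator's true dynamics plus feature-space state centroids."""

    def __init__(self, probs, initial_dist, valid_actions, centroids):
        super().__init__(probs, initial_dist, valid_actions)
        centroids = np.asarray(centroids, dtype=float)
        if centroids.shape[0] != self.n_states:
            raise ValueError("one centroid per non-terminal state required")
        self.centroids = centroids


def generate_latent_mdp(config: CohortConfig) -> GroundTruthMDP:
    """Seeded random ground-truth MDP.

    Per valid (state, action) a recovery and a death hazard are drawn
    independently, so actions genuinely differ in value; the remaining mass
    is spread over latent states by a Dirichlet draw.  Valid-action subsets
    are drawn per state and always non-empty.
    """
    if config.k_true < 2:
        raise ValueError("k_true must be >= 2")
    rng = np.random.default_rng(config.seed)
    K, A = config.k_true, config.n_actions
    probs = np.zeros((K, A, K + 2))
    valid_actions = []
    for x in range(K):
        n_valid = int(rng.integers(min(config.min_valid_actions, A), A + 1))
        va = np.sort(rng.choice(A, size=n_valid, replace=False))
        valid_actions.append(va)
        for a in va:
            h_rec = rng.uniform(0.0, config.recover_hazard_max)
            h_die = rng.uniform(0.0, config.death_hazard_max)
            inner = rng.dirichlet(np.ones(K)) * (1.0 - h_rec - h_die)
            probs[x, a, :K] = inner
            probs[x, a, K] = h_rec
            probs[x, a, K + 1] = h_die
    initial = rng.dirichlet(np.ones(K) * 2.0)
    centroids = rng.normal(size=(K, config.n_features)) * config.centroid_scale
    return GroundTruthMDP(probs, initial, valid_actions, centroids)


def behavior_policy(
    mdp: GroundTruthMDP, quality: float = 0.5, gamma: float = 0.99
) -> np.ndarray:
    """Clinician stand-in: mix of the optimal and the uniform-valid policy.

    ``quality = 1`` is the deterministic optimal policy, ``quality = 0`` is
    uniform over valid actions; rows sum to one over valid actions.
    """
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must be in [0, 1]")
    _, opt = value_iteration(mdp, gamma=gamma)
    K, A = mdp.n_states, mdp.n_actions
    policy = np.zeros((K, A))
    for x in range(K):
        va = mdp.valid_actions[x]
        policy[x, va] += (1.0 - quality) / va.size
        policy[x, opt[x]] += quality
    return policy


def sample_trajectories(
    mdp: TabularMDP,
    policy: np.ndarray,
    n_patients: int,
    cap: int = 200,
    seed: Optional[int] = None,
    n_vaso_bins: int = 5,
) -> pd.DataFrame:
    """Roll episodes to absorption (or the cap) under a stochastic policy.

    Returns the discrete trajectory table (one row per patient-hour) with
    flat action ids plus their (iv, vaso) bin decomposition and the
    episode-level outcome label; cap-hit episodes are 'censored' and their
    final row has no observed successor.
    """
    rng = np.random.default_rng(seed)
    from .simulator import as_policy_matrix, reset, step

    pol = as_policy_matrix(policy, mdp)
    cum_pol = np.cumsum(pol, axis=1)
    records = []
    for pid in range(n_patients):
        x, va = reset(mdp, rng)
        rows = []
        outcome = "censored"
        for t in range(cap):
            a = int(np.searchsorted(cum_pol[x], rng.random(), side="right"))
            a = min(a, mdp.n_actions - 1)
            nxt, r, done, va = step(mdp, x, a, rng)
            if done:
                code = RECOVERED_CODE if nxt == mdp.recovered_index else DIED_CODE
                rows.append((pid, t, x, a, code))
                outcome = "recovered" if code == RECOVERED_CODE else "died"
                break
            rows.append((pid, t, x, a, nxt))
            x = nxt
        if outcome == "censored" and rows:
            last = rows[-1]
            rows[-1] = (last[0], last[1], last[2], last[3], CENSORED_CODE)
        for pid_, t_, x_, a_, nxt_ in rows:
            records.append(
                {
                    "patient_id": pid_,
                    "t": t_,
                    "state": x_,
                    "action": a_,
                    "action_iv_bin": a_ // n_vaso_bins,
                    "action_vaso_bin": a_ % n_vaso_bins,
                    "next_state": nxt_,
                    "outcome": outcome,
                }
            )
    return pd.DataFrame.from_records(records)


def emit_features(
    traj: pd.DataFrame, mdp: GroundTruthMDP, config: CohortConfig
) -> Tuple[ObservationMatrix, pd.DataFrame]:
    """Continuous features for every visited state: centroid + isotropic noise.

    Rows align one-to-one (same order) with the trajectory table; the
    returned alignment frame carries (patient_id, t) per row.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    states = traj["state"].to_numpy(dtype=int)
    X = mdp.centroids[states] + config.noise_scale * rng.standard_normal(
        (len(states), config.n_features)
    )
    alignment = traj[["patient_id", "t"]].reset_index(drop=True)
    return ObservationMatrix(X), alignment


def apply_missingness(
    m: ObservationMatrix, rate: float, seed: Optional[int] = None
) -> ObservationMatrix:
    """Mask entries independently at the given rate (MCAR).

    Guards the no-fully-missing-feature invariant by unmasking one random
    entry in any column the draw wiped out entirely.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        return m.copy()
    mask = rng.random(m.values.shape) < rate
    for j in np.where(mask.all(axis=0))[0]:
        mask[rng.integers(m.n_obs), j] = False
    values = np.where(mask, np.nan, m.values)
    return ObservationMatrix(values, list(m.feature_names))


def perturb_kernel(
    mdp: GroundTruthMDP, eps: float, seed: Optional[int] = None
) -> GroundTruthMDP:
    """Mix each valid transition row with an independent Dirichlet draw.

    Used for controlled experiments on the coverage heuristic: ``eps = 0``
    returns the same dynamics, larger values move the two cohorts apart.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = mdp.probs.copy()
    K = mdp.n_states
    for x in range(K):
        for a in mdp.valid_actions[x]:
            noise = rng.dirichlet(np.ones(K + 2))
            probs[x, a] = (1.0 - eps) * probs[x, a] + eps * noise
    return GroundTruthMDP(probs, mdp.initial_dist, mdp.valid_actions, mdp.centroids)


def generate_cohort(config: CohortConfig):
    """Convenience bundle: MDP, behavior policy, trajectories, features.

    Returns a dict with keys ``mdp``, ``behavior``, ``traj``, ``features``
    (with missingness already applied when configured), ``features_full``,
    and ``alignment``.
    """
    mdp = generate_latent_mdp(config)
    beh = behavior_policy(mdp, config.behavior_quality, gamma=config.gamma)
    traj = sample_trajectories(
        mdp,
        beh,
        config.n_patients,
        cap=config.episode_cap,
        seed=np.random.SeedSequence([config.seed, 11]).generate_state(1)[0],
        n_vaso_bins=config.n_vaso_bins,
    )
    features_full, alignment = emit_features(traj, mdp, config)
    features = apply_missingness(
        features_full,
        config.missing_rate,
        seed=np.random.SeedSequence([config.seed, 13]).generate_state(1)[0],
    )
    return {
        "mdp": mdp,
        "behavior": beh,
        "traj": traj,
        "features": features,
        "features_full": features_full,
        "alignment": alignment,
    }
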