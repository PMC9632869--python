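"""Synchronous speedy categorical distributional Q-learning.

Return distributions live on a fixed support grid.  Per iteration k, every
valid (state, action) pair draws one successor sample; the Bellman targets
of the current and previous tables share that sample, are projected back
onto the grid, and are combined by the speedy rule

    D_k = k * Proj T eta_k - (k - 1) * Proj T eta_{k-1}
    eta_{k+1} = (1 - a_k) * eta_k + a_k * D_k,      a_k = 1 / (k + 1)

which extrapolates the two successive targets.  The extrapolation can push
weights negative; tables are carried as signed measures internally and
clip-renormalized only at readout.  Policy control stops early once the
sup-Cramér change drops below a threshold; policy evaluation runs the full
iteration budget.

A plain categorical Q-learning loop (same sampling, non-extrapolated
target) is provided as the speed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .distributions import (
    CategoricalPMF,
    ReturnTable,
    SupportGrid,
    clip_renormalize,
    make_support,
    projection_matrix,
    sup_cramer_weights,
)
from .simulator import TabularMDP, as_policy_matrix

__all__ = [
    "TrainConfig",
    "greedy_policy",
    "bellman_backup_pair",
    "speedy_control",
    "speedy_policy_evaluation",
    "categorical_q_control",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the synchronous training loop."""

    gamma: float = 0.99
    v_min: float = -100.0
    v_max: float = 100.0
    n_atoms: int = 51
    max_iter: int = 1000
    delta: float = 0.05
    init_value: float = 0.0  # eta_0 = point mass at the atom nearest this
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def grid(self) -> SupportGrid:
        return make_support(self.v_min, self.v_max, self.n_atoms)


def greedy_policy(eta: ReturnTable, valid_actions) -> np.ndarray:
    """Per state, the valid action with the largest expected return.

    Ties break toward the lowest action index.  Raises for states with an
    empty valid-action set.
    """
    exps = eta.expectations()
    n_states = len(valid_actions)
    out = np.empty(n_states, dtype=int)
    for x in range(n_states):
        va = np.asarray(valid_actions[x], dtype=int)
        if va.size == 0:
            raise ValueError(f"state {x} has no valid action")
        vals = np.array([exps[eta.index[(x, int(a))]] for a in va])
        out[x] = int(va[int(np.argmax(vals))])  # argmax returns first max
    return out


def bellman_backup_pair(
    eta_k: ReturnTable,
    eta_km1: ReturnTable,
    x: int,
    a: int,
    sample: Tuple[Optional[int], float],
    a_prime: Optional[int],
    gamma: float,
    grid: SupportGrid,
) -> Tuple[CategoricalPMF, CategoricalPMF]:
    """Projected Bellman targets of both tables for one shared sample.

    ``sample`` is ``(x_prime, reward)``; ``x_prime is None`` marks a terminal
    successor, in which case both targets are the projected point mass at the
    reward (no bootstrapping past absorption).  Otherwise the successor
    distributions ``eta(x', a')`` are shifted/scaled by ``reward + gamma z``
    and projected.
    """
    if not grid.same_as(eta_k.grid) or not grid.same_as(eta_km1.grid):
        raise ValueError("grid mismatch")
    x_prime, reward = sample
    if x_prime is None:
        mat = projection_matrix(grid, [reward])
        pmf = CategoricalPMF(grid, mat[0])
        return pmf, pmf
    locations = reward + gamma * grid.atoms
    mat = projection_matrix(grid, locations)
    w_k = eta_k.weights[eta_k.index[(int(x_prime), int(a_prime))]]
    w_km1 = eta_km1.weights[eta_km1.index[(int(x_prime), int(a_prime))]]
    t_k, _ = clip_renormalize(w_k @ mat)
    t_km1, _ = clip_renormalize(w_km1 @ mat)
    return CategoricalPMF(grid, t_k), CategoricalPMF(grid, t_km1)


def _greedy_from_weights(
    W: np.ndarray,
    atoms: np.ndarray,
    pair_index: np.ndarray,
    valid_actions,
) -> np.ndarray:
    exps = W @ atoms
    out = np.empty(len(valid_actions), dtype=int)
    for x, va in enumerate(valid_actions):
        out[x] = int(va[int(np.argmax(exps[pair_index[x, va]]))])
    return out


def _train(
    env: TabularMDP,
    config: TrainConfig,
    mode: str,
    policy=None,
    algo: str = "speedy",
    early_stop: bool = True,
    callback=None,
) -> Tuple[ReturnTable, np.ndarray, Dict]:
    """Shared synchronous loop for control / evaluation, speedy / plain."""
    if mode not in ("control", "evaluation"):
        raise ValueError("mode must be 'control' or 'evaluation'")
    if algo not in ("speedy", "plain"):
        raise ValueError("algo must be 'speedy' or 'plain'")
    grid = config.grid()
    atoms = grid.atoms
    K = env.n_states
    pairs = env.valid_pairs()
    if not pairs:
        raise ValueError("environment has no valid (state, action) pairs")
    n_pairs = len(pairs)
    pair_index = -np.ones((K, env.n_actions), dtype=int)
    for i, (x, a) in enumerate(pairs):
        pair_index[x, a] = i
    pair_states = np.array([x for x, _ in pairs])
    pair_actions = np.array([a for _, a in pairs])

    rng = np.random.default_rng(config.seed)
    init = ReturnTable.constant(grid, pairs, config.init_value)
    W = init.weights.copy()
    W_prev = W.copy()

    # per-pair successor sampling tables
    cum_succ = np.cumsum(env.probs[pair_states, pair_actions], axis=1)
    rec_idx, die_idx = env.recovered_index, env.died_index
    # projection of a point mass shifted by gamma (non-terminal targets)
    P_shift = projection_matrix(grid, config.gamma * atoms)
    e_rec = projection_matrix(grid, [100.0])[0]
    e_die = projection_matrix(grid, [-100.0])[0]

    if mode == "evaluation":
        pol = as_policy_matrix(policy, env)
        cum_pol = np.cumsum(pol, axis=1)

    # states entered as successors must expose a usable action; states with
    # no valid action are treated as censoring (target = point mass at 0)
    e_zero = projection_matrix(grid, [0.0])[0]
    has_actions = np.array([va.size > 0 for va in env.valid_actions])

    trace = np.empty(config.max_iter)
    converged = False
    n_iter = 0
    for k in range(config.max_iter):
        alpha = 1.0 / (k + 1.0)
        if mode == "control":
            greedy = _greedy_from_weights(W, atoms, pair_index, env.valid_actions)
        u = rng.random(n_pairs)
        succ = (cum_succ < u[:, None]).sum(axis=1)
        T_k = np.empty_like(W)
        T_km1 = np.empty_like(W)
        T_k[succ == rec_idx] = e_rec
        T_km1[succ == rec_idx] = e_rec
        T_k[succ == die_idx] = e_die
        T_km1[succ == die_idx] = e_die
        nonterm = succ < K
        dead_end = nonterm & ~has_actions[np.minimum(succ, K - 1)]
        nonterm &= ~dead_end
        T_k[dead_end] = e_zero
        T_km1[dead_end] = e_zero
        if np.any(nonterm):
            s_nt = succ[nonterm]
            if mode == "control":
                a_nt = greedy[s_nt]
            else:
                ua = rng.random(s_nt.size)
                a_nt = (cum_pol[s_nt] < ua[:, None]).sum(axis=1)
                a_nt = np.minimum(a_nt, env.n_actions - 1)
            rows = pair_index[s_nt, a_nt]
            if np.any(rows < 0):
                raise ValueError("policy placed mass on an invalid action")
            WP = W @ P_shift
            T_k[nonterm] = WP[rows]
            if algo == "speedy":
                WP_prev = W_prev @ P_shift
                T_km1[nonterm] = WP_prev[rows]
        if algo == "speedy":
            D = k * T_k - (k - 1) * T_km1
            W_new = (1.0 - alpha) * W + alpha * D
        else:
            W_new = (1.0 - alpha) * W + alpha * T_k
        if not np.all(np.isfinite(W_new)):
            raise FloatingPointError("non-finite weights during training")
        dist = sup_cramer_weights(W_new, W, grid)
        trace[k] = dist
        W_prev, W = W, W_new
        n_iter = k + 1
        if callback is not None and callback(k, W):
            converged = True
            break
        if early_stop and dist <= config.delta:
            converged = True
            break

    signed = ReturnTable(grid, pairs, W, signed=True)
    readout, clipped = signed.to_pmf_table()
    final_greedy = _greedy_from_weights(W, atoms, pair_index, env.valid_actions)
    diagnostics = {
        "trace": trace[:n_iter].copy(),
        "iterations": n_iter,
        "converged": converged,
        "clipped_mass": clipped,
        "algo": algo,
        "mode": mode,
    }
    return readout, final_greedy, diagnostics


def speedy_control(
    env: TabularMDP, config: Optional[TrainConfig] = None
) -> Tuple[ReturnTable, np.ndarray, Dict]:
    """Speedy categorical policy control.

    Returns the (clip-renormalized) return table, the greedy deterministic
    policy, and diagnostics including the per-iteration sup-Cramér trace.
    """
    config = config or TrainConfig()
    return _train(env, config, mode="control", algo="speedy", early_stop=True)


def speedy_policy_evaluation(
    env: TabularMDP, policy, config: Optional[TrainConfig] = None
) -> Tuple[ReturnTable, Dict]:
    """Speedy evaluation of a fixed policy (full iteration budget, no
    early stop); successor actions are sampled from the policy."""
    config = config or TrainConfig()
    table, _, diag = _train(
        env, config, mode="evaluation", policy=policy, algo="speedy", early_stop=False
    )
    return table, diag


def categorical_q_control(
    env: TabularMDP, config: Optional[TrainConfig] = None
) -> Tuple[ReturnTable, np.ndarray, Dict]:
    """Plain categorical Q-learning control (the acceleration baseline)."""
    config = config or TrainConfig()
    return _train(env, config, mode="control", algo="plain", early_stop=True)


# ---------------------------------------------------------------------------
# expected-operator fixed point & speed benchmark
# ---------------------------------------------------------------------------

def exact_categorical_fixed_point(
    env: TabularMDP,
    config: Optional[TrainConfig] = None,
    policy=None,
    tol: float = 1e-12,
    max_sweeps: int = 20_000,
) -> ReturnTable:
    """Fixed point of the projected Bellman operator in expectation.

    Iterates the full (non-sampled) operator — control when ``policy`` is
    None, evaluation otherwise — until the sup-Cramér change drops below
    ``tol``.  Serves as the noise-free reference the sampled algorithms
    approach.
    """
    config = config or TrainConfig()
    grid = config.grid()
    atoms = grid.atoms
    K = env.n_states
    pairs = env.valid_pairs()
    pair_index = -np.ones((K, env.n_actions), dtype=int)
    for i, (x, a) in enumerate(pairs):
        pair_index[x, a] = i
    pair_states = np.array([x for x, _ in pairs])
    pair_actions = np.array([a for _, a in pairs])
    P_shift = projection_matrix(grid, config.gamma * atoms)
    e_rec = projection_matrix(grid, [100.0])[0]
    e_die = projection_matrix(grid, [-100.0])[0]
    e_zero = projection_matrix(grid, [0.0])[0]
    has_actions = np.array([va.size > 0 for va in env.valid_actions])
    if policy is not None:
        pol = as_policy_matrix(policy, env)
    W = ReturnTable.constant(grid, pairs, config.init_value).weights.copy()
    succ = env.probs[pair_states, pair_actions]  # (n_pairs, K+2)
    for _ in range(max_sweeps):
        WP = W @ P_shift
        G = np.empty((K, grid.n))  # successor-state continuation distribution
        if policy is None:
            greedy = _greedy_from_weights(W, atoms, pair_index, env.valid_actions)
            for y in range(K):
                G[y] = WP[pair_index[y, greedy[y]]] if has_actions[y] else e_zero
        else:
            for y in range(K):
                if not has_actions[y]:
                    G[y] = e_zero
                    continue
                va = env.valid_actions[y]
                G[y] = pol[y, va] @ WP[pair_index[y, va]]
        W_new = (
            succ[:, :K] @ G
            + np.outer(succ[:, K], e_rec)
            + np.outer(succ[:, K + 1], e_die)
        )
        if sup_cramer_weights(W_new, W, grid) < tol:
            W = W_new
            break
        W = W_new
    return ReturnTable(grid, pairs, W)


def iterations_to_threshold(
    env: TabularMDP,
    config: TrainConfig,
    algo: str = "speedy",
    reference: Optional[ReturnTable] = None,
    policy=None,
) -> int:
    """First iteration at which the iterate is within ``config.delta``
    (sup-Cramér) of the expected-operator fixed point.

    Returns ``config.max_iter`` when the threshold is never reached within
    the budget (right-censored).
    """
    if reference is None:
        reference = exact_categorical_fixed_point(env, config, policy=policy)
    ref_w = reference.weights
    grid = config.grid()
    hit = {"k": config.max_iter}

    def cb(k, W):
        if sup_cramer_weights(W, ref_w, grid) <= config.delta:
            hit["k"] = k + 1
            return True
        return False

    mode = "control" if policy is None else "evaluation"
    _train(
        env, config, mode=mode, policy=policy, algo=algo,
        early_stop=False, callback=cb,
    )
    return hit["k"]
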