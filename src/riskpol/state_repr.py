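"""State discretization and the coverage heuristic for selecting it.

A continuous feature matrix is standardized and clustered many times
(k-means over a grid of cluster counts with repeated restarts).  Each
candidate clustering is scored by "coverage": split patients into two
halves, extract the empirical behavior policy from the first half, policy-
evaluate it by dynamic programming on each half's empirical MDP, and measure
the fraction of shared states whose values agree within a threshold
(default 15 on the [-100, 100] value scale).  The candidate with the highest
coverage is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .simulator import (
    CENSORED_CODE,
    TabularMDP,
    build_empirical_mdp,
    split_by_patient,
)

__all__ = [
    "StandardizationParams",
    "Representation",
    "PolicyTable",
    "CoverageReport",
    "standardize",
    "fit_candidates",
    "assign_states",
    "relabel_states",
    "extract_policy",
    "dp_policy_evaluation",
    "value_iteration",
    "coverage",
    "coverage_from_halves",
    "select_representation",
]


@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def standardize(X: np.ndarray) -> Tuple[np.ndarray, StandardizationParams]:
    """Zero-mean unit-sd columns (population sd); constant columns become
    all-zero with a warning."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("standardize requires a completed (no-missing) matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) mapped to zero columns",
            stacklevel=2,
        )
        sd = np.where(const, 1.0, sd)
    params = StandardizationParams(mean=mean, sd=sd)
    return params.apply(X), params


@dataclass
class Representation:
    """A fitted clustering: centers in standardized feature space."""

    centers: np.ndarray
    seed: int
    standardization: Optional[StandardizationParams] = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[0] < 2:
            raise ValueError("need at least 2 cluster centers")
        d = cdist(self.centers, self.centers)
        np.fill_diagonal(d, np.inf)
        if d.min() == 0:
            raise ValueError("cluster centers must be pairwise distinct")

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]


@dataclass
class PolicyTable:
    """Per-state probabilities over actions; unvisited states have zero rows."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        sums = self.probs.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0)
        if not ok.all():
            raise ValueError("policy rows must sum to 1 (or 0 for absent states)")

    @property
    def states_present(self) -> np.ndarray:
        return self.probs.sum(axis=1) > 0


def fit_candidates(
    X: np.ndarray,
    k_grid: Sequence[int],
    n_restarts: int = 50,
    seed: Optional[int] = None,
    standardization: Optional[StandardizationParams] = None,
) -> List[Representation]:
    """K-means candidates: one fit per (K, restart), each with its own seed."""
    X = np.asarray(X, dtype=float)
    if any(K < 2 for K in k_grid):
        raise ValueError("all cluster counts must be >= 2")
    ss = np.random.SeedSequence(seed)
    candidates: List[Representation] = []
    for K in k_grid:
        if K > X.shape[0]:
            warnings.warn(f"skipping K={K} > {X.shape[0]} observations", stacklevel=2)
            continue
        for child in ss.spawn(n_restarts):
            rs = int(child.generate_state(1)[0] % (2**31 - 1))
            km = KMeans(n_clusters=int(K), n_init=1, random_state=rs).fit(X)
            candidates.append(
                Representation(km.cluster_centers_, seed=rs, standardization=standardization)
            )
    return candidates


def assign_states(X: np.ndarray, rep: Representation) -> np.ndarray:
    """Nearest-center assignment (Euclidean); ties go to the lowest index."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != rep.centers.shape[1]:
        raise ValueError("feature dimension does not match representation")
    return np.argmin(cdist(X, rep.centers), axis=1)


def relabel_states(traj: pd.DataFrame, states: np.ndarray) -> pd.DataFrame:
    """Replace a trajectory table's states with a new discretization.

    ``states`` must align row-for-row with ``traj``.  Within each episode the
    next-state column is rebuilt by shifting; terminal sentinel codes on
    final rows are preserved.
    """
    states = np.asarray(states, dtype=int)
    if len(states) != len(traj):
        raise ValueError("states must align with trajectory rows")
    out = traj.copy()
    out["state"] = states
    shifted = out.groupby("patient_id", sort=False)["state"].shift(-1)
    old_next = out["next_state"].to_numpy()
    new_next = np.where(old_next < 0, old_next, shifted.to_numpy())
    out["next_state"] = np.nan_to_num(new_next, nan=CENSORED_CODE).astype(int)
    return out


def extract_policy(
    traj: pd.DataFrame, n_states: int, n_actions: int = 25
) -> PolicyTable:
    """Empirical behavior policy: action frequencies per state."""
    if len(traj) == 0:
        raise ValueError("empty trajectory table")
    counts = np.zeros((n_states, n_actions))
    np.add.at(
        counts,
        (traj["state"].to_numpy(dtype=int), traj["action"].to_numpy(dtype=int)),
        1.0,
    )
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, counts / totals, 0.0)
    return PolicyTable(probs)


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

def _policy_transition(mdp: TabularMDP, policy) -> np.ndarray:
    from .simulator import as_policy_matrix

    pol = as_policy_matrix(policy, mdp)
    return np.einsum("xa,xay->xy", pol, mdp.probs)


def dp_policy_evaluation(
    mdp: TabularMDP,
    policy,
    gamma: float = 0.99,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Iterative Bellman-expectation evaluation of a policy.

    Returns per-state values; states with no valid action (no data) are NaN.
    Raises if the sup-norm change has not dropped below ``tol`` within
    ``max_iter`` sweeps.
    """
    K = mdp.n_states
    P = _policy_transition(mdp, policy)  # (K, K+2)
    r = P @ mdp.terminal_rewards()
    defined = np.array([va.size > 0 for va in mdp.valid_actions])
    v = np.zeros(K)
    for it in range(max_iter):
        v_new = r + gamma * P[:, :K] @ v
        delta = np.max(np.abs(v_new - v)) if K else 0.0
        v = v_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"policy evaluation did not converge: last sup-change {delta:.3g} "
            f"after {max_iter} sweeps (gamma={gamma})"
        )
    v = np.where(defined, v, np.nan)
    return v


def value_iteration(
    mdp: TabularMDP,
    gamma: float = 0.99,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact optimal values and a greedy deterministic policy.

    Returns ``(v, policy)``; states without valid actions get value NaN and
    policy -1.  Ties break toward the lowest action index.
    """
    K = mdp.n_states
    r_term = mdp.terminal_rewards()
    rewards = mdp.probs @ r_term  # (K, A) expected immediate reward
    defined = np.array([va.size > 0 for va in mdp.valid_actions])
    valid_mask = np.zeros((K, mdp.n_actions), dtype=bool)
    for x, va in enumerate(mdp.valid_actions):
        valid_mask[x, va] = True
    v = np.zeros(K)
    for it in range(max_iter):
        q = rewards + gamma * mdp.probs[:, :, :K] @ v
        q = np.where(valid_mask, q, -np.inf)
        v_new = np.where(defined, q.max(axis=1), 0.0)
        delta = np.max(np.abs(v_new - v)) if K else 0.0
        v = v_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"value iteration did not converge within {max_iter} sweeps")
    policy = np.where(defined, q.argmax(axis=1), -1)
    return np.where(defined, v, np.nan), policy


# ---------------------------------------------------------------------------
# coverage heuristic
# ---------------------------------------------------------------------------

def coverage(v1: np.ndarray, v2: np.ndarray, threshold: float = 15.0) -> float:
    """Fraction of states (defined in both halves) with |v1 - v2| < threshold."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("value vectors must have equal length")
    shared = np.isfinite(v1) & np.isfinite(v2)
    if not shared.any():
        raise ValueError("no state is defined in both halves")
    return float(np.mean(np.abs(v1[shared] - v2[shared]) < threshold))


def coverage_from_halves(
    traj1: pd.DataFrame,
    traj2: pd.DataFrame,
    n_states: int,
    n_actions: int = 25,
    gamma: float = 0.99,
    threshold: float = 15.0,
) -> float:
    """Coverage score for a pair of discrete data halves.

    The behavior policy is extracted from the first half only and policy-
    evaluated on both halves' empirical MDPs.
    """
    policy = extract_policy(traj1, n_states, n_actions)
    mdp1 = build_empirical_mdp(traj1, n_states, n_actions)
    mdp2 = build_empirical_mdp(traj2, n_states, n_actions)
    v1 = dp_policy_evaluation(mdp1, policy, gamma=gamma)
    v2 = dp_policy_evaluation(mdp2, policy, gamma=gamma)
    return coverage(v1, v2, threshold)


@dataclass
class CoverageReport:
    """Per-candidate coverage scores and the selected candidate."""

    table: pd.DataFrame  # columns: candidate, n_states, seed, coverage
    selected_index: int
    selected: Representation

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_representation(
    X: np.ndarray,
    traj: pd.DataFrame,
    candidates: Sequence[Representation],
    n_actions: int = 25,
    gamma: float = 0.99,
    threshold: float = 15.0,
    seed: Optional[int] = None,
    use_value_iteration: bool = False,
) -> CoverageReport:
    """Rank candidate discretizations by the coverage heuristic.

    Patients are split once (patient-level, seeded) into two halves shared by
    all candidates.  ``use_value_iteration=True`` replaces the extracted
    behavior policy by each half's own optimal policy (kept for comparison;
    not the default selection rule).
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    half1, half2 = split_by_patient(traj, train_frac=0.5, seed=seed)
    if len(half1) == 0 or len(half2) == 0:
        raise ValueError("a half of the split contains no episodes")
    rows = []
    for i, rep in enumerate(candidates):
        states = assign_states(X, rep)
        relabeled = relabel_states(traj, states)
        t1 = relabeled[relabeled["patient_id"].isin(half1["patient_id"].unique())]
        t2 = relabeled[relabeled["patient_id"].isin(half2["patient_id"].unique())]
        K = rep.n_states
        if use_value_iteration:
            mdp1 = build_empirical_mdp(t1, K, n_actions)
            mdp2 = build_empirical_mdp(t2, K, n_actions)
            v1, pol1 = value_iteration(mdp1, gamma=gamma)
            v2 = dp_policy_evaluation(mdp2, pol1, gamma=gamma)
            score = coverage(v1, v2, threshold)
        else:
            score = coverage_from_halves(
                t1, t2, K, n_actions, gamma=gamma, threshold=threshold
            )
        rows.append(
            {"candidate": i, "n_states": K, "seed": rep.seed, "coverage": score}
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["coverage", "n_states", "seed"], ascending=[False, True, True]
    )
    best = int(order.iloc[0]["candidate"])
    return CoverageReport(table=table, selected_index=best, selected=candidates[best])
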