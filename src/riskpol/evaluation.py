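"""Policy deployment and measurement.

Ranked stochastic policies (best action with weight 1/2, second best 1/4,
..., renormalized over the valid set), Monte-Carlo rollout metrics,
outcome classification of return distributions, the train/test
generalization experiment, and the end-to-end pipeline driver.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort_synth import CohortConfig, generate_cohort
from .distributions import CategoricalPMF, ReturnTable, SupportGrid, project_weights
from .imputation import knn_impute
from .simulator import (
    TabularMDP,
    as_policy_matrix,
    build_empirical_mdp,
    sample_episode,
    split_by_patient,
)
from .speedy_cdrl import TrainConfig, speedy_control
from .state_repr import (
    assign_states,
    extract_policy,
    fit_candidates,
    relabel_states,
    select_representation,
    standardize,
)

__all__ = [
    "EvalReport",
    "OutcomeClass",
    "ranked_stochastic_policy",
    "rollout_metrics",
    "classify_return_distribution",
    "generalization_experiment",
    "PipelineConfig",
    "run_full_pipeline",
]


class OutcomeClass(str, Enum):
    NEGATIVE = "negative"
    BIMODAL = "bimodal"
    POSITIVE = "positive"
    SAFE = "safe"


@dataclass
class EvalReport:
    """Monte-Carlo rollout summary."""

    mean_return: float
    recovery_rate: float
    n_episodes: int
    n_censored: int
    seed: Optional[int]
    returns_by_initial_state: Dict[int, CategoricalPMF] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "mean_return": self.mean_return,
            "recovery_rate": self.recovery_rate,
            "n_episodes": self.n_episodes,
            "n_censored": self.n_censored,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def ranked_stochastic_policy(eta: ReturnTable, valid_actions) -> np.ndarray:
    """Rank valid actions by expected return; weight rank r by 2^-(r+1).

    Weights are renormalized to sum to one over the m valid actions, so the
    leading probabilities approach 1/2, 1/4, ... as m grows.  This breaks
    the loops a deterministic near-optimal policy can fall into.
    """
    exps = eta.expectations()
    n_states = len(valid_actions)
    n_actions = 1 + max(int(np.max(a)) if len(a) else 0 for a in valid_actions)
    policy = np.zeros((n_states, n_actions))
    for x in range(n_states):
        va = np.asarray(valid_actions[x], dtype=int)
        if va.size == 0:
            raise ValueError(f"state {x} has no valid action")
        vals = np.array([exps[eta.index[(x, int(a))]] for a in va])
        order = np.lexsort((va, -vals))  # ties -> lower action index first
        w = 0.5 ** (np.arange(va.size) + 1)
        w /= w.sum()
        policy[x, va[order]] = w
    return policy


def rollout_metrics(
    env: TabularMDP,
    policy,
    n_episodes: int = 10_000,
    gamma: float = 0.99,
    h_max: int = 500,
    seed: Optional[int] = None,
    grid: Optional[SupportGrid] = None,
) -> EvalReport:
    """Simulate episodes from random initial states and summarize them.

    Recovery rate is the fraction of episodes absorbed in the recovered
    outcome (censored episodes count as non-recovered); the mean return is
    discounted with ``gamma``.  When ``grid`` is given, per-initial-state
    empirical return distributions are projected onto it and attached.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    rng = np.random.default_rng(seed)
    pol = as_policy_matrix(policy, env)
    returns: List[float] = []
    recovered = 0
    censored = 0
    by_state: Dict[int, List[float]] = {}
    for _ in range(n_episodes):
        ep = sample_episode(env, pol, h_max=h_max, rng=rng, policy_matrix_checked=pol)
        g = ep.discounted_return(gamma)
        returns.append(g)
        if ep.outcome == "recovered":
            recovered += 1
        elif ep.outcome == "censored":
            censored += 1
        if grid is not None:
            by_state.setdefault(ep.states[0], []).append(g)
    dists = {}
    if grid is not None:
        for x, gs in by_state.items():
            w = np.full(len(gs), 1.0 / len(gs))
            dists[x] = CategoricalPMF(grid, project_weights(grid, gs, w))
    return EvalReport(
        mean_return=float(np.mean(returns)),
        recovery_rate=recovered / n_episodes,
        n_episodes=n_episodes,
        n_censored=censored,
        seed=seed,
        returns_by_initial_state=dists,
    )


def classify_return_distribution(
    pmf: CategoricalPMF,
    grid: SupportGrid,
    death_cut: float = 0.5,
    safe_cut: float = 0.95,
    bimodal_cut: float = 0.4,
) -> OutcomeClass:
    """Classify a return distribution by its death/recovery mass.

    Death probability is the mass on negative atoms, recovery the mass on
    positive atoms; an atom at exactly zero contributes half to each.  Rules
    are applied in order: negative (death > 0.5), safe (recovery > 0.95),
    bimodal (both >= 0.4), positive otherwise — a total, exclusive
    classification.
    """
    if not grid.same_as(pmf.grid):
        raise ValueError("grid mismatch")
    atoms = grid.atoms
    p = pmf.probs
    zero = atoms == 0
    death = float(p[atoms < 0].sum() + 0.5 * p[zero].sum())
    recov = float(p[atoms > 0].sum() + 0.5 * p[zero].sum())
    if death > death_cut:
        return OutcomeClass.NEGATIVE
    if recov > safe_cut:
        return OutcomeClass.SAFE
    if min(death, recov) >= bimodal_cut:
        return OutcomeClass.BIMODAL
    return OutcomeClass.POSITIVE


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:  # surface the failing stage by name
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


@dataclass
class PipelineConfig:
    """End-to-end pipeline: synth -> impute -> discretize -> train -> eval."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    k_grid: Optional[Tuple[int, ...]] = None  # default: (cohort.k_true,)
    n_restarts: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)
    split_frac: float = 0.8
    n_eval_episodes: int = 2000
    h_max: int = 500
    coverage_threshold: float = 15.0
    knn_k: int = 10
    seed: int = 0


def run_full_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage and return the artifact bundle.

    Bundle keys: ``cohort``, ``representation``, ``coverage_report``,
    ``traj_discrete``, ``mdp_train``, ``mdp_test``, ``eta``, ``greedy``,
    ``policy``, ``clinician``, ``reports`` and ``summary``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    with _stage("synth"):
        cohort = generate_cohort(config.cohort)
    with _stage("impute"):
        features = cohort["features"]
        if features.missing_fraction > 0:
            features = knn_impute(features, k=config.knn_k)
    with _stage("standardize"):
        Z, std_params = standardize(features.values)
    with _stage("discretize"):
        k_grid = config.k_grid or (config.cohort.k_true,)
        candidates = fit_candidates(
            Z, k_grid, n_restarts=config.n_restarts, seed=seeds[0],
            standardization=std_params,
        )
        report = select_representation(
            Z,
            cohort["traj"],
            candidates,
            n_actions=config.cohort.n_actions,
            gamma=config.train.gamma,
            threshold=config.coverage_threshold,
            seed=seeds[1],
        )
        rep = report.selected
        states = assign_states(Z, rep)
        dtraj = relabel_states(cohort["traj"], states)
    with _stage("split"):
        train_traj, test_traj = split_by_patient(
            dtraj, train_frac=config.split_frac, seed=seeds[2]
        )
        mdp_train = build_empirical_mdp(train_traj, rep.n_states, config.cohort.n_actions)
        mdp_test = build_empirical_mdp(test_traj, rep.n_states, config.cohort.n_actions)
    with _stage("clinician"):
        clinician = extract_policy(train_traj, rep.n_states, config.cohort.n_actions)
    with _stage("train"):
        train_cfg = config.train
        if train_cfg.seed is None:
            from dataclasses import replace

            train_cfg = replace(train_cfg, seed=seeds[3])
        eta, greedy, diag = speedy_control(mdp_train, train_cfg)
    with _stage("evaluate"):
        policy = ranked_stochastic_policy(eta, mdp_train.valid_actions)
        reports = {}
        for name, env, pol, seed in [
            ("agent_train", mdp_train, policy, seeds[4]),
            ("agent_test", mdp_test, policy, seeds[5]),
            ("clinician_train", mdp_train, clinician, seeds[6]),
            ("clinician_test", mdp_test, clinician, seeds[7]),
        ]:
            reports[name] = rollout_metrics(
                env,
                pol,
                n_episodes=config.n_eval_episodes,
                gamma=config.train.gamma,
                h_max=config.h_max,
                seed=seed,
            )
    summary = {
        name: {"recovery_rate": r.recovery_rate, "mean_return": r.mean_return}
        for name, r in reports.items()
    }
    summary["n_states"] = rep.n_states
    summary["train_iterations"] = diag["iterations"]
    return {
        "cohort": cohort,
        "representation": rep,
        "coverage_report": report,
        "traj_discrete": dtraj,
        "mdp_train": mdp_train,
        "mdp_test": mdp_test,
        "eta": eta,
        "greedy": greedy,
        "policy": policy,
        "clinician": clinician,
        "reports": reports,
        "diagnostics": diag,
        "summary": summary,
    }


def generalization_experiment(
    cohort_config: CohortConfig,
    k_grid: Sequence[int],
    n_repeats: int = 10,
    seed: Optional[int] = None,
    n_restarts: int = 1,
    train_config: Optional[TrainConfig] = None,
    n_eval_episodes: int = 2000,
    h_max: int = 500,
) -> pd.DataFrame:
    """Train/test recovery rates across cluster counts and random splits.

    The cohort is generated once; each repeat draws a fresh patient-level
    80/20 split, fits a representation per K, trains on the train simulator
    and evaluates the ranked stochastic policy on both simulators.
    """
    cohort = generate_cohort(cohort_config)
    Z, std_params = standardize(
        (
            knn_impute(cohort["features"])
            if cohort["features"].missing_fraction > 0
            else cohort["features"]
        ).values
    )
    base_cfg = train_config or TrainConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    from dataclasses import replace

    for rep_i, child in enumerate(ss.spawn(n_repeats)):
        sub = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4 + len(k_grid))]
        for ki, K in enumerate(k_grid):
            cands = fit_candidates(
                Z, [K], n_restarts=n_restarts, seed=sub[4 + ki],
                standardization=std_params,
            )
            sel = select_representation(
                Z,
                cohort["traj"],
                cands,
                n_actions=cohort_config.n_actions,
                gamma=base_cfg.gamma,
                seed=sub[0],
            )
            states = assign_states(Z, sel.selected)
            dtraj = relabel_states(cohort["traj"], states)
            train_traj, test_traj = split_by_patient(dtraj, 0.8, seed=sub[1])
            mdp_tr = build_empirical_mdp(train_traj, K, cohort_config.n_actions)
            mdp_te = build_empirical_mdp(test_traj, K, cohort_config.n_actions)
            eta, _, _ = speedy_control(mdp_tr, replace(base_cfg, seed=sub[2]))
            pol = ranked_stochastic_policy(eta, mdp_tr.valid_actions)
            r_tr = rollout_metrics(
                mdp_tr, pol, n_eval_episodes, base_cfg.gamma, h_max, seed=sub[3]
            )
            r_te = rollout_metrics(
                mdp_te, pol, n_eval_episodes, base_cfg.gamma, h_max, seed=sub[3] + 1
            )
            rows.append(
                {
                    "K": K,
                    "repeat": rep_i,
                    "train_recovery": r_tr.recovery_rate,
                    "test_recovery": r_te.recovery_rate,
                    "train_mean_return": r_tr.mean_return,
                    "test_mean_return": r_te.mean_return,
                }
            )
    return pd.DataFrame(rows)
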