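import numpy as np
import pandas as pd
import pytest

from riskpol.cohort_synth import (
    CohortConfig,
    behavior_policy,
    generate_cohort,
    generate_latent_mdp,
    perturb_kernel,
    sample_trajectories,
)
from riskpol.simulator import make_random_mdp
from riskpol.state_repr import (
    Representation,
    assign_states,
    coverage,
    coverage_from_halves,
    dp_policy_evaluation,
    extract_policy,
    fit_candidates,
    relabel_states,
    select_representation,
    standardize,
    value_iteration,
)
from conftest import deterministic_chain, toy_trajectory, two_point_mdp


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.5, size=(100, 4))
        Z, params = standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_already_standardized_unchanged(self):
        X = np.array([[-1.0, 1.0], [1.0, -1.0]])
        Z, _ = standardize(X)
        np.testing.assert_allclose(Z, X, atol=1e-9)

    def test_population_convention(self):
        Z, _ = standardize(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(Z, [[-1.0], [1.0]])

    def test_constant_feature_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            Z, _ = standardize(np.array([[1.0, 5.0], [2.0, 5.0]]))
        np.testing.assert_array_equal(Z[:, 1], 0.0)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.array([[np.nan, 1.0], [0.0, 2.0]]))


class TestCandidates:
    def test_candidate_count(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        cands = fit_candidates(X, [2, 3, 4], n_restarts=5, seed=0)
        assert len(cands) == 15
        assert sorted({c.n_states for c in cands}) == [2, 3, 4]

    def test_separable_blobs(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-10, 0.5, (30, 2)), rng.normal(10, 0.5, (30, 2))])
        rep = fit_candidates(X, [2], n_restarts=1, seed=0)[0]
        labels = assign_states(X, rep)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        a = fit_candidates(X, [2, 3], n_restarts=3, seed=9)
        b = fit_candidates(X, [2, 3], n_restarts=3, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.centers, rb.centers)

    def test_k_above_n_skipped_with_warning(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.warns(UserWarning, match="skipping"):
            cands = fit_candidates(X, [2, 10], n_restarts=1, seed=0)
        assert {c.n_states for c in cands} == {2}


class TestAssign:
    def test_center_maps_to_itself(self):
        rep = Representation(np.array([[0.0, 0.0], [5.0, 5.0]]), seed=0)
        assert assign_states(np.array([[5.0, 5.0]]), rep)[0] == 1

    def test_tie_goes_to_lowest_index(self):
        rep = Representation(np.array([[-1.0], [1.0]]), seed=0)
        assert assign_states(np.array([[0.0]]), rep)[0] == 0

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        rep = fit_candidates(X, [3], 1, seed=0)[0]
        s1 = assign_states(X, rep)
        s2 = assign_states(rep.centers[s1], rep)
        np.testing.assert_array_equal(s1, s2)

    def test_dim_mismatch(self):
        rep = Representation(np.array([[0.0, 0.0], [1.0, 1.0]]), seed=0)
        with pytest.raises(ValueError):
            assign_states(np.zeros((3, 5)), rep)


class TestExtractPolicy:
    def test_single_observation(self):
        traj = pd.DataFrame(
            [dict(patient_id=0, t=0, state=0, action=3, next_state=-1, outcome="recovered")]
        )
        pol = extract_policy(traj, n_states=1, n_actions=5)
        assert pol.probs[0, 3] == 1.0

    def test_count_normalization(self):
        rows = [
            dict(patient_id=0, t=0, state=0, action=0, next_state=0, outcome="recovered"),
            dict(patient_id=0, t=1, state=0, action=0, next_state=0, outcome="recovered"),
            dict(patient_id=0, t=2, state=0, action=1, next_state=0, outcome="recovered"),
            dict(patient_id=0, t=3, state=0, action=2, next_state=-1, outcome="recovered"),
        ]
        pol = extract_policy(pd.DataFrame(rows), n_states=1, n_actions=3)
        np.testing.assert_allclose(pol.probs[0], [0.5, 0.25, 0.25])
        assert pol.probs.sum() == 1.0

    def test_unvisited_states_zero_rows(self):
        pol = extract_policy(toy_trajectory(), n_states=4, n_actions=2)
        np.testing.assert_array_equal(pol.states_present, [True, True, False, False])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_policy(pd.DataFrame(columns=["state", "action"]), 2)


class TestDP:
    def test_immediate_recovery_value_100(self):
        mdp = two_point_mdp(1.0)
        v = dp_policy_evaluation(mdp, np.array([0]), gamma=0.99)
        assert v[0] == pytest.approx(100.0, abs=1e-4)

    def test_chain_closed_form(self):
        mdp = deterministic_chain(3)
        v = dp_policy_evaluation(mdp, np.array([0, 0, 0]), gamma=0.99)
        assert v[0] == pytest.approx(100 * 0.99**2, abs=1e-4)

    def test_fifty_fifty_zero(self):
        mdp = two_point_mdp(0.5)
        v = dp_policy_evaluation(mdp, np.array([0]), gamma=0.99)
        assert v[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_linear_solve_oracle(self):
        # independent oracle: (I - gamma * P_pi) v = r_pi
        for seed in range(5):
            mdp = make_random_mdp(10, 3, seed=seed)
            rng = np.random.default_rng(seed)
            pol = rng.dirichlet(np.ones(3), size=10)
            from riskpol.simulator import as_policy_matrix

            P = np.einsum("xa,xay->xy", as_policy_matrix(pol, mdp), mdp.probs)
            r = P @ mdp.terminal_rewards()
            v_exact = np.linalg.solve(np.eye(10) - 0.99 * P[:, :10], r)
            v_iter = dp_policy_evaluation(mdp, pol, gamma=0.99, tol=1e-10)
            np.testing.assert_allclose(v_iter, v_exact, atol=1e-6)

    def test_value_iteration_greedy_consistent(self):
        mdp = make_random_mdp(8, 3, seed=1)
        v, pol = value_iteration(mdp, gamma=0.99)
        # greedy policy evaluates back to v*
        v_pol = dp_policy_evaluation(mdp, pol, gamma=0.99, tol=1e-10)
        np.testing.assert_allclose(v_pol, v, atol=1e-5)


class TestCoverage:
    def test_equal_values(self):
        assert coverage(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 1.0

    def test_half_within_threshold(self):
        assert coverage(np.array([0.0, 50.0]), np.array([10.0, 80.0]), 15) == 0.5

    def test_zero_threshold(self):
        assert coverage(np.array([1.0, 2.0]), np.array([1.0, 3.0]), 0.0) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        v1, v2 = rng.normal(size=50) * 30, rng.normal(size=50) * 30
        cs = [coverage(v1, v2, t) for t in (5, 15, 30, 60)]
        assert cs == sorted(cs)

    def test_nan_states_excluded(self):
        v1 = np.array([0.0, np.nan, 5.0])
        v2 = np.array([0.0, 1.0, 100.0])
        assert coverage(v1, v2, 15) == 0.5

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            coverage(np.array([np.nan]), np.array([1.0]))


class TestRelabel:
    def test_relabel_preserves_terminals(self):
        traj = toy_trajectory()
        out = relabel_states(traj, np.array([1, 0, 1, 1]))
        assert list(out["state"]) == [1, 0, 1, 1]
        assert list(out["next_state"]) == [0, -1, 1, -2]


class TestSelectRepresentation:
    def _cohort(self, seed=0, n=300):
        cfg = CohortConfig(
            n_patients=n, n_features=5, k_true=3, noise_scale=0.2, seed=seed,
            missing_rate=0.0,
        )
        return cfg, generate_cohort(cfg)

    def test_single_candidate_selected(self):
        cfg, cohort = self._cohort()
        Z, _ = standardize(cohort["features"].values)
        cands = fit_candidates(Z, [3], 1, seed=0)
        report = select_representation(Z, cohort["traj"], cands, n_actions=cfg.n_actions, seed=0)
        assert report.selected is cands[0]
        assert ((report.table["coverage"] >= 0) & (report.table["coverage"] <= 1)).all()

    def test_reproducible(self):
        cfg, cohort = self._cohort()
        Z, _ = standardize(cohort["features"].values)
        cands = fit_candidates(Z, [2, 3], 2, seed=1)
        r1 = select_representation(Z, cohort["traj"], cands, n_actions=cfg.n_actions, seed=5)
        r2 = select_representation(Z, cohort["traj"], cands, n_actions=cfg.n_actions, seed=5)
        assert r1.selected_index == r2.selected_index
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_identical_halves_high_coverage_and_perturbed_lower(self):
        cfg = CohortConfig(n_patients=600, k_true=6, seed=3)
        mdp = generate_latent_mdp(cfg)
        beh = behavior_policy(mdp, 0.5)
        t1 = sample_trajectories(mdp, beh, 600, seed=31)
        t2 = sample_trajectories(mdp, beh, 600, seed=32)
        t3 = sample_trajectories(perturb_kernel(mdp, 0.6, seed=3), beh, 600, seed=33)
        c_same = coverage_from_halves(t1, t2, cfg.k_true)
        c_pert = coverage_from_halves(t1, t3, cfg.k_true)
        assert c_same >= 0.95
        assert c_pert < c_same

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_representation(np.zeros((2, 2)), toy_trajectory(), [], seed=0)
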