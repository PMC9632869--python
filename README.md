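# riskpol

Risk-aware treatment-policy learning from ICU-style trajectory tables, end
to end:

1. **Imputation** (`riskpol.imputation`) — kNN matrix completion with a
   missingness-aware dissimilarity: per coordinate,
   `(x_i - y_i)^2 / (p_i + (x_i - y_i)^2)` when both values are observed and
   a fixed penalty `a` otherwise. Neighbor queries use the square root of
   the summed dissimilarity, which is a true metric exactly when
   `a >= 1/4` (so KD-/ball-tree indexing is admissible). Default scales are
   twice each feature's variance (motivated by `E[(X - Y)^2] = 2V` for
   i.i.d. X, Y), default `a = 1`. Includes a mean-imputation baseline, an
   RSSE metric, and an orthonormally embedded Swiss-roll completion
   benchmark.
2. **State representation** (`riskpol.state_repr`) — feature
   standardization, repeated k-means candidate generation, empirical
   behavior-policy extraction, dynamic-programming policy evaluation, and a
   *coverage heuristic* for choosing among candidate discretizations: split
   patients into two halves, evaluate the first half's behavior policy on
   both halves' empirical MDPs, and score the fraction of shared states
   whose values agree within 15 (on the [-100, 100] value scale).
3. **Simulator** (`riskpol.simulator`) — an empirical MDP estimated from
   discretized trajectories: K states plus absorbing recovered/died
   outcomes, per-state valid-action subsets (the observed subset of the
   5 x 5 dose grid), terminal-only rewards of +100/-100, and a gym-style
   episodic interface with horizon-cap censoring.
4. **Learning** (`riskpol.distributions`, `riskpol.speedy_cdrl`) —
   synchronous speedy categorical distributional Q-learning: return
   distributions on 51 atoms over [-100, 100], the clip-and-interpolate
   categorical projection, sup-Cramér stopping, and the speedy
   two-target extrapolated update (signed measures internally,
   clip-renormalized at readout). A plain categorical Q-learning loop is
   included as the speed baseline, plus an expected-operator fixed-point
   solver used for convergence benchmarking.
5. **Evaluation** (`riskpol.evaluation`) — ranked stochastic deployment
   policies (best action w.p. ~1/2, second ~1/4, ...), Monte-Carlo rollout
   metrics (recovery rate, mean discounted return), outcome classification
   of return distributions (negative / bimodal / positive / safe), a
   train/test generalization experiment, and a single-call full pipeline.
6. **Synthetic cohorts** (`riskpol.cohort_synth`) — a seeded generator with
   a known ground-truth MDP (action-dependent recovery/death hazards,
   Dirichlet kernels, valid-action subsets), cluster-structured continuous
   features (53 by default), MCAR missingness (39% by default), and a
   behavior policy of tunable quality, so every downstream stage can be
   tested against ground truth.

## CLI

```bash
riskpol synth --n-patients 500 --k-true 8 --missing-rate 0.39 --seed 1 --out-prefix cohort
riskpol impute cohort_features.csv --out imputed.csv --k 10 --penalty-a 1.0
riskpol select imputed.csv cohort_traj.csv --k-grid 4,8,16 --restarts 5 --out rep.json
riskpol build-sim imputed.csv cohort_traj.csv rep.json --split 0.8 --out-prefix sim
riskpol train sim_train.h5 --algo speedy --max-iter 1000 --delta 0.05 --out eta.h5
riskpol evaluate sim_train.h5 eta.h5 --n-episodes 10000 --out report.json
riskpol pipeline --n-patients 500 --seed 1 --out summary.json
riskpol experiment --k-grid 4,8 --repeats 10 --out experiment.csv
```

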