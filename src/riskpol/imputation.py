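"""Missing-value imputation with a missingness-aware dissimilarity.

The dissimilarity between two feature vectors sums, per coordinate, a
bounded squared-difference term ``d^2 / (scale + d^2)`` when both values are
observed and a fixed penalty ``a`` when either is missing.  Neighbor queries
use the square root of that sum, which is a true metric whenever
``a >= 1/4`` (each per-coordinate root term is subadditive and the observed
term is bounded by 1, so the missing-value triangle cases need
``1 <= 2 sqrt(a)``); this is what makes KD-/ball-tree indexing admissible.

Matrices are held as float arrays with NaN marking missing entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ObservationMatrix",
    "MetricParams",
    "default_metric_params",
    "pair_dissimilarity",
    "tree_metric",
    "triangle_violation_exists",
    "triangle_threshold_search",
    "knn_impute",
    "mean_impute",
    "rsse",
    "swiss_roll_benchmark",
    "scaling_identity_ratio",
    "drop_high_missing",
]


class ObservationMatrix:
    """Observations x features with explicit missingness (NaN entries)."""

    def __init__(self, values: np.ndarray, feature_names: Optional[Sequence[str]] = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (observations x features)")
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(values.shape[1])]
        feature_names = list(feature_names)
        if len(feature_names) != values.shape[1]:
            raise ValueError("feature_names length does not match columns")
        fully_missing = np.where(np.all(np.isnan(values), axis=0))[0]
        if fully_missing.size:
            names = [feature_names[j] for j in fully_missing]
            raise ValueError(f"features entirely missing: {names}")
        self.values = values
        self.feature_names = feature_names

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask, True where a value is present."""
        return ~np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def copy(self) -> "ObservationMatrix":
        return ObservationMatrix(self.values.copy(), list(self.feature_names))

    # -- delimited-text round trip (empty field = missing) ------------------
    def to_csv(self, path, metadata_path=None) -> None:
        pd.DataFrame(self.values, columns=self.feature_names).to_csv(path, index=False)
        if metadata_path is not None:
            meta = {"feature_names": self.feature_names, "n_obs": self.n_obs}
            Path(metadata_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ObservationMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=float), list(df.columns))


@dataclass(frozen=True)
class MetricParams:
    """Per-feature scales and the missing-value penalty ``a``."""

    scales: np.ndarray
    penalty: float = 1.0

    def __post_init__(self):
        scales = np.asarray(self.scales, dtype=float)
        if np.any(scales <= 0):
            raise ValueError("all scales must be strictly positive")
        if not 0.25 <= self.penalty <= 1.0:
            raise ValueError("penalty a must lie in [1/4, 1]")
        object.__setattr__(self, "scales", scales)


def default_metric_params(
    m: ObservationMatrix, penalty: float = 1.0, variance: str = "population"
) -> MetricParams:
    """Scales set to twice the observed variance of each feature, ``a = 1``.

    Motivated by ``E[(X - Y)^2] = 2 V`` for i.i.d. X, Y with variance V: the
    bounded term then equals 1/2 in expectation for unrelated observations.
    """
    if variance not in ("population", "sample"):
        raise ValueError("variance must be 'population' or 'sample'")
    ddof = 0 if variance == "population" else 1
    obs = m.observed
    counts = obs.sum(axis=0)
    short = np.where(counts < 2)[0]
    if short.size:
        names = [m.feature_names[j] for j in short]
        raise ValueError(f"features with fewer than 2 observed values: {names}")
    var = np.array(
        [np.var(m.values[obs[:, j], j], ddof=ddof) for j in range(m.n_features)]
    )
    zero = np.where(var <= 0)[0]
    if zero.size:
        names = [m.feature_names[j] for j in zero]
        raise ValueError(f"constant features give zero scale: {names}")
    return MetricParams(scales=2.0 * var, penalty=penalty)


def _coord_terms(x: np.ndarray, y: np.ndarray, params: MetricParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape != params.scales.shape:
        raise ValueError("vector/params dimension mismatch")
    both = ~np.isnan(x) & ~np.isnan(y)
    d2 = np.where(both, x - y, 0.0) ** 2
    return np.where(both, d2 / (params.scales + d2), params.penalty)


def pair_dissimilarity(x, y, params: MetricParams) -> float:
    """Sum over coordinates of the bounded/penalized dissimilarity terms.

    Lies in ``[0, n]``; each both-observed coordinate contributes strictly
    less than 1, each coordinate with a missing value contributes exactly
    ``a``.
    """
    return float(_coord_terms(x, y, params).sum())


def tree_metric(x, y, params: MetricParams) -> float:
    """``sqrt`` of :func:`pair_dissimilarity`; a metric for ``a >= 1/4``."""
    return float(np.sqrt(_coord_terms(x, y, params).sum()))


# ---------------------------------------------------------------------------
# triangle-inequality threshold search
# ---------------------------------------------------------------------------

def _triple_components(
    n_random: int, rng: np.random.Generator, n_features: int = 4
) -> Tuple[np.ndarray, np.ndarray]:
    """Random triples, reduced per pair to (sum of observed terms, #missing).

    For a fixed triple the candidate metric is ``sqrt(S + a * m)`` with S the
    observed-coordinate sum and m the missing-coordinate count, so violations
    can be re-evaluated across penalties without regenerating data.
    """
    X = rng.standard_cauchy((n_random, 3, n_features)) * rng.choice(
        [0.1, 1.0, 10.0, 1000.0], size=(n_random, 1, 1)
    )
    miss = rng.random((n_random, 3, n_features)) < rng.uniform(
        0.0, 0.8, size=(n_random, 1, 1)
    )
    scales = np.ones(n_features)
    S = np.empty((n_random, 3))
    M = np.empty((n_random, 3), dtype=int)
    pairs = [(0, 1), (1, 2), (0, 2)]
    for p, (i, j) in enumerate(pairs):
        both = ~miss[:, i, :] & ~miss[:, j, :]
        d2 = np.where(both, X[:, i, :] - X[:, j, :], 0.0) ** 2
        S[:, p] = np.where(both, d2 / (scales + d2), 0.0).sum(axis=1)
        M[:, p] = (~both).sum(axis=1)
    return S, M


def _adversarial_components() -> Tuple[np.ndarray, np.ndarray]:
    # x = (c), y = (missing), z = (-c) with c -> large: d(x,z) -> 1 while
    # d(x,y) = d(y,z) = sqrt(a); violated exactly when a < 1/4.
    rows_S = []
    rows_M = []
    for c in (10.0, 1e3, 1e6):
        d2 = (2 * c) ** 2
        rows_S.append([0.0, 0.0, d2 / (1.0 + d2)])
        rows_M.append([1, 1, 0])
    return np.array(rows_S), np.array(rows_M, dtype=int)


def triangle_violation_exists(
    penalty: float,
    n_random: int = 100_000,
    seed: Optional[int] = None,
    include_adversarial: bool = True,
    _components: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> bool:
    """Search random + adversarial triples for a triangle-inequality break.

    Checks ``d(x, z) <= d(x, y) + d(y, z)`` (all three orderings) for the
    candidate metric ``sqrt(D)`` at the given penalty.
    """
    if _components is None:
        rng = np.random.default_rng(seed)
        S, M = _triple_components(n_random, rng)
        if include_adversarial:
            Sa, Ma = _adversarial_components()
            S = np.vstack([S, Sa])
            M = np.vstack([M, Ma])
    else:
        S, M = _components
    d = np.sqrt(S + penalty * M)  # columns: d(x,y), d(y,z), d(x,z)
    tol = 1e-12
    viol = (
        (d[:, 2] > d[:, 0] + d[:, 1] + tol)
        | (d[:, 0] > d[:, 1] + d[:, 2] + tol)
        | (d[:, 1] > d[:, 0] + d[:, 2] + tol)
    )
    return bool(viol.any())


def triangle_threshold_search(
    a_grid: Sequence[float],
    n_random: int = 100_000,
    seed: Optional[int] = None,
    include_adversarial: bool = True,
) -> Tuple[float, "pd.DataFrame"]:
    """Smallest grid penalty for which no triangle violation is found.

    Returns ``(threshold, table)`` where the table records, per penalty,
    whether a violating triple was found. One set of random triples is shared
    across penalties (plus the deterministic adversarial family).
    """
    a_grid = sorted(float(a) for a in a_grid)
    if not a_grid:
        raise ValueError("a_grid must be non-empty")
    rng = np.random.default_rng(seed)
    S, M = _triple_components(n_random, rng)
    if include_adversarial:
        Sa, Ma = _adversarial_components()
        S = np.vstack([S, Sa])
        M = np.vstack([M, Ma])
    rows = []
    for a in a_grid:
        violated = triangle_violation_exists(a, _components=(S, M))
        rows.append({"penalty": a, "violated": violated})
    table = pd.DataFrame(rows)
    ok = table.loc[~table["violated"], "penalty"]
    if ok.empty:
        raise ValueError("every penalty in the grid admitted a violation")
    return float(ok.min()), table


# ---------------------------------------------------------------------------
# imputers
# ---------------------------------------------------------------------------

def _pairwise_metric(
    X: np.ndarray, params: MetricParams, chunk: int = 256
) -> np.ndarray:
    """Full pairwise tree-metric matrix, chunked over query rows."""
    n = X.shape[0]
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    out = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diff = Xz[start:stop, None, :] - Xz[None, :, :]
        d2 = diff * diff
        both = obs[start:stop, None, :] & obs[None, :, :]
        f = np.where(both, d2 / (params.scales + d2), params.penalty)
        out[start:stop] = np.sqrt(f.sum(axis=2))
    return out


def _observed_means(m: ObservationMatrix) -> np.ndarray:
    obs = m.observed
    with np.errstate(invalid="ignore"):
        return np.nansum(m.values, axis=0) / obs.sum(axis=0)


def mean_impute(m: ObservationMatrix) -> ObservationMatrix:
    """Replace every missing entry by its feature's observed mean."""
    means = _observed_means(m)
    filled = np.where(m.observed, m.values, means)
    return ObservationMatrix(filled, list(m.feature_names))


def knn_impute(
    m: ObservationMatrix,
    k: int = 10,
    params: Optional[MetricParams] = None,
    weighted: bool = False,
) -> ObservationMatrix:
    """Fill missing entries from the k nearest observations.

    Neighbors are ranked by the missingness-aware tree metric over *all*
    other observations (not per patient).  Pairs with no co-observed
    coordinate have a well-defined penalty distance but carry no
    information, so they are excluded from neighbor selection.  Entry
    (i, j) becomes the mean of feature j over the k nearest informative
    neighbors of i that observe j, falling back to the feature's global
    observed mean when no informative neighbor observes j.  Observed
    entries are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_obs - 1:
        raise ValueError(f"k={k} exceeds available neighbors ({m.n_obs - 1})")
    if params is None:
        params = default_metric_params(m)
    obs = m.observed
    if obs.all():
        return m.copy()
    dist = _pairwise_metric(m.values, params)
    np.fill_diagonal(dist, np.inf)
    co_observed = (obs.astype(np.int8) @ obs.T.astype(np.int8)) > 0
    dist[~co_observed] = np.inf
    means = _observed_means(m)
    filled = m.values.copy()
    rows_missing = np.where(~obs.all(axis=1))[0]
    for i in rows_missing:
        order = np.argsort(dist[i], kind="stable")
        order = order[np.isfinite(dist[i, order])]
        for j in np.where(~obs[i])[0]:
            have = order[obs[order, j]][:k]
            if have.size == 0:
                filled[i, j] = means[j]
            elif weighted:
                w = 1.0 / (dist[i, have] + 1e-12)
                filled[i, j] = float(np.average(m.values[have, j], weights=w))
            else:
                filled[i, j] = float(m.values[have, j].mean())
    return ObservationMatrix(filled, list(m.feature_names))


def drop_high_missing(
    m: ObservationMatrix, threshold: float = 0.9
) -> Tuple[ObservationMatrix, List[str]]:
    """Drop features whose missing fraction exceeds ``threshold``."""
    frac = np.isnan(m.values).mean(axis=0)
    keep = frac <= threshold
    dropped = [n for n, kp in zip(m.feature_names, keep) if not kp]
    if keep.all():
        return m.copy(), []
    kept = ObservationMatrix(
        m.values[:, keep], [n for n, kp in zip(m.feature_names, keep) if kp]
    )
    return kept, dropped


def rsse(
    completed: np.ndarray, truth: np.ndarray, mask_missing: np.ndarray
) -> float:
    """Root of the sum of squared errors over originally-missing entries."""
    completed = np.asarray(completed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask_missing = np.asarray(mask_missing, dtype=bool)
    if completed.shape != truth.shape or completed.shape != mask_missing.shape:
        raise ValueError("shape mismatch")
    err = completed[mask_missing] - truth[mask_missing]
    return float(np.sqrt(np.sum(err * err)))


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

def orthonormal_embedding(dim_out: int, dim_in: int, rng: np.random.Generator) -> np.ndarray:
    """Column-orthonormal (dim_out x dim_in) map from a uniform random matrix.

    QR factorization performs the Gram-Schmidt orthonormalization; the result
    satisfies ``Q.T @ Q = I`` to floating precision.
    """
    if dim_out < dim_in:
        raise ValueError("embedding dimension must be >= input dimension")
    A = rng.uniform(-1.0, 1.0, size=(dim_out, dim_in))
    Q, R = np.linalg.qr(A)
    # fix signs for determinism
    Q = Q * np.sign(np.diag(R))
    return Q


def swiss_roll_benchmark(
    n_points: int = 2000,
    dims: Sequence[int] = (3, 10, 100),
    missing_frac: float = 0.7,
    seed: Optional[int] = None,
    k: int = 10,
) -> pd.DataFrame:
    """Matrix-completion benchmark on an orthonormally embedded Swiss roll.

    A 3-D Swiss roll is mapped into each embedding dimension with a random
    orthonormal map, entries are removed uniformly at random, and the masked
    matrix is completed by mean imputation and by kNN with the
    missingness-aware metric.  Returns an RSSE table (rows: method, columns:
    embedding dimension).
    """
    if not 0.0 < missing_frac < 1.0:
        raise ValueError("missing_frac must be in (0, 1)")
    if any(d < 3 for d in dims):
        raise ValueError("embedding dimensions must be >= 3")
    from sklearn.datasets import make_swiss_roll

    rng = np.random.default_rng(seed)
    roll, _ = make_swiss_roll(n_samples=n_points, random_state=int(rng.integers(2**31)))
    results = {}
    for d in dims:
        Q = orthonormal_embedding(d, 3, rng)
        X = roll @ Q.T
        mask = rng.random(X.shape) < missing_frac
        # keep the ObservationMatrix invariant: no feature fully missing
        for j in np.where(mask.all(axis=0))[0]:  # pragma: no cover
            mask[rng.integers(X.shape[0]), j] = False
        Xm = np.where(mask, np.nan, X)
        m = ObservationMatrix(Xm)
        results[d] = {
            "mean": rsse(mean_impute(m).values, X, mask),
            "knn": rsse(knn_impute(m, k=k).values, X, mask),
        }
    table = pd.DataFrame(results)
    table.index.name = "method"
    return table


def scaling_identity_ratio(
    n: int = 1_000_000, seed: Optional[int] = None, dist: str = "normal"
) -> float:
    """Monte-Carlo estimate of ``E[(X - Y)^2] / V`` for i.i.d. X, Y.

    The identity value 2 motivates setting the metric scales to twice each
    feature's variance.  ``dist`` may be 'normal' (V = 1) or 'exponential'
    (rate 1, V = 1).
    """
    rng = np.random.default_rng(seed)
    if dist == "normal":
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        v = 1.0
    elif dist == "exponential":
        x, y = rng.standard_exponential(n), rng.standard_exponential(n)
        v = 1.0
    else:
        raise ValueError("dist must be 'normal' or 'exponential'")
    return float(np.mean((x - y) ** 2) / v)
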