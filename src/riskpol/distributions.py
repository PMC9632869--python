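"""Categorical return distributions on a fixed support grid.

This module provides the small algebra the distributional learner is built
on: equally spaced support grids, the proximity-splitting categorical
projection, expectations, the Cramér distance between categorical
distributions, and its supremum over a table of state-action pairs.

Probability mass functions (:class:`CategoricalPMF`) are strictly
non-negative; :class:`SignedCategoricalMeasure` relaxes non-negativity while
keeping total mass one, which the speedy update needs for its extrapolated
intermediate iterates.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SupportGrid",
    "CategoricalPMF",
    "SignedCategoricalMeasure",
    "ReturnTable",
    "make_support",
    "projection_matrix",
    "project_weights",
    "project_categorical",
    "expectation",
    "cramer_distance",
    "sup_cramer",
]

MASS_TOL = 1e-9


class SupportGrid:
    """A strictly increasing grid of atoms ``z_1 < z_2 < ... < z_N``.

    Parameters
    ----------
    atoms
        Strictly increasing sequence of at least two support points.
    """

    __slots__ = ("atoms",)

    def __init__(self, atoms: Sequence[float]):
        atoms = np.asarray(atoms, dtype=float)
        if atoms.ndim != 1 or atoms.size < 2:
            raise ValueError("a support grid needs at least 2 atoms")
        if not np.all(np.diff(atoms) > 0):
            raise ValueError("atoms must be strictly increasing")
        self.atoms = atoms
        self.atoms.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.atoms.size)

    @property
    def v_min(self) -> float:
        return float(self.atoms[0])

    @property
    def v_max(self) -> float:
        return float(self.atoms[-1])

    @property
    def spacings(self) -> np.ndarray:
        """Gaps ``z_{i+1} - z_i`` (length ``N - 1``)."""
        return np.diff(self.atoms)

    def same_as(self, other: "SupportGrid") -> bool:
        return self is other or (
            self.atoms.shape == other.atoms.shape
            and bool(np.array_equal(self.atoms, other.atoms))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"SupportGrid(v_min={self.v_min}, v_max={self.v_max}, n={self.n})"


def make_support(v_min: float, v_max: float, n_atoms: int) -> SupportGrid:
    """Equally spaced support with ``z_1 = v_min`` and ``z_N = v_max``.

    The spacing is ``(v_max - v_min) / (n_atoms - 1)``.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    if not v_min < v_max:
        raise ValueError("v_min must be strictly below v_max")
    return SupportGrid(np.linspace(v_min, v_max, int(n_atoms)))


def _check_grid(grid: SupportGrid, other: SupportGrid) -> None:
    if not grid.same_as(other):
        raise ValueError("support grids do not match")


class CategoricalPMF:
    """Probabilities ``p_1..p_N`` aligned with a :class:`SupportGrid`."""

    __slots__ = ("grid", "probs")

    def __init__(self, grid: SupportGrid, probs: Sequence[float]):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (grid.n,):
            raise ValueError("probability vector does not match grid size")
        if np.any(probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        total = probs.sum()
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"probabilities sum to {total!r}, expected 1")
        self.grid = grid
        self.probs = np.clip(probs, 0.0, None)

    @property
    def weights(self) -> np.ndarray:
        return self.probs

    def mean(self) -> float:
        return float(self.probs @ self.grid.atoms)


class SignedCategoricalMeasure:
    """Weights summing to one, allowed to be negative.

    Intermediate iterates of the speedy update are affine combinations of
    PMFs with coefficients that can leave ``[0, 1]``; this type carries them
    without pretending they are probabilities.
    """

    __slots__ = ("grid", "weights")

    def __init__(self, grid: SupportGrid, weights: Sequence[float]):
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (grid.n,):
            raise ValueError("weight vector does not match grid size")
        total = weights.sum()
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"weights sum to {total!r}, expected 1")
        self.grid = grid
        self.weights = weights

    def mean(self) -> float:
        return float(self.weights @ self.grid.atoms)

    def clip_to_pmf(self) -> Tuple[CategoricalPMF, float]:
        """Clip negative weights and renormalize; returns the mass removed."""
        w, removed = clip_renormalize(self.weights)
        return CategoricalPMF(self.grid, w), removed


Distribution = Union[CategoricalPMF, SignedCategoricalMeasure]


def clip_renormalize(weights: np.ndarray) -> Tuple[np.ndarray, float]:
    """Project signed weights onto the simplex by clipping at zero.

    Returns the clipped, renormalized vector and the total negative mass
    that was removed (summed over entries, per row for 2-D input).
    """
    w = np.asarray(weights, dtype=float)
    clipped = np.clip(w, 0.0, None)
    removed = float(np.abs(w - clipped).sum())
    total = clipped.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot renormalize: all mass clipped away")
    return clipped / total, removed


def projection_matrix(grid: SupportGrid, locations: Sequence[float]) -> np.ndarray:
    """Row ``j`` is the categorical projection of a unit point mass at
    ``locations[j]`` onto ``grid``.

    Locations are clipped into ``[v_min, v_max]``; in-range locations split
    their mass between the two bracketing atoms in proportion to proximity.
    """
    z = grid.atoms
    x = np.clip(np.asarray(locations, dtype=float), z[0], z[-1])
    hi = np.searchsorted(z, x, side="left")
    hi = np.clip(hi, 1, z.size - 1)
    lo = hi - 1
    w_hi = (x - z[lo]) / (z[hi] - z[lo])
    mat = np.zeros((x.size, z.size))
    rows = np.arange(x.size)
    np.add.at(mat, (rows, lo), 1.0 - w_hi)
    np.add.at(mat, (rows, hi), w_hi)
    return mat


def project_weights(
    grid: SupportGrid, locations: Sequence[float], weights: Sequence[float]
) -> np.ndarray:
    """Project a weighted collection of point masses onto the grid atoms."""
    w = np.asarray(weights, dtype=float)
    return w @ projection_matrix(grid, locations)


def project_categorical(
    grid: SupportGrid, locations: Sequence[float], masses: Sequence[float]
) -> CategoricalPMF:
    """Categorical projection of a finitely supported distribution.

    ``masses`` must be non-negative and sum to one. Each location is clipped
    to the grid range, then its mass is linearly interpolated between the two
    bracketing atoms; output mass equals input mass.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses < 0):
        raise ValueError("masses must be non-negative")
    if abs(masses.sum() - 1.0) > MASS_TOL:
        raise ValueError("masses must sum to 1")
    return CategoricalPMF(grid, project_weights(grid, locations, masses))


def expectation(dist: Distribution, grid: SupportGrid) -> float:
    """``sum_i w_i z_i`` for a distribution aligned with ``grid``."""
    _check_grid(grid, dist.grid)
    return dist.mean()


def _cramer_rows(w_a: np.ndarray, w_b: np.ndarray, grid: SupportGrid) -> np.ndarray:
    # General non-uniform-spacing form: sum_i (z_{i+1}-z_i) (F_a(z_i)-F_b(z_i))^2
    diff = np.cumsum(w_a - w_b, axis=-1)[..., :-1]
    return np.sqrt(np.sum(grid.spacings * diff * diff, axis=-1))


def cramer_distance(a: Distribution, b: Distribution, grid: SupportGrid) -> float:
    """Cramér (L2-between-CDFs) distance of two categorical distributions."""
    _check_grid(grid, a.grid)
    _check_grid(grid, b.grid)
    return float(_cramer_rows(a.weights, b.weights, grid))


class ReturnTable:
    """Per (state, action) categorical return distributions on one grid.

    Stored densely as a ``(n_pairs, N)`` weight matrix plus an ordered key
    list; during training entries may be signed measures (``signed=True``),
    at readout they are valid PMFs.
    """

    def __init__(
        self,
        grid: SupportGrid,
        keys: Sequence[Tuple[int, int]],
        weights: np.ndarray,
        signed: bool = False,
    ):
        weights = np.asarray(weights, dtype=float)
        keys = [(int(x), int(a)) for x, a in keys]
        if weights.shape != (len(keys), grid.n):
            raise ValueError("weight matrix shape does not match keys/grid")
        sums = weights.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > MASS_TOL):
            raise ValueError("every row must sum to 1")
        if not signed and np.any(weights < -1e-12):
            raise ValueError("negative weights in an unsigned table")
        self.grid = grid
        self.keys = keys
        self.index: Dict[Tuple[int, int], int] = {k: i for i, k in enumerate(keys)}
        if len(self.index) != len(keys):
            raise ValueError("duplicate (state, action) keys")
        self.weights = weights
        self.signed = bool(signed)

    @classmethod
    def constant(
        cls,
        grid: SupportGrid,
        keys: Sequence[Tuple[int, int]],
        atom_value: float = 0.0,
    ) -> "ReturnTable":
        """Table of identical point masses at the atom nearest ``atom_value``."""
        i = int(np.argmin(np.abs(grid.atoms - atom_value)))
        w = np.zeros((len(keys), grid.n))
        w[:, i] = 1.0
        return cls(grid, keys, w)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: Tuple[int, int]) -> bool:
        return tuple(key) in self.index

    def __getitem__(self, key: Tuple[int, int]) -> Distribution:
        row = self.weights[self.index[tuple(key)]]
        if self.signed:
            return SignedCategoricalMeasure(self.grid, row)
        return CategoricalPMF(self.grid, row)

    def expectations(self) -> np.ndarray:
        """Vector of row means, aligned with ``keys``."""
        return self.weights @ self.grid.atoms

    def expectation(self, key: Tuple[int, int]) -> float:
        return float(self.weights[self.index[tuple(key)]] @ self.grid.atoms)

    def to_pmf_table(self) -> Tuple["ReturnTable", float]:
        """Clip-renormalize every row; returns (table, total clipped mass)."""
        if not self.signed and np.all(self.weights >= 0):
            return self, 0.0
        w, removed = clip_renormalize(self.weights)
        return ReturnTable(self.grid, self.keys, w, signed=False), removed

    def copy(self) -> "ReturnTable":
        return ReturnTable(self.grid, self.keys, self.weights.copy(), self.signed)


def sup_cramer(a: ReturnTable, b: ReturnTable) -> float:
    """Maximum Cramér distance over all shared (state, action) pairs."""
    _check_grid(a.grid, b.grid)
    if a.keys != b.keys:
        raise ValueError("return tables are keyed differently")
    return float(_cramer_rows(a.weights, b.weights, a.grid).max())


def sup_cramer_weights(w_a: np.ndarray, w_b: np.ndarray, grid: SupportGrid) -> float:
    """Sup-Cramér on raw aligned weight matrices (training fast path)."""
    return float(_cramer_rows(w_a, w_b, grid).max())
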