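"""The local least squares system for one target gene.

Given a target gene with q missing positions and a set of k neighbor genes
observed at every position the target needs, the system is

    A : k x n_tilde   neighbor values at the target's observed positions
    b : k x q         neighbor values at the target's missing positions
    w : n_tilde       the target's observed values

Plain local least squares solves min_x || A^T x - w ||^2 and predicts each
missing entry as the corresponding column of b dotted with x.  When A A^T is
invertible the solution is (A A^T)^{-1} A w; in the common rank-deficient
regime (k > n_tilde) the minimum-norm least squares solution is used instead.
The shrinkage variants rescale x by the James-Stein-style factor from
:mod:`shrinklls.shrinkage_core` before predicting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_matrix import ExpressionMatrix
from .neighbors import NeighborSet
from .shrinkage_core import ShrinkageConfig, shrink_coefficients

logger = logging.getLogger(__name__)


class SystemConsistencyError(RuntimeError):
    """A neighbor row contains a masked entry the system needs —
    the upstream eligibility filter was violated."""


@dataclass(frozen=True)
class RegressionSystem:
    """The per-target local system (A, b, w) plus bookkeeping.

    ``missing_positions`` are the target's masked condition indices in
    ascending order; column ``j`` of ``b`` predicts ``missing_positions[j]``.
    """

    A: np.ndarray  # (k, n_tilde)
    b: np.ndarray  # (k, q)
    w: np.ndarray  # (n_tilde,)
    k: int
    n_tilde: int
    missing_positions: np.ndarray  # (q,)

    def __post_init__(self) -> None:
        if self.A.shape != (self.k, self.n_tilde):
            raise ValueError(f"A has shape {self.A.shape}, expected ({self.k}, {self.n_tilde})")
        if self.b.shape[0] != self.k or self.b.ndim != 2:
            raise ValueError(f"b has shape {self.b.shape}, expected ({self.k}, q)")
        if self.w.shape != (self.n_tilde,):
            raise ValueError(f"w has shape {self.w.shape}, expected ({self.n_tilde},)")
        if self.n_tilde < 1 or self.b.shape[1] < 1:
            raise ValueError("system needs >= 1 observed and >= 1 missing position")

    @property
    def q(self) -> int:
        return self.b.shape[1]


@dataclass(frozen=True)
class CoefficientVector:
    """Least-squares coefficients and their shrunk counterpart."""

    ls: np.ndarray
    shrunk: np.ndarray
    factor: float


def build_system(
    matrix: ExpressionMatrix,
    neighbors: NeighborSet,
    target_index: int,
    values: np.ndarray | None = None,
) -> RegressionSystem:
    """Assemble (A, b, w) for *target_index* from its neighbor set.

    Rows of A and b follow the neighbor order in *neighbors*.  The split
    into observed (w, columns of A) and missing (columns of b) positions is
    taken from the target's mask in *matrix*.  *values* optionally supplies
    the array neighbor rows are read from (the iterative imputer passes its
    working, fully-filled matrix while keeping the original mask).
    """
    if len(neighbors) == 0:
        raise ValueError("neighbor set is empty")
    vals = matrix.values if values is None else values
    row_mask = matrix.missing_mask[target_index]
    observed = np.flatnonzero(~row_mask)
    missing = np.flatnonzero(row_mask)
    if observed.size == 0 or missing.size == 0:
        raise ValueError(
            "target gene must have at least one observed and one missing position"
        )
    idx = neighbors.neighbor_indices
    if values is None and matrix.missing_mask[idx].any():
        raise SystemConsistencyError(
            f"neighbor of target {target_index} has a masked entry needed by the system"
        )
    A = vals[idx][:, observed]
    b = vals[idx][:, missing]
    w = vals[target_index, observed]
    return RegressionSystem(
        A=A, b=b, w=w, k=idx.size, n_tilde=observed.size, missing_positions=missing
    )


def solve_ls(system: RegressionSystem) -> np.ndarray:
    """Minimize ||A^T x - w||^2; minimum-norm solution when rank-deficient."""
    x, *_ = np.linalg.lstsq(system.A.T, system.w, rcond=None)
    return x


def impute_target(
    system: RegressionSystem,
    coeffs: CoefficientVector,
    use_shrunk: bool,
) -> np.ndarray:
    """Predict the q missing entries: estimate_j = b[:, j] . x."""
    x = coeffs.shrunk if use_shrunk else coeffs.ls
    if x.shape != (system.k,):
        raise ValueError(f"coefficient length {x.size} != k = {system.k}")
    return system.b.T @ x


def fit_and_impute(
    matrix: ExpressionMatrix,
    neighbors: NeighborSet,
    target_index: int,
    shrinkage: ShrinkageConfig | None = None,
    values: np.ndarray | None = None,
) -> tuple[np.ndarray, CoefficientVector]:
    """Full per-target pipeline: build, solve, optionally shrink, predict.

    With an empty neighbor set the estimates fall back to the target's row
    average over observed values (column averages if nothing is observed);
    the returned coefficient vector is then empty with factor 1.
    """
    if len(neighbors) == 0:
        logger.warning(
            "target %d has no eligible neighbors; falling back to row average",
            target_index,
        )
        estimates = row_average_estimates(matrix, target_index)
        empty = np.array([], dtype=np.float64)
        return estimates, CoefficientVector(ls=empty, shrunk=empty, factor=1.0)
    system = build_system(matrix, neighbors, target_index, values=values)
    x = solve_ls(system)
    if shrinkage is not None:
        shrunk, factor = shrink_coefficients(x, system.n_tilde, shrinkage)
    else:
        shrunk, factor = x, 1.0
    coeffs = CoefficientVector(ls=x, shrunk=shrunk, factor=factor)
    estimates = impute_target(system, coeffs, use_shrunk=shrinkage is not None)
    return estimates, coeffs


def row_average_estimates(matrix: ExpressionMatrix, target_index: int) -> np.ndarray:
    """Fallback estimates for a target's missing positions: its observed-value
    mean, or the per-condition means of other genes if nothing is observed."""
    row_mask = matrix.missing_mask[target_index]
    missing = np.flatnonzero(row_mask)
    observed_vals = matrix.values[target_index, ~row_mask]
    if observed_vals.size:
        return np.full(missing.size, float(observed_vals.mean()))
    col_means = np.empty(missing.size)
    for out_i, j in enumerate(missing):
        col = matrix.values[~matrix.missing_mask[:, j], j]
        col_means[out_i] = float(col.mean()) if col.size else 0.0
    return col_means
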