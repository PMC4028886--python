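"""Neighbor-gene selection for a target gene with missing values.

Two selection modes are provided, matching the two families of local least
squares imputers:

* **correlation mode** (LLS/SLLS): rank candidates by the absolute Pearson
  correlation with the target, computed only over the target's observed
  coordinates, and keep the top ``k``;
* **threshold mode** (ILLS): keep every candidate whose length-normalized
  Euclidean distance to the target (again over the target's observed
  coordinates) is at most ``delta = delta_ratio * mean(candidate distances)``.

The correlation uses the sample convention on the p usable coordinates:
both standard deviations and the cross-product sum are divided by p - 1,
the unique pairing under which a gene's correlation with itself is exactly 1.
Candidates that are constant over the usable coordinates have undefined
correlation and are silently skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborSet:
    """Neighbors of one target gene, in selection order.

    ``scores`` holds |r| values (non-increasing) in correlation mode and
    distances (non-decreasing) in threshold mode.
    """

    target_index: int
    neighbor_indices: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "neighbor_indices", np.asarray(self.neighbor_indices, dtype=np.intp)
        )
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))
        if self.target_index in self.neighbor_indices:
            raise ValueError("target gene cannot be its own neighbor")
        if self.neighbor_indices.size != self.scores.size:
            raise ValueError("neighbor_indices and scores must have equal length")

    def __len__(self) -> int:
        return int(self.neighbor_indices.size)


def pearson_similarity(
    target_row: np.ndarray,
    candidate_row: np.ndarray,
    usable_positions: np.ndarray,
) -> float:
    """Pearson correlation between target and candidate over the usable
    coordinates (those observed in the target gene).

    Returns ``nan`` when either vector is constant over the usable
    coordinates — a skip condition for the caller, not an exception.
    Requires at least 3 usable coordinates.
    """
    usable = np.asarray(usable_positions, dtype=np.intp)
    if usable.size < 3:
        raise ValueError(
            f"need >= 3 usable coordinates for a correlation, got {usable.size}"
        )
    x = np.asarray(target_row, dtype=np.float64)[usable]
    y = np.asarray(candidate_row, dtype=np.float64)[usable]
    p = usable.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(float(xc @ xc) / (p - 1))
    sy = np.sqrt(float(yc @ yc) / (p - 1))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc / sx) @ (yc / sy)) / (p - 1)


def _correlations_to_target(
    values: np.ndarray,
    target_index: int,
    candidate_indices: np.ndarray,
    usable: np.ndarray,
) -> np.ndarray:
    """Vectorized Pearson r of each candidate row with the target row over
    the usable columns; nan where a row is constant there."""
    t = values[target_index, usable]
    c = values[candidate_indices][:, usable]
    tc = t - t.mean()
    cc = c - c.mean(axis=1, keepdims=True)
    tn = np.sqrt(float(tc @ tc))
    cn = np.sqrt((cc * cc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (cc @ tc) / (cn * tn)
    r[(cn == 0.0) | (tn == 0.0)] = np.nan
    # |r| <= 1 exactly; rounding past 1 would defeat the index tie-break
    return np.clip(r, -1.0, 1.0)


def select_k_nearest(
    matrix: ExpressionMatrix,
    target_index: int,
    candidate_indices: np.ndarray,
    k: int,
    usable_positions: np.ndarray,
) -> NeighborSet:
    """The k candidates with the largest |Pearson r| to the target.

    Candidates must be fully observed at the usable positions (the caller's
    eligibility filter guarantees this).  Constant candidates are skipped;
    fewer than k neighbors are returned when the pool is small.  Ties in
    |r| break toward the lower row index; output is non-increasing in |r|.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    cands = np.asarray(candidate_indices, dtype=np.intp)
    cands = cands[cands != target_index]
    if cands.size == 0:
        return NeighborSet(target_index, np.array([], dtype=np.intp), np.array([]))
    usable = np.asarray(usable_positions, dtype=np.intp)
    if usable.size < 3:
        raise ValueError(
            f"need >= 3 usable coordinates for correlation ranking, got {usable.size}"
        )
    r = _correlations_to_target(matrix.values, target_index, cands, usable)
    ok = np.isfinite(r)
    if not ok.all():
        logger.debug(
            "target %d: skipped %d constant candidate(s)",
            target_index,
            int((~ok).sum()),
        )
    cands, r = cands[ok], r[ok]
    absr = np.abs(r)
    # sort by descending |r|, ties by ascending row index (lexsort: last key primary)
    order = np.lexsort((cands, -absr))[:k]
    return NeighborSet(target_index, cands[order], absr[order])


def select_by_threshold(
    matrix: ExpressionMatrix,
    target_index: int,
    candidate_indices: np.ndarray,
    delta_ratio: float,
    usable_positions: np.ndarray,
) -> NeighborSet:
    """All candidates within the per-target distance threshold.

    Distance is the length-normalized Euclidean distance over the usable
    coordinates, d_j = sqrt(mean_t (g_target,t - g_j,t)^2), so thresholds
    are comparable across targets with different numbers of observed
    coordinates.  The threshold is delta = delta_ratio * mean(d_j over the
    candidate pool); if no candidate qualifies the single closest one is
    returned.  Output is sorted by increasing distance, ties by row index.
    """
    if not delta_ratio > 0:
        raise ValueError(f"delta_ratio must be > 0, got {delta_ratio}")
    cands = np.asarray(candidate_indices, dtype=np.intp)
    cands = cands[cands != target_index]
    if cands.size == 0:
        return NeighborSet(target_index, np.array([], dtype=np.intp), np.array([]))
    usable = np.asarray(usable_positions, dtype=np.intp)
    if usable.size < 1:
        raise ValueError("need at least one usable coordinate")
    diff = matrix.values[cands][:, usable] - matrix.values[target_index, usable]
    d = np.sqrt((diff * diff).mean(axis=1))
    delta = delta_ratio * float(d.mean())
    keep = d <= delta
    if not keep.any():
        keep = d == d.min()
    cands, d = cands[keep], d[keep]
    order = np.lexsort((cands, d))
    return NeighborSet(target_index, cands[order], d[order])
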