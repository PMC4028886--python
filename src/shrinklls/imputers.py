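"""The three local least squares imputers — LLS, SLLS, ILLS — with optional
James-Stein coefficient shrinkage.

All three share the same per-target core (neighbor selection, a local least
squares fit, prediction of the target's missing entries) and differ in where
neighbors come from:

* **LLS** treats every target independently and draws its k most correlated
  neighbors from the genes observed at every position the target needs.
* **SLLS** imputes genes sequentially in ascending missing-rate order,
  drawing neighbors from the complete submatrix G1; an imputed gene joins
  the candidate pool only if its missing rate is below the reuse threshold
  r0, the mean missing rate over incomplete genes.
* **ILLS** initializes missing entries with row averages and then iterates:
  each pass reselects neighbors by a distance threshold (all genes are
  candidates, since the working matrix is complete) and re-imputes every
  originally-missing entry from the previous pass's filled matrix.

Observed entries are never modified by any imputer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io_matrix import ExpressionMatrix
from .neighbors import select_by_threshold, select_k_nearest
from .regression import fit_and_impute, row_average_estimates
from .shrinkage_core import ShrinkageConfig

logger = logging.getLogger(__name__)

#: k grid commonly swept when tuning the neighbor count for LLS/SLLS.
DEFAULT_K_GRID = (50, 100, 150, 200, 250, 300)


class Method(str, Enum):
    LLS = "lls"
    SLLS = "slls"
    ILLS = "ills"
    ROW_AVERAGE = "row_average"


@dataclass(frozen=True)
class ImputeConfig:
    """Parameters for one imputation run.

    ``k`` (neighbor count) applies to LLS/SLLS; ``delta_ratio``,
    ``max_iterations`` and ``convergence_tol`` apply to ILLS only.
    ``shrinkage=None`` runs the plain (unshrunk) variant.
    """

    method: Method = Method.LLS
    k: int = 150
    delta_ratio: float = 1.0
    max_iterations: int = 5
    convergence_tol: float = 1e-4
    shrinkage: ShrinkageConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not self.delta_ratio > 0:
            raise ValueError(f"delta_ratio must be > 0, got {self.delta_ratio}")
        if self.max_iterations < 1:
            raise ValueError(f"max_iterations must be >= 1, got {self.max_iterations}")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")

    def label(self) -> str:
        prefix = "shr_" if self.shrinkage is not None else ""
        return f"{prefix}{self.method.value}"


@dataclass(frozen=True)
class MissingProfile:
    """Per-gene missing counts/rates and the SLLS reuse threshold r0.

    r0 is the average missing rate over the genes that contain missing
    values: r0 = sum_i c_i / ((m - m1) * n), with m1 the number of complete
    genes.  It is computed once, on the input matrix, and not revised as
    imputed genes are recycled.
    """

    per_gene_missing_count: np.ndarray
    per_gene_missing_rate: np.ndarray
    reuse_threshold: float


def missing_profile(matrix: ExpressionMatrix) -> MissingProfile:
    counts = matrix.missing_mask.sum(axis=1)
    n = matrix.n_conditions
    rates = counts / n
    incomplete = counts > 0
    if incomplete.any():
        r0 = float(counts[incomplete].sum() / (incomplete.sum() * n))
    else:
        r0 = 0.0
    return MissingProfile(
        per_gene_missing_count=counts,
        per_gene_missing_rate=rates,
        reuse_threshold=r0,
    )


@dataclass
class ImputeReport:
    """Run diagnostics an imputer fills in (all optional for callers)."""

    fallback_targets: list[int] = field(default_factory=list)
    visit_order: list[int] = field(default_factory=list)
    reused_genes: list[int] = field(default_factory=list)
    iterations: int = 0
    notices: list[str] = field(default_factory=list)


def _finish(out: ExpressionMatrix) -> ExpressionMatrix:
    assert not np.isnan(out.values).any(), "imputer left a nan behind"
    out.missing_mask = np.zeros(out.shape, dtype=bool)
    return out


def _eligible_candidates(mask: np.ndarray, target_index: int) -> np.ndarray:
    """Genes observed at every position the target's system needs.

    The target's observed positions feed A and its missing positions feed b,
    so together they span all conditions: eligibility reduces to genes with
    no missing entries at all, the target excluded."""
    ok = ~mask.any(axis=1)
    ok[target_index] = False
    return np.flatnonzero(ok)


def lls_impute(
    matrix: ExpressionMatrix,
    config: ImputeConfig | None = None,
    report: ImputeReport | None = None,
) -> ExpressionMatrix:
    """Local least squares imputation; each target gene handled independently.

    For each gene with missing entries (in row order): rank the eligible
    candidate genes by |Pearson r| over the target's observed positions,
    keep the top ``config.k``, fit the local least squares system and
    predict all of the target's missing positions at once.  Estimates never
    feed other targets.  Targets with fewer than 3 observed values (too few
    for a correlation) fall back to their row average.
    """
    config = config or ImputeConfig(method=Method.LLS)
    report = report if report is not None else ImputeReport()
    out = matrix.copy()
    if matrix.is_complete():
        report.notices.append("input matrix is complete; nothing to impute")
        logger.info("lls: input complete, returning unchanged")
        return out
    mask = matrix.missing_mask
    for i in np.flatnonzero(mask.any(axis=1)):
        report.visit_order.append(int(i))
        observed = np.flatnonzero(~mask[i])
        missing = np.flatnonzero(mask[i])
        cands = _eligible_candidates(mask, i)
        if observed.size < 3 or cands.size == 0:
            estimates = row_average_estimates(matrix, i)
            report.fallback_targets.append(int(i))
            logger.warning("lls: target %d imputed by row-average fallback", i)
        else:
            nbrs = select_k_nearest(matrix, i, cands, config.k, observed)
            if len(nbrs) == 0:
                report.fallback_targets.append(int(i))
            estimates, _ = fit_and_impute(matrix, nbrs, i, config.shrinkage)
        out.values[i, missing] = estimates
    return _finish(out)


def slls_impute(
    matrix: ExpressionMatrix,
    config: ImputeConfig | None = None,
    report: ImputeReport | None = None,
) -> ExpressionMatrix:
    """Sequential LLS: impute genes in ascending missing-rate order, recycling
    sub-threshold imputed genes as neighbor candidates.

    The matrix splits into complete genes G1 and incomplete genes G2.  G2 is
    processed by ascending missing rate (ties by row index); each target's
    neighbors come from the current G1.  After imputation a gene joins G1
    if and only if its original missing rate is below r0 (see
    :func:`missing_profile`); above-threshold genes are imputed but never
    reused.  r0 and the ordering are fixed from the input matrix.
    """
    config = config or ImputeConfig(method=Method.SLLS)
    report = report if report is not None else ImputeReport()
    work = matrix.copy()
    if matrix.is_complete():
        report.notices.append("input matrix is complete; nothing to impute")
        logger.info("slls: input complete, returning unchanged")
        return work
    profile = missing_profile(matrix)
    r0 = profile.reuse_threshold
    pool = ~matrix.missing_mask.any(axis=1)  # current G1 membership
    targets = np.flatnonzero(~pool)
    order = np.lexsort((targets, profile.per_gene_missing_rate[targets]))
    for i in targets[order]:
        report.visit_order.append(int(i))
        observed = np.flatnonzero(~work.missing_mask[i])
        missing = np.flatnonzero(work.missing_mask[i])
        cands = np.flatnonzero(pool)
        if observed.size < 3 or cands.size == 0:
            estimates = row_average_estimates(work, i)
            report.fallback_targets.append(int(i))
            if cands.size == 0:
                report.notices.append(f"gene {i}: empty candidate pool, bootstrapped")
                logger.warning("slls: empty G1, bootstrapping gene %d via row average", i)
        else:
            nbrs = select_k_nearest(work, i, cands, config.k, observed)
            if len(nbrs) == 0:
                report.fallback_targets.append(int(i))
            estimates, _ = fit_and_impute(work, nbrs, i, config.shrinkage)
        work.values[i, missing] = estimates
        work.missing_mask[i, missing] = False
        if cands.size == 0:
            # bootstrap gene joins G1 so later targets have a candidate pool
            pool[i] = True
        elif profile.per_gene_missing_rate[i] < r0:
            pool[i] = True
            report.reused_genes.append(int(i))
    return _finish(work)


def ills_impute(
    matrix: ExpressionMatrix,
    config: ImputeConfig | None = None,
    report: ImputeReport | None = None,
) -> ExpressionMatrix:
    """Iterated LLS with threshold-based neighbor selection.

    Iteration 0 fills every missing entry with its gene's observed-value
    average (column averages for fully-missing genes).  Each subsequent
    iteration treats the previous filled matrix as complete: per target it
    selects all genes within the distance threshold (delta_ratio times the
    mean candidate distance, over the target's original observed positions),
    refits the local system with the original observed values as the
    response, and replaces only the originally-missing entries.  Stops when
    the mean absolute change over imputed entries drops below
    ``convergence_tol`` or after ``max_iterations`` passes.
    """
    config = config or ImputeConfig(method=Method.ILLS)
    report = report if report is not None else ImputeReport()
    if matrix.is_complete():
        report.notices.append("input matrix is complete; nothing to impute")
        logger.info("ills: input complete, returning unchanged")
        return matrix.copy()
    orig_mask = matrix.missing_mask
    filled = row_average_impute(matrix)
    work_values = filled.values
    targets = np.flatnonzero(orig_mask.any(axis=1))
    all_rows = np.arange(matrix.n_genes)
    for iteration in range(1, config.max_iterations + 1):
        work_matrix = ExpressionMatrix(
            gene_ids=list(matrix.gene_ids),
            condition_ids=list(matrix.condition_ids),
            values=work_values.copy(),
        )
        new_values = work_values.copy()
        for i in targets:
            observed = np.flatnonzero(~orig_mask[i])
            missing = np.flatnonzero(orig_mask[i])
            if observed.size < 3:
                # too few coordinates for a meaningful local fit; keep the
                # running row-average fill
                if iteration == 1:
                    report.fallback_targets.append(int(i))
                    logger.warning("ills: target %d kept at row-average fallback", i)
                continue
            nbrs = select_by_threshold(
                work_matrix, i, all_rows, config.delta_ratio, observed
            )
            estimates, _ = fit_and_impute(
                matrix, nbrs, i, config.shrinkage, values=work_matrix.values
            )
            new_values[i, missing] = estimates
        change = float(np.abs(new_values[orig_mask] - work_values[orig_mask]).mean())
        work_values = new_values
        report.iterations = iteration
        logger.debug("ills: iteration %d, mean |change| = %.3g", iteration, change)
        if change < config.convergence_tol:
            break
    out = matrix.copy()
    out.values[orig_mask] = work_values[orig_mask]
    return _finish(out)


def row_average_impute(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """The naive baseline: each missing entry becomes its gene's observed-value
    mean; a fully-missing gene gets the per-condition means of the other genes."""
    out = matrix.copy()
    if matrix.is_complete():
        return out
    mask = matrix.missing_mask
    for i in np.flatnonzero(mask.any(axis=1)):
        missing = np.flatnonzero(mask[i])
        out.values[i, missing] = row_average_estimates(matrix, i)
    return _finish(out)


def impute(
    matrix: ExpressionMatrix,
    config: ImputeConfig,
    report: ImputeReport | None = None,
) -> ExpressionMatrix:
    """Dispatch to the imputer named by ``config.method``."""
    dispatch = {
        Method.LLS: lls_impute,
        Method.SLLS: slls_impute,
        Method.ILLS: ills_impute,
    }
    if config.method is Method.ROW_AVERAGE:
        out = row_average_impute(matrix)
        if report is not None and matrix.is_complete():
            report.notices.append("input matrix is complete; nothing to impute")
        return out
    return dispatch[config.method](matrix, config, report)
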