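"""James-Stein shrinkage: the reference estimator and the regression-coefficient
shrinkage transform used by the imputers.

For independent normal observations Y_i ~ N(theta_i, sigma^2), i = 1..k with
known common variance, the James-Stein estimator

    theta_hat_JS = (1 - (k - 2) * sigma^2 / S_Y^2) * Y,   S_Y^2 = sum_i Y_i^2,

dominates the identity estimator Y under squared error loss whenever k >= 3.
More generally any factor (1 - c * sigma^2 / S_Y^2) with 0 < c < 2(k - 2)
dominates, with c = k - 2 minimizing the risk; ``shrink_constant`` exposes c.

The imputers do not shrink raw observations but least-squares regression
coefficients: for a coefficient vector x_hat of length k fitted on a design
with n_tilde observed conditions, each coefficient is scaled by

    factor = 1 - (k - 2) * sigma^2 / (n_tilde * S^2)

where sigma^2 is the variance of the coefficients (x_hat_1..x_hat_k) and
S^2 = sum_i x_hat_i^2 is their squared norm.  The variance-divisor
convention (sample, k - 1, vs population, k) and the optional positive-part
truncation are recorded in :class:`ShrinkageConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class VarianceConvention(str, Enum):
    """Divisor convention for the coefficient variance in the shrinkage factor."""

    SAMPLE = "sample"  # divide by k - 1
    POPULATION = "population"  # divide by k


@dataclass(frozen=True)
class ShrinkageConfig:
    """How the coefficient-shrinkage factor is computed.

    ``variance_convention`` defaults to the sample variance (divisor k - 1),
    the standard estimator, well-defined throughout the k >= 3 regime where
    shrinkage activates.  ``positive_part`` truncates negative factors at 0
    (the classical positive-part Stein remedy); off by default, so small,
    dispersed coefficient vectors can legitimately produce a negative factor.
    """

    variance_convention: VarianceConvention = VarianceConvention.SAMPLE
    positive_part: bool = False

    def coefficient_variance(self, coeffs: np.ndarray) -> float:
        k = coeffs.size
        if k <= 1:
            return 0.0
        ddof = 1 if self.variance_convention is VarianceConvention.SAMPLE else 0
        return float(np.var(coeffs, ddof=ddof))


@dataclass(frozen=True)
class JamesSteinProblem:
    """A k-vector of observations with known noise variance.

    ``shrink_constant`` is the constant c of the generalized estimator;
    ``None`` selects the risk-minimizing c = k - 2.
    """

    observations: np.ndarray
    noise_variance: float = 1.0
    shrink_constant: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "observations", np.asarray(self.observations, dtype=np.float64)
        )
        if self.observations.ndim != 1 or self.observations.size < 1:
            raise ValueError("observations must be a non-empty 1-D vector")
        if not self.noise_variance > 0:
            raise ValueError(f"noise variance must be > 0, got {self.noise_variance}")

    @property
    def k(self) -> int:
        return self.observations.size

    @property
    def c(self) -> float:
        return float(self.k - 2) if self.shrink_constant is None else self.shrink_constant


def james_stein_estimate(problem: JamesSteinProblem) -> np.ndarray:
    """Evaluate the James-Stein estimator (1 - c*sigma^2/S_Y^2) * Y.

    A zero observation vector (S_Y^2 = 0) shrinks to the zero vector by
    convention.  The estimator is computable for any k >= 1; the dominance
    guarantee only holds for k >= 3.
    """
    y = problem.observations
    s2 = float(y @ y)
    if s2 == 0.0:
        return np.zeros_like(y)
    factor = 1.0 - problem.c * problem.noise_variance / s2
    return factor * y


def shrink_coefficients(
    coeffs: np.ndarray,
    n_tilde: int,
    config: ShrinkageConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Shrink a least-squares coefficient vector, returning (shrunk, factor).

    factor = 1 - (k - 2) * sigma^2 / (n_tilde * S^2), with sigma^2 the
    variance of the coefficients under ``config.variance_convention`` and
    S^2 their squared norm.  Degenerate regimes are the identity:
    k <= 2 (the numerator k - 2 vanishes or the classical estimator does
    not apply), zero coefficient variance, and the all-zero vector (S^2 = 0).
    With ``positive_part`` a negative factor is truncated to 0.
    """
    if config is None:
        config = ShrinkageConfig()
    x = np.asarray(coeffs, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("coefficients must be a non-empty 1-D vector")
    if n_tilde < 1:
        raise ValueError(f"n_tilde must be >= 1, got {n_tilde}")
    k = x.size
    if k <= 2:
        return x.copy(), 1.0
    s2 = float(x @ x)
    if s2 == 0.0:
        return x.copy(), 1.0
    sigma2 = config.coefficient_variance(x)
    factor = 1.0 - (k - 2) * sigma2 / (n_tilde * s2)
    if config.positive_part and factor < 0.0:
        factor = 0.0
    return factor * x, factor
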