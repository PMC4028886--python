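"""NRMSE benchmarking protocol: random masking, noise injection, scoring.

The protocol mirrors the standard imputation benchmark: start from a
complete matrix, optionally add i.i.d. Gaussian noise, hide a fixed fraction
of entries uniformly at random, impute them, and score

    NRMSE = sqrt(mean((y_guess - y_ans)^2)) / std(y_ans)

over the hidden entries, where y_ans are the (noisy) true values.  Each
benchmark cell is repeated for several independent rounds and the mean
NRMSE is reported.  Within one round, every method/parameter cell at the
same (missing rate, noise level) sees the same mask — a paired design that
removes mask sampling noise from method comparisons.

Default sweep grids: missing rates 1/5/10/15/20 %, noise standard
deviations 0 to 0.25 in steps of 0.05, neighbor counts 50 to 300 in steps
of 50, five rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imputers import DEFAULT_K_GRID, ImputeConfig, Method, impute
from .io_matrix import ExpressionMatrix

DEFAULT_MISSING_RATES = (0.01, 0.05, 0.10, 0.15, 0.20)
DEFAULT_NOISE_SDS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
DEFAULT_ROUNDS = 5

_SEED_MOD = 2**31 - 1


def _derive_seed(base_seed: int, *streams: int) -> int:
    """Deterministic sub-seed, kept below 2^31."""
    h = int(base_seed) % _SEED_MOD
    for s in streams:
        h = (h * 1_000_003 + int(s) + 1) % _SEED_MOD
    return h


@dataclass(frozen=True)
class MaskRecord:
    """Positions hidden during a benchmark round and their true values."""

    positions: np.ndarray  # (n_masked, 2) of (gene index, condition index)
    true_values: np.ndarray  # (n_masked,)

    def __len__(self) -> int:
        return int(self.true_values.size)


@dataclass
class EvaluationReport:
    """Per-round and mean NRMSE for one (method, rate, noise) benchmark cell."""

    method: str
    k_or_delta: float
    missing_rate: float
    noise_sd: float
    base_seed: int
    per_round_nrmse: list[float] = field(default_factory=list)

    @property
    def mean_nrmse(self) -> float:
        return float(np.mean(self.per_round_nrmse))


def mask_random(
    matrix: ExpressionMatrix, rate: float, seed: int
) -> tuple[ExpressionMatrix, MaskRecord]:
    """Hide ``floor(rate * m * n)`` entries (at least 1) chosen uniformly
    without replacement from a complete matrix.  Reproducible per seed."""
    if not matrix.is_complete():
        raise ValueError("mask_random requires a complete input matrix")
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    m, n = matrix.shape
    count = max(1, int(np.floor(rate * m * n)))
    rng = np.random.default_rng(seed)
    flat = rng.choice(m * n, size=count, replace=False)
    rows, cols = np.unravel_index(flat, (m, n))
    record = MaskRecord(
        positions=np.column_stack([rows, cols]),
        true_values=matrix.values[rows, cols].copy(),
    )
    masked = matrix.copy()
    masked.missing_mask[rows, cols] = True
    masked.values[rows, cols] = np.nan
    return masked, record


def add_noise(matrix: ExpressionMatrix, sd: float, seed: int) -> ExpressionMatrix:
    """Add i.i.d. Gaussian(0, sd^2) noise to every observed entry."""
    if sd < 0:
        raise ValueError(f"noise sd must be >= 0, got {sd}")
    out = matrix.copy()
    if sd == 0.0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=out.shape)
    observed = ~out.missing_mask
    out.values[observed] += noise[observed]
    return out


def nrmse(
    guess: np.ndarray, answer: np.ndarray, ddof: int = 1
) -> float:
    """Root mean squared error normalized by the standard deviation of the
    true values (sample convention by default; ``ddof=0`` for population)."""
    g = np.asarray(guess, dtype=np.float64)
    a = np.asarray(answer, dtype=np.float64)
    if g.shape != a.shape or g.ndim != 1:
        raise ValueError("guess and answer must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 entries to normalize")
    sd = float(np.std(a, ddof=ddof))
    if sd == 0.0:
        raise ValueError("answer vector is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((g - a) ** 2)) / sd)


def score_imputation(
    imputed: ExpressionMatrix, record: MaskRecord, ddof: int = 1
) -> float:
    """NRMSE of an imputed matrix against the mask record's true values."""
    rows, cols = record.positions[:, 0], record.positions[:, 1]
    return nrmse(imputed.values[rows, cols], record.true_values, ddof=ddof)


def run_benchmark(
    matrix: ExpressionMatrix,
    methods: list[ImputeConfig],
    rates: tuple[float, ...] = (0.05,),
    noise_sds: tuple[float, ...] = (0.0,),
    rounds: int = DEFAULT_ROUNDS,
    base_seed: int = 0,
) -> list[EvaluationReport]:
    """Run the full masking/imputation/scoring protocol over a grid.

    For each round i and each (rate, noise sd): noise is injected (seeded
    per round and noise level), a mask is drawn (seeded per round and rate),
    every method imputes the same masked matrix, and NRMSE is computed over
    the hidden entries.  Fully reproducible from ``base_seed``.
    """
    if not matrix.is_complete():
        raise ValueError("run_benchmark requires a complete input matrix")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    reports = {
        (cfg.label(), _param_of(cfg), rate, sd): EvaluationReport(
            method=cfg.label(),
            k_or_delta=_param_of(cfg),
            missing_rate=rate,
            noise_sd=sd,
            base_seed=base_seed,
        )
        for cfg in methods
        for rate in rates
        for sd in noise_sds
    }
    for rnd in range(rounds):
        for sd_idx, sd in enumerate(noise_sds):
            noisy = add_noise(matrix, sd, _derive_seed(base_seed, rnd, 1, sd_idx))
            for rate_idx, rate in enumerate(rates):
                masked, record = mask_random(
                    noisy, rate, _derive_seed(base_seed, rnd, 2, rate_idx)
                )
                for cfg in methods:
                    try:
                        imputed = impute(masked, cfg)
                        value = score_imputation(imputed, record)
                    except Exception as exc:  # add cell context, re-raise
                        raise RuntimeError(
                            f"benchmark cell failed: method={cfg.label()} "
                            f"rate={rate} noise_sd={sd} round={rnd}: {exc}"
                        ) from exc
                    reports[(cfg.label(), _param_of(cfg), rate, sd)].per_round_nrmse.append(
                        value
                    )
    return list(reports.values())


def _param_of(cfg: ImputeConfig) -> float:
    return float(cfg.delta_ratio if cfg.method is Method.ILLS else cfg.k)


def reports_to_frames(
    reports: list[EvaluationReport],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-round table and a summary table of mean NRMSE per cell."""
    rows = [
        {
            "method": r.method,
            "k_or_delta": r.k_or_delta,
            "rate": r.missing_rate,
            "noise_sd": r.noise_sd,
            "round": i,
            "nrmse": v,
        }
        for r in reports
        for i, v in enumerate(r.per_round_nrmse)
    ]
    tidy = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {
                "method": r.method,
                "k_or_delta": r.k_or_delta,
                "rate": r.missing_rate,
                "noise_sd": r.noise_sd,
                "rounds": len(r.per_round_nrmse),
                "mean_nrmse": r.mean_nrmse,
            }
            for r in reports
        ]
    )
    return tidy, summary


def write_reports(reports: list[EvaluationReport], out_dir: str | Path) -> None:
    """Write ``results.tsv`` (per-round) and ``summary.tsv`` (means)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tidy, summary = reports_to_frames(reports)
    tidy.to_csv(out_dir / "results.tsv", sep="\t", index=False, float_format="%.10g")
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.10g")
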