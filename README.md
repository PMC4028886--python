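# shrinklls

Missing-value imputation for gene expression matrices by **local least
squares (LLS) regression**, together with its **sequential (SLLS)** and
**iterated (ILLS)** refinements, each available with **James-Stein
shrinkage** of the regression coefficients — plus the NRMSE benchmarking
protocol used to evaluate imputation methods.

## Who this is for

Microarray and other bulk expression matrices routinely contain more than
5% missing entries, while most downstream analyses (clustering,
classification, network inference) need complete data. Regression-based
imputation exploits the co-expression structure of the data: a *target
gene* with missing values is modeled as a linear combination of similar
genes, and the fitted model predicts the missing entries.

## The model

For a matrix **G** ∈ ℝ^(m×n) (m genes, n conditions, m ≫ n), let the
target gene have ñ observed and q missing positions. From its k most
similar genes (largest |Pearson r|, computed over the target's observed
coordinates only) form

- **A** ∈ ℝ^(k×ñ) — neighbor values at the target's observed positions,
- **b** ∈ ℝ^(k×q) — neighbor values at the target's missing positions,
- **w** ∈ ℝ^ñ — the target's observed values,

solve min_x ‖Aᵀx − w‖² (minimum-norm solution when AAᵀ is singular, the
usual case for k > ñ), and predict the missing entries as **bᵀx̂**.

The shrinkage variants rescale the coefficients before predicting:

    x̂ᴶˢ = (1 − (k−2)·σ² / (ñ·S²)) · x̂,    S² = Σᵢ x̂ᵢ²,

with σ² the variance of the coefficients — a James-Stein-style factor that
pulls dispersed coefficient vectors toward zero (it is exactly 1 for k ≤ 2
or equal coefficients, and always positive since σ² ≤ S²/(k−1)).

- **SLLS** imputes genes in ascending missing-rate order rᵢ = cᵢ/n, drawing
  neighbors from the complete submatrix; an imputed gene is recycled as a
  candidate only if its missing rate is below the threshold r₀, the mean
  missing rate of the incomplete genes.
- **ILLS** initializes missing entries with row averages and iterates,
  selecting neighbors by a distance threshold δ (a ratio of the mean
  candidate distance) instead of a fixed k.

Accuracy is scored as **NRMSE** = √mean[(y_guess − y_ans)²] / std(y_ans)
over the hidden entries, averaged over five independently masked rounds.

## Worked example

Generate a synthetic cluster-correlated matrix (300 genes × 12 conditions,
10 co-expression clusters), benchmark plain vs shrinkage variants at a 5%
missing rate, and impute a file with missing entries:

```
$ shrinklls simulate -o demo.tsv --genes 300 --conditions 12 --seed 1
INFO shrinklls: wrote 300 x 12 synthetic matrix to demo.tsv

$ shrinklls benchmark --input demo.tsv -o demo_results \
      --method lls --method ills --k 50 --compare-shrinkage \
      --rate 0.05 --rounds 5 --seed 1
INFO shrinklls: ills         param=1     rate=0.05 noise=0.00 mean NRMSE=0.3127
INFO shrinklls: lls          param=50    rate=0.05 noise=0.00 mean NRMSE=0.2917
INFO shrinklls: shr_ills     param=1     rate=0.05 noise=0.00 mean NRMSE=0.3138
INFO shrinklls: shr_lls      param=50    rate=0.05 noise=0.00 mean NRMSE=0.2967

$ shrinklls impute demo_missing.tsv -o demo_filled.tsv --method lls --k 50 --shrinkage
INFO shrinklls: imputed 180 missing entries in 300 genes x 12 conditions with shr_lls (k=50, 0 fallback target(s))
```

Each `mean NRMSE` line is the 5-round average normalized error on the
hidden entries: here LLS with 50 neighbors recovers them at ~0.29 NRMSE,
about 3.5× better than the row-average baseline (~1.07 on this data), and
ILLS with the default distance threshold lands at ~0.31. On this strongly
clustered synthetic matrix the local linear fit is already well calibrated,
so the shrinkage variants score within half a point of their plain
counterparts rather than below them; see `docs/methods.md` for when the
shrinkage factor helps and when it cannot. `demo_results/` holds the tidy
per-round table (`results.tsv`) and the per-cell means (`summary.tsv`).
The same grids the protocol sweeps — missing rates 1–20%, Gaussian noise
sd 0–0.25, k ∈ {50,…,300} — are available as repeatable `--rate`,
`--noise-sd` and `--k` flags.

The library mirrors the CLI one-to-one:

```python
import shrinklls as s

matrix = s.generate(s.SyntheticSpec(seed=1))
masked, record = s.mask_random(matrix, rate=0.05, seed=1)
filled = s.lls_impute(masked, s.ImputeConfig(method="lls", k=50,
                                             shrinkage=s.ShrinkageConfig()))
print(s.score_imputation(filled, record))
```

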