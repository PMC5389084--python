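# beidc — adaptive-threshold SNP screening for genomic selection

Feature screening ranks every SNP in a genome-wide panel by its association
with a trait and keeps the top *d*. In practice *d* is set by convention
(e.g. *d* = [n/log n] or 2[n/log n]), which ignores how many candidates
there are and how strong the signal is. `beidc` determines *d* adaptively
from prediction error:

1. **Rank** all p SNPs by iterative distance-correlation screening
   (IDC-SIS): distance correlation

   Dcorr(y, Xⱼ) = dcov(y, Xⱼ) / √(dcov(y, y) · dcov(Xⱼ, Xⱼ)) ∈ [0, 1]

   is zero iff y ⊥ Xⱼ and captures nonlinear association; the iterative
   step repeatedly projects unselected SNPs onto the residual space of the
   already-selected block and re-ranks, recovering SNPs that are jointly
   important but marginally silent and demoting noise that rides on
   linkage disequilibrium.
2. **Eliminate backward**: walk nested pools (the top-k prefix of the
   ranking), halving the pool each step (drop rate 0.5 by default), and
   score each pool by the bootstrap out-of-bag mean squared prediction
   error (MSPE) of a SCAD-penalized regression with cross-validated λ
   (α = 3.7).
3. **Select the threshold**: d̂ is the visited pool size minimizing the
   MSPE; the top-d̂ SNPs are the selected set. A 1-standard-error
   alternative (smallest pool within one SE of the minimum) is reported
   alongside.

The package is organized as scikit-learn estimators —
`DistanceCorrelationScreener`, `IterativeDCScreener` (feature selectors),
`ScadRegressor` / `ScadRegressorCV` (regressors) and
`BackwardEliminationSelector` (the full pipeline) — with functional
equivalents (`dcsis_rank`, `idcsis_rank`, `fit_scad`, `run_be_idc`, …),
three seeded synthetic study designs, genotype TSV/VCF input, and a CLI.

## Worked example

```python
from beidc import SimulationDesign, generate, run_be_idc, BeConfig

design = SimulationDesign("example1", n=200, p=500, seed=42)
X, y = generate(design, 0)   # y = 5*X1 + 5*X2 + 5*X3 - 15*sqrt(0.5)*X4 + N(0,1)
ranking, trace, result = run_be_idc(X.values, y, BeConfig(n_bootstrap=100, seed=7))

for k, m, s in zip(trace.pool_sizes, trace.mspe_mean, trace.mspe_se):
    print(f"{k:9d}  {m:9.3f}  {s:7.3f}")
print(f"d_hat = {result.d_hat}   (1-SE rule: {result.d_one_se})")
print("selected:", [f"X{j+1}" for j in result.selected[:4]], "...")
```

prints

```
      500      1.547    0.213
      250      0.804    0.011
      125      0.803    0.011
       62      0.803    0.011
       31      0.803    0.011
       15      0.802    0.011
        7      0.802    0.011
        3     26.851    0.336
        1     28.063    0.340
d_hat = 7   (1-SE rule: 7)
selected: ['X3', 'X1', 'X2', 'X4'] ...
```

Reading the trace: the error collapses once the pool is small enough for
the SCAD fit to isolate the four influential features, stays flat on a
plateau near the noise variance, and explodes when elimination cuts into
the true model (pool 3 cannot hold all four signals — note X4, which is
*marginally independent* of y by construction, is ranked 4th by the
iterative screen and kept). Pools on the plateau are statistically
indistinguishable (the per-bootstrap paired differences are within one
standard error of the minimum), so the threshold resolves to the plateau's
smallest pool, d̂ = 7. All four true features sit at the top of the
selected list.

The same run from the shell:

```bash
beidc simulate --design example1 --n 200 --p 500 --seed 42 --out-prefix sim
beidc select --genotypes sim.geno.tsv --phenotype sim.pheno.tsv \
             --bootstraps 100 --seed 7 --out-prefix out
# -> out.trace.tsv (pool_size, mspe_mean, mspe_se), out.selected.tsv
```

`beidc rank` writes a full ranking (feature, score, rank, stage) for
Manhattan-style plots, and `beidc evaluate` runs replicate studies
(average threshold, strict/individual power, CV MSPE) for any of the three
built-in designs. Genotypes can also be read from VCF (biallelic sites
converted to 0/1/2 alternate-allele dosages; missing genotypes
mean-imputed, multi-allelic sites skipped, both logged).

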