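# survcoxbench

Benchmarking how much genome-wide gene expression adds to clinical
prognostic prediction in cancer survival data — and how much of the survival
variation each information source explains.

`survcoxbench` is for biostatisticians and computational biologists who want
to compare, on the same footing, four Cox proportional-hazards prediction
models on datasets that pair per-sample clinical covariates with a
high-dimensional expression matrix (the pan-cancer Xena TSV layout, or
synthetic data with known truth):

| model | hazard | gene effects |
|---|---|---|
| `cox_clinical` | h(t\|X) = h0(t) exp(Xᵀa) | none (benchmark) |
| `coxlasso` | h0(t) exp(Xᵀa + Gᵀb) | lasso penalty (α = 1), most b_j exactly 0 |
| `coxenet` | h0(t) exp(Xᵀa + Gᵀb) | elastic net (α = 0.5) |
| `coxlmm` | h0(t) exp(Xᵀa + Gᵀb) | random, b_j ~ N(0, σ²_b), all genes kept |

The penalized models are fitted by cyclic coordinate descent on an
iteratively reweighted least-squares approximation of the partial
likelihood, with the tuning parameter chosen by a subsampling strategy
(repeated 80/20 splits scored by held-out C-index). The mixed model
integrates the m gene effects out of the partial likelihood by Laplace
approximation and maximizes the resulting marginal over σ²_b; a low-rank
kernel reformulation (G Gᵀ eigenspace) keeps the cost O(n³) rather than
O(m³), so m ≫ n is routine.

On top of the models sit:

- **Harrell's C-index** and a Monte Carlo cross-validation (MCCV) harness —
  repeated 80/20 train/test splits, every model fitted (tuning included)
  inside the training fold — plus the relative prediction gain
  (C_M2 − C_M1)/C_M1;
- a **permuted-expression control**: shuffling the sample-to-expression-row
  assignment destroys any gene–outcome signal while keeping gene–gene
  correlation, so a model that only overfits collapses to the clinical
  benchmark;
- a **gene-number sweep**: mixed-model accuracy as a function of how many
  genes are included, selected either at random or by training-fold
  univariate Cox p-values;
- a **survival-variance partition** on the log-hazard scale: with
  v_c = var(Xᵀa), v_g = m·σ̂²_b and the Gumbel residual variance π²/6,

      PCE = v_c / (v_c + v_g + π²/6)   (clinical share)
      PGE = v_g / (v_c + v_g + π²/6)   (transcriptomic share)
      PVE = PCE + PGE

  with delete-one jackknife confidence intervals;
- a **synthetic-data generator** drawing from exactly the assumed model
  (polygenic, sparse or null gene architectures; calibrated independent
  censoring) with the full ground truth returned for recovery tests.

## Worked example

```python
from survcoxbench import (SimulationConfig, simulate_dataset, MixedCox,
                          run_mccv, estimate_partition)

ds, truth = simulate_dataset(SimulationConfig(
    n=300, p=3, m=200, a_true=0.5, genetic_variance=1.0,
    censoring=0.3, seed=7))

fit = MixedCox(ds).fit()
print(f"per-sample genetic variance: {fit.genetic_variance:.3f}"
      f"  (truth {truth.v_g_true})")
part = estimate_partition(ds, fit)
print(f"PCE={part.pce:.3f}  PGE={part.pge:.3f}  PVE={part.pve:.3f}"
      f"  (true PGE {truth.pge_true:.3f})")

res = run_mccv(ds, ["cox_clinical", "coxlmm"], n_rep=10, seed=1)
print(res.summary())
```

prints

```
per-sample genetic variance: 1.247  (truth 1.0)
PCE=0.223  PGE=0.335  PVE=0.558  (true PGE 0.318)
              mean_cindex  sd_cindex
model
cox_clinical     0.665194   0.038746
coxlmm           0.729043   0.043253
```

The mixed model recovers the simulated per-sample genetic variance (1.25 vs
1.0, within this dataset's sampling noise), attributes about 34% of the
log-hazard variation to the transcriptome (truth 32%), and improves held-out
discrimination over the clinical-only Cox model by about 0.06 C-index on
this dataset.

The same stages are available from the shell:

```bash
survcoxbench simulate --n 300 --m 200 --seed 7 --out ds.npz
survcoxbench benchmark --dataset ds.npz --models cox_clinical,coxlmm \
    --n-rep 10 --seed 1 --out mccv.csv
survcoxbench partition --dataset ds.npz --max-delete 50 --out part.json
survcoxbench run --config pipeline.yaml   # full pipeline with manifest
```

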