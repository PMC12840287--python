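# gtsurv

Restricted-mean-survival-time (RMST) prediction from high-dimensional
covariates when event times are **arbitrarily censored** — left, right, or
interval censored, as in cohort studies where disease onset is only
detectable at intermittent clinic visits.

Classical survival regression struggles here twice over: the event time is
never observed directly, and the covariate–outcome relationship (e.g.
between a gene-expression panel and progression) is high-dimensional and
nonlinear. `gtsurv` addresses both with a two-stage pipeline:

1. **Pseudo-observations.** The survival function is estimated by the
   Turnbull nonparametric MLE for interval-censored data (hybrid EM-ICM
   algorithm), the RMST `μ(τ) = ∫₀^τ Ŝ(t) dt` is integrated exactly, and
   each subject receives a jackknife pseudo-observation

       ỹᵢ(τₖ) = n·μ̂(τₖ) − (n−1)·μ̂⁽⁻ⁱ⁾(τₖ),

   a fully observed regression target that equals `min(Tᵢ, τ)` exactly when
   the data are uncensored.

2. **Graph + tree regression.** Subjects become nodes of a KNN similarity
   graph (Euclidean distance on covariates); two graph-convolution layers
   `H ← ReLU(Â H W)` over the normalized self-looped adjacency
   `Â = D̃^{-1/2}(A+I)D̃^{-1/2}` embed each subject using its neighborhood,
   and a soft binary decision tree maps the embedding to predictions: node
   `e` routes left with probability `σ(f_e(x))`, and the RMST prediction is
   the routing-probability-weighted mean of per-leaf RMST vectors,
   `g(xᵢ, τₖ) = Σ_l λ_lk p_l(xᵢ)`. Training minimizes the pseudo-value MSE
   with full-batch Adam, transductively (propagation over all nodes, loss
   masked to training nodes). All gradients are exact analytic backprop,
   verified against finite differences in the test suite.

Baselines with the same training loop are included: a GCN-only ablation, a
plain fully connected network (DNN), and an FC + tree variant (NDF). A
simulation module generates the benchmark cohorts (AR(1)-correlated
Gaussian covariates, exponential survival with nonlinear/linear/mixed rate
designs, 10-visit interval censoring), so no external data is needed.

## Worked example

Simulate a 200-subject cohort under the nonlinear rate design, compute
pseudo-values at horizons 1, 3, 5 years, and benchmark three methods:

```bash
gtsurv simulate --experiment 1 --n 200 --p 50 --seed 7 --out demo/cohort
gtsurv pseudo --intervals demo/cohort/intervals.csv --taus 1,3,5 --out demo/pv
gtsurv evaluate --experiment 1 --n 200 --p 50 --k 1 --reps 5 \
    --methods gt,gcn,dnn --seed 7 --out demo/eval
```

The pseudo-value table has one row per subject and horizon —

```
id,tau,pseudo_value
0,1.0,0.3465180104483352
0,3.0,0.3705693479217729
0,5.0,0.37047611609958153
```

— subject 0's estimated restricted mean survival contribution barely grows
past τ = 1, i.e. the model of the cohort expects this subject's event well
before 3 years. The evaluation prints test-set error against the true
conditional RMST (known in simulation), averaged over 5 replications:

```
method metric     mean       sd   n  p  K  reps
    gt    mse 0.048660 0.021260 200 50  1     5
    gt    mae 0.174589 0.039746 200 50  1     5
   gcn    mse 0.049266 0.015641 200 50  1     5
   gcn    mae 0.179510 0.030679 200 50  1     5
   dnn    mse 0.162174 0.074145 200 50  1     5
   dnn    mae 0.304661 0.081924 200 50  1     5
```

Lower is better: the graph-based models (`gt`, `gcn`) roughly halve the MAE
of the fully connected baseline at this sample size, and the full
GCN + tree model edges out the GCN-only ablation. `fit` / `predict`
subcommands support the checkpoint workflow for your own interval tables
(CSV with columns `id, L, R`; empty or `inf` right bounds mean right
censoring, `L == R` an exact event).

Every run writes a `manifest.json` (config, seeds, input hashes) sufficient
to reproduce its outputs. See `docs/methods.md` for the estimator, the
model, the generator's design choices, and known limitations.

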