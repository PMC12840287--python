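# Methods

`gtsurv` predicts restricted mean survival time (RMST) from high-dimensional
covariates when event times are arbitrarily censored — left, right, or
interval censored, as arises when a condition is only detectable at
intermittent clinic visits. The pipeline has two stages: (1) convert the
censored times into per-subject regression targets via NPMLE-based jackknife
pseudo-observations, and (2) regress those targets on covariates with a
graph-convolutional network feeding a soft decision tree.

## Censoring model and the Turnbull NPMLE

Each subject contributes an interval `[L, R]` with `P(T ∈ [L, R]) = 1`:
`L = 0` is left censoring, `R = ∞` right censoring, `L = R` an exactly
observed event. (Treating `L = R` as exact, rather than as a censoring
class, is what makes the estimator reduce to the empirical survival
function on uncensored data — a reduction the tests assert exactly.)

The nonparametric MLE of `S(t)` places masses `ρ_j` on the gaps
`(s_{j-1}, s_j]` between the ordered unique endpoints
`{0} ∪ {L_i} ∪ {R_i}` (an `∞` sentinel collects right-censored mass, so
`Ŝ` may plateau above zero; RMST integration to finite `τ` is unaffected).
With `α_ij = I(s_j ∈ (L_i, R_i])` the log-likelihood is
`Σ_i log Σ_j α_ij ρ_j`, maximized by a hybrid algorithm alternating:

- **EM (self-consistency):** `ρ_j ← d_j / n` with
  `d_j = Σ_i α_ij ρ_j / Σ_l α_il ρ_l`, the expected event count per gap.
- **ICM (iterative convex minorant):** a projected-Newton step on the CDF
  `β_j = Σ_{l≤j} ρ_l` under `β_1 ≤ … ≤ β_m = 1`, using the diagonal of the
  negative Hessian as working curvature (floored at `1e-8`), weighted
  isotonic regression (PAVA, via `scipy.optimize.isotonic_regression`) as
  the projection, `β` clipped into `[1e-10, 1]`, and step-halving so the
  likelihood never decreases.

One EM sweep then one ICM sweep per outer iteration; convergence when the
log-likelihood gain drops below `tol = 1e-7` (`max_iter = 500`). Likelihood
ascent, simplex feasibility, and agreement with a dense simplex search on
small instances are asserted by the test suite; fitted curves also agree
with an independent implementation (lifelines) on mixed-censoring cohorts.

NPMLE mass placement is not identified inside equivalence-class intervals;
this implementation spreads mass over all support gaps compatible with the
data rather than collapsing to innermost intervals. Consequences are
confined to quantities that integrate the curve inside such intervals.

## RMST pseudo-observations

`μ(τ) = E[min(T, τ)] = ∫_0^τ S(t) dt` is computed by exact step-function
integration. The jackknife pseudo-observation for subject `i` at horizon
`τ_k` is

    ỹ_i(τ_k) = n·μ̂(τ_k) − (n−1)·μ̂^(−i)(τ_k),

with `μ̂^(−i)` the leave-one-out estimate. Leave-one-out fits reuse the
full-sample support grid (subject `i`'s membership row removed) and are
warm-started from the full-sample masses, capped at 100 iterations. On the
simulated cohorts this matches per-subject rebuilt supports in distribution
(residual differences trace to the mass-placement indeterminacy above, and
downstream results are insensitive to the choice — verified empirically),
at roughly a fifth of the cost. With exact data the construction returns
`min(T_i, τ)` to 1e-10 — the jackknife of a sample mean returns the
observations — which the tests assert for every `τ`.

Pseudo-values are computed once on the full cohort before any train/test
split (test-set targets must exist, and the construction is unsupervised in
the covariates); individual values may fall outside `[0, τ]` and are
deliberately not clipped, since clipping would bias the regression target.
Under heavy censoring the jackknife values are strongly dispersed (variance
well above that of `min(T, τ)`), which matters for how results are scored —
see "Evaluation targets" below.

## Patient graph and predictor

Subjects are nodes; `kn`-nearest-neighbor edges (Euclidean distance on the
covariates as given, union symmetrization, unit weights, index tie-break)
define adjacency `A`. The GCN propagates over
`Â = D̃^{-1/2}(A + I)D̃^{-1/2}`. The graph is transductive — built over all
subjects, training and test alike — because prediction propagates over test
nodes; only training-node residuals enter the loss.

Two propagation layers `H^(v+1) = ReLU(Â H^(v) W^(v))` (no biases, inverted
dropout 0.1 after each ReLU during training) produce embeddings that a
single shared affine map converts to one score `f_e` per internal node of a
full binary tree of depth `d`. Node `e` routes left with probability
`d_e = sigmoid(f_e)`; leaf `l` is reached with probability
`p_l = Π_e d_e^{[left]} (1−d_e)^{[right]}` along its path, and the
prediction is the convex combination `g_ik = Σ_l λ_lk p_l(X_i)` of the
per-leaf RMST vectors `λ_l`. Rows of `p` sum to one and predictions lie in
the leaf convex hull, both asserted as invariants.

**Training.** Full-batch Adam (lr 1e-3, up to 1000 epochs) on the
pseudo-value MSE `L = (1/nK) Σ_ik (ỹ_ik − g_ik)²` masked to training
nodes; early stopping on validation MSE with patience 50 and best-weight
restoration. Gradients are hand-derived backprop through the exact forward
pass and are verified against central finite differences to 1e-4 relative
error on randomized small models. The per-node closed form

    ∂L/∂f_e(X_i) = (2/nK) · P(reach e) · d_e(1−d_e) · Σ_k r_ik (A_el − A_er)

(`r = g − ỹ`; `A_el`, `A_er` the left/right subtree outputs) is exposed
separately and tested against the same oracle; note the reach-probability
factor is required for this to be the true gradient. Leaf gradients are
`(2/nK) Σ_i r_ik p_l(X_i)`.

**Weight decay.** L2 regularization is applied through the optimizer to the
propagation and routing weights, never to leaf values or biases (decaying
the leaves would shrink the predicted RMST scale toward zero). The default
coefficient is 5e-4, the canonical value for this two-layer GCN
architecture; at 1.0 every variant collapses to a near-constant predictor
and all methods become indistinguishable, which is inconsistent with the
separated baseline behaviour the model family is known for.

**Initialization.** Glorot-uniform for all weight matrices; leaf vectors at
the training-set mean pseudo-value per horizon plus `0.01` Gaussian noise.
The model therefore starts at (essentially) the constant predictor and
moves away only where the data support it.

**Baselines** share the training loop: `gcn` (GCN-only ablation) replaces
the tree with a linear K-output head; `dnn` additionally replaces `Â` with
the identity, making the propagation layers plain fully connected layers;
`ndf` keeps the tree but uses the identity adjacency. With an edgeless
graph the GCN baselines reduce bitwise to their FC counterparts.

## Synthetic cohorts

Covariates are i.i.d. `MVN(0, Σ)` rows with AR(1) structure
`Σ_lm = 0.5^{|l−m|}`. Event times are exponential with rate `η(X)` drawn by
inverse-CDF sampling; three designs cover a nonlinear rate
(`η₁ = |X₁| + (X₂−0.5)² + |X₃−X₄|`), a linear one (`η₂ = Σ γ_p X_p`,
`γ ~ MVN(0.2·1, 0.01Σ)`, one draw per cohort), and a mixed one
(`η₃ = η₂ + X₃² + X₄²`). Censoring emulates ten clinic visits per subject:
`V₁ ~ U(0,2)`, `V_k = V_{k−1} + U(0,1)`; an event before `V₁` is
left-censored on `(0, V₁]`, after `V₁₀` right-censored, otherwise
interval-censored in the bracketing gap. The latent time always lies in its
interval (asserted for every generated cohort), and distributional checks
(AR(1) correlations, exponential means, visit moments) hold within three
standard errors at n = 20000.

Under the linear and mixed designs roughly half of all Gaussian draws give
`η ≤ 0`, for which an exponential time is undefined. The generator
conditions on a valid design by redrawing each offending subject's
covariate row until its rate is positive. The alternative — flooring rates
at a tiny constant — creates a large subpopulation that effectively never
fails (true RMST ≈ τ at every horizon), inflating the target dispersion by
roughly fivefold and making the published error magnitudes for these
designs unreachable by any regression method we tried, including oracle
ones; rejection reproduces them naturally.

What the generator does not emulate: covariate-dependent visit processes,
non-exponential hazards, measurement error in the covariates, and the
correlation structure of real gene-expression panels. Passing tests
therefore certify the pipeline's statistical mechanics, not performance on
real cohorts.

## Evaluation protocol

Splits are 80% train / 20% test with 10% of the training part held out for
validation, rotated for fivefold cross-validation; splits and targets are
identical across methods within a replication, and replication `r` of an
experiment uses seed `base + r` for every stochastic stream. Metrics follow
the per-subject summed convention: `MSE = (1/n) Σ_i Σ_k r_ik²` and
`MAE = (1/n) Σ_i Σ_k |r_ik|` (divide by `n` only — the training loss
divides by `nK`). Hyperparameters (`kn ∈ {5,10,15,20}`, hidden dims
`{[64,32],[128,64],[256,128]}`, depth `{2..5}`) can be grid-searched per
fold on validation MSE; the scaled-down replication harness defaults to the
fixed mid-grid configuration (kn=10, [64,32], depth 3), with the full grid
behind a flag.

**Evaluation targets.** In simulation, test predictions are scored against
the true conditional RMST `μ(τ|X_i) = (1 − e^{−η_i τ})/η_i`, which the
generator knows exactly. Scoring against the pseudo-values themselves is
not informative at these sample sizes: their jackknife dispersion puts a
floor under the test error of every method — including the Bayes predictor
`E[min(T,τ)|X]`, which scores several times worse against pseudo-values
than plausible model errors against the truth — so differences between
methods would be swamped. Training, validation and model selection use
only pseudo-values throughout; the truth enters solely as the final
scoring target. For real data (no truth available) the CLI scores against
pseudo-values, and this caveat applies.

A known consequence of selecting on validation pseudo-MSE: occasionally a
replication's selected fit tracks the conditional mean of the
pseudo-values, which under heavy censoring is a biased transform of
`μ(τ|X)`, and scores poorly against the truth. This is inherent to
pseudo-value model selection at these censoring rates, shows up as rare
outlier replications, and is reported rather than filtered.

## Scaled-down problem sizes

The replication harness defaults to 10 replications for the
(n=200/400, p=50, K=1) settings and 5 for (n=400, p=500, K=3), with the
fixed configuration above — sizes chosen so a complete replication run is a
desk-scale computation on one CPU. Means are reported with
across-replication standard deviations.

## Known limitations

- NPMLE mass placement inside equivalence-class intervals is a convention;
  RMST values inherit that indeterminacy (small on realistic grids).
- Pseudo-value regression assumes the censoring mechanism carries no
  covariate information (visit schedules independent of `X` in the
  simulations); violation biases the targets.
- The transductive graph means adding subjects changes predictions for
  existing ones; there is no inductive out-of-graph prediction path.
- Single tree, two propagation layers, full-batch training only — by
  design, not engineering limitation.
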