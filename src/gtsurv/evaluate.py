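"""Cross-validation, grid search, metrics, baselines and simulation harness.

The evaluation metrics follow the per-subject summed convention: with
residuals r_ik = y~_ik - g_ik over n subjects and K horizons,

    MSE = (1/n) sum_i sum_k r_ik^2,     MAE = (1/n) sum_i sum_k |r_ik|

(divided by n only; the training loss divides by nK instead).  In the
simulation harness the observed RMST y~_ik that test predictions are scored
against is the true conditional RMST mu(tau_k | X_i) = (1 - e^{-eta_i
tau_k})/eta_i, which the generator knows exactly; training always targets
the jackknife pseudo-values, computed once on the full cohort before any
split.  (Scoring against the pseudo-values themselves is not meaningful:
their jackknife noise puts a large floor under the test MSE of every
method, including the Bayes predictor.)

Methods: ``gt`` (GCN + soft tree, the full model), ``gcn`` (GCN-only
ablation, linear head), ``dnn`` (fully connected layers, linear head) and
``ndf`` (fully connected layers + soft tree).  All share the same training
loop, optimizer settings, splits and targets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from gtsurv.graph import build_patient_graph
from gtsurv.model import TrainConfig, predict_rmst, train
from gtsurv.pseudo import TauGrid, jackknife_pseudovalues
from gtsurv.simulate import SimConfig, conditional_rmst, generate_cohort

logger = logging.getLogger(__name__)

METHODS = ("gt", "gcn", "dnn", "ndf")
#: methods whose propagation uses the patient graph
GRAPH_METHODS = ("gt", "gcn")
#: RMST horizon grids by number of observation points
TAU_GRIDS = {1: (1.0,), 3: (1.0, 3.0, 5.0), 5: (1.0, 3.0, 5.0, 7.0, 9.0)}


def metrics(pred: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """(MSE, MAE) with the summed-over-horizons, averaged-over-subjects
    convention."""
    pred = np.atleast_2d(np.asarray(pred, float))
    observed = np.atleast_2d(np.asarray(observed, float))
    if pred.shape != observed.shape:
        raise ValueError("prediction/observed shape mismatch")
    r = observed - pred
    n = r.shape[0]
    return (float(np.sum(r ** 2) / n), float(np.sum(np.abs(r)) / n))


@dataclass(frozen=True)
class SplitPlan:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split index sets overlap")


def make_split(n: int, seed: int, fold: int = 0, n_folds: int = 5) -> SplitPlan:
    """80/20 train/test split with 10% of the training part as validation.

    The five folds (``fold`` = 0..4) rotate the test block through a single
    seed-determined permutation, giving a fivefold cross-validation scheme.
    Deterministic given (n, seed, fold).
    """
    if n < 10:
        raise ValueError("need n >= 10 to split")
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold must be in [0, {n_folds})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    test = perm[bounds[fold]:bounds[fold + 1]]
    rest = np.concatenate([perm[:bounds[fold]], perm[bounds[fold + 1]:]])
    n_val = max(1, int(round(0.1 * len(rest))))
    val = rest[:n_val]
    tr = rest[n_val:]
    return SplitPlan(train_idx=np.sort(tr), val_idx=np.sort(val),
                     test_idx=np.sort(test), seed=seed)


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter candidate sets for the fold-wise grid search."""

    kn: tuple[int, ...] = (5, 10, 15, 20)
    hidden: tuple[tuple[int, int], ...] = ((64, 32), (128, 64), (256, 128))
    depth: tuple[int, ...] = (2, 3, 4, 5)

    def configs(self, base: TrainConfig, graph_method: bool,
                tree_method: bool):
        """Yield (kn, TrainConfig) pairs, honoring which axes apply."""
        kns = self.kn if graph_method else (None,)
        depths = self.depth if tree_method else (base.depth,)
        for kn, hid, dep in itertools.product(kns, self.hidden, depths):
            yield kn, replace(base, hidden=hid, depth=dep)


#: the fixed mid-grid configuration used when the full search is skipped
FAST_CONFIG = dict(kn=10, hidden=(64, 32), depth=3)


def _n_params(config: TrainConfig, p: int, K: int, tree: bool) -> int:
    h1, h2 = config.hidden
    n = p * h1 + h1 * h2
    if tree:
        e = 2 ** config.depth - 1
        n += h2 * e + e + 2 ** config.depth * K
    else:
        n += h2 * K + K
    return n


def fit_method(method: str, X, pseudo, split: SplitPlan,
               config: TrainConfig, kn: int | None = None):
    """Train one method on one split; returns (model, A_hat, result)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    Y = pseudo.values
    taus = pseudo.taus.taus
    if method in GRAPH_METHODS:
        if kn is None:
            raise ValueError(f"{method} needs a neighborhood size kn")
        A_hat = build_patient_graph(X, kn).normalized
    else:
        A_hat = np.eye(X.shape[0])
    head = "tree" if method in ("gt", "ndf") else "linear"
    result = train(X, A_hat, Y, split.train_idx, split.val_idx, config,
                   taus=taus, kn=kn, head=head)
    return result.model, A_hat, result


def grid_search(X, pseudo, split: SplitPlan, grid: GridSpec,
                base: TrainConfig, method: str = "gt"):
    """Exhaustive search minimizing validation MSE; ties broken by smaller
    parameter count, then listed order.  Returns (kn, TrainConfig)."""
    Y = pseudo.values
    best = None
    graph_method = method in GRAPH_METHODS
    tree_method = method in ("gt", "ndf")
    n_fail = 0
    for kn, cfg in grid.configs(base, graph_method, tree_method):
        try:
            model, A_hat, _ = fit_method(method, X, pseudo, split, cfg, kn=kn)
        except FloatingPointError:
            n_fail += 1
            continue
        pred = predict_rmst(X, A_hat, model)
        val_mse, _ = metrics(pred[split.val_idx], Y[split.val_idx])
        key = (val_mse, _n_params(cfg, X.shape[1], Y.shape[1], tree_method))
        if best is None or key < best[0]:
            best = (key, kn, cfg)
    if best is None:
        raise RuntimeError(f"all {n_fail} grid configurations diverged")
    return best[1], best[2]


def screen_features(X: np.ndarray, outcome: np.ndarray, top_m: int,
                    var_quantile: float = 0.1) -> np.ndarray:
    """Variance filter + information-gain ranking (optional preprocessing).

    Columns with variance at or below the ``var_quantile`` quantile are
    dropped; the survivors are ranked by the mutual information between the
    quartile-discretized feature and the quartile-discretized outcome, and
    the ``top_m`` best column indices (into the original X) are returned.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(outcome, float).ravel()
    var = X.var(axis=0)
    thresh = np.quantile(var, var_quantile)
    keep = np.flatnonzero(var > thresh)
    if keep.size == 0:
        keep = np.flatnonzero(var > 0)
    if top_m > keep.size:
        logger.warning("top_m=%d exceeds %d surviving columns; clipping",
                       top_m, keep.size)
        top_m = keep.size

    def quartiles(v):
        qs = np.quantile(v, [0.25, 0.5, 0.75])
        return np.searchsorted(qs, v, side="left")

    yq = quartiles(y)
    gains = np.array([mutual_info_score(quartiles(X[:, j]), yq) for j in keep])
    order = np.argsort(-gains, kind="stable")
    return keep[order[:top_m]]


@dataclass
class ReplicationRecord:
    rep: int
    method: str
    mse: float
    mae: float
    kn: int | None
    config: TrainConfig


@dataclass
class ExperimentResult:
    table: pd.DataFrame              # method, metric, mean, sd, ...
    records: list = field(default_factory=list)
    n_failed: int = 0


def run_replication(sim: SimConfig, methods, taus, base: TrainConfig,
                    rep_seed: int, fast: bool = True,
                    grid: GridSpec | None = None) -> list[ReplicationRecord]:
    """One replication: cohort → pseudo-values → split → train → test
    metrics, with identical splits and targets across methods."""
    cohort = generate_cohort(replace(sim, seed=rep_seed))
    X = cohort.dataset.X
    pseudo = jackknife_pseudovalues(cohort.dataset, TauGrid(np.asarray(taus)))
    truth = conditional_rmst(cohort.rates, taus)
    split = make_split(cohort.n, seed=rep_seed)
    out = []
    for method in methods:
        cfg = replace(base, hidden=FAST_CONFIG["hidden"],
                      depth=FAST_CONFIG["depth"], seed=rep_seed)
        kn = FAST_CONFIG["kn"]
        if not fast:
            kn, cfg = grid_search(X, pseudo, split, grid or GridSpec(),
                                  replace(base, seed=rep_seed), method=method)
        model, A_hat, _ = fit_method(method, X, pseudo, split, cfg, kn=kn)
        pred = predict_rmst(X, A_hat, model)
        mse, mae = metrics(pred[split.test_idx], truth[split.test_idx])
        out.append(ReplicationRecord(rep=rep_seed, method=method, mse=mse,
                                     mae=mae,
                                     kn=kn if method in GRAPH_METHODS else None,
                                     config=cfg))
    return out


def run_experiment(sim: SimConfig, methods=METHODS, reps: int = 10,
                   K_horizons: int = 1, base: TrainConfig | None = None,
                   fast: bool = True, grid: GridSpec | None = None
                   ) -> ExperimentResult:
    """Replicate the simulation study: ``reps`` cohorts (replication r uses
    seed ``sim.seed + r`` for every stochastic stream), shared splits across
    methods, mean and SD of test MSE/MAE across replications."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if K_horizons not in TAU_GRIDS:
        raise ValueError(f"K_horizons must be one of {sorted(TAU_GRIDS)}")
    taus = TAU_GRIDS[K_horizons]
    base = base or TrainConfig()
    records: list[ReplicationRecord] = []
    n_failed = 0
    for r in range(reps):
        try:
            records.extend(run_replication(sim, methods, taus, base,
                                           rep_seed=sim.seed + r, fast=fast,
                                           grid=grid))
        except (RuntimeError, FloatingPointError) as exc:
            n_failed += 1
            logger.warning("replication %d failed: %s", r, exc)
    if not records:
        raise RuntimeError("every replication failed")
    df = pd.DataFrame([{"method": rec.method, "mse": rec.mse,
                        "mae": rec.mae, "rep": rec.rep} for rec in records])
    rows = []
    for method in methods:
        sub = df[df.method == method]
        for metric in ("mse", "mae"):
            rows.append({
                "method": method, "metric": metric,
                "mean": sub[metric].mean(),
                "sd": sub[metric].std(ddof=1) if len(sub) > 1 else 0.0,
                "n": sim.n, "p": sim.p, "K": K_horizons, "reps": len(sub),
            })
    return ExperimentResult(table=pd.DataFrame(rows), records=records,
                            n_failed=n_failed)
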