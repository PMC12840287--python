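"""Turnbull NPMLE of the survival function for arbitrarily censored data.

Each subject contributes an observed interval ``[L, R]`` known to contain the
latent event time ``T``: ``L = 0`` means left censoring, ``R = inf`` right
censoring, ``0 < L < R < inf`` strict interval censoring, and ``L == R`` an
exactly observed event.  The nonparametric maximum-likelihood estimator
places probability masses ``rho_j`` on the gaps between consecutive support
points built from the observed endpoints, and is computed here with the
hybrid EM-ICM algorithm: self-consistency (EM) sweeps alternated with
projected-Newton iterative-convex-minorant (ICM) steps on the CDF under the
monotonicity constraint, using weighted isotonic regression (PAVA) as the
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import isotonic_regression

logger = logging.getLogger(__name__)

_BETA_FLOOR = 1e-10
_CURV_FLOOR = 1e-8


class DegenerateLikelihoodError(RuntimeError):
    """Raised when an update would make a subject's interval carry no mass."""


@dataclass(frozen=True)
class IntervalSample:
    """One subject: censoring interval [L, R] plus a covariate vector.

    ``R`` may be ``np.inf`` (right censoring); ``L == R`` encodes an exact
    observation.
    """

    left: float
    right: float
    covariates: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.left <= self.right):
            raise ValueError(
                f"invalid censoring interval [{self.left}, {self.right}]: "
                "need 0 <= L <= R"
            )
        if not np.isfinite(self.left):
            raise ValueError("left bound must be finite")


@dataclass(frozen=True)
class SurvivalDataset:
    """A cohort of interval-censored subjects with a shared covariate space."""

    left: np.ndarray   # (n,) finite, >= 0
    right: np.ndarray  # (n,) >= left, may contain inf
    X: np.ndarray      # (n, p)

    def __post_init__(self) -> None:
        L = np.asarray(self.left, dtype=float)
        R = np.asarray(self.right, dtype=float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "left", L)
        object.__setattr__(self, "right", R)
        object.__setattr__(self, "X", X)
        if L.ndim != 1 or R.shape != L.shape:
            raise ValueError("left and right must be equal-length 1-D arrays")
        if X.shape[0] != L.shape[0]:
            raise ValueError(
                f"covariate rows ({X.shape[0]}) != number of subjects ({L.shape[0]})"
            )
        if L.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if np.any(L < 0) or np.any(~np.isfinite(L)):
            raise ValueError("left bounds must be finite and nonnegative")
        if np.any(R < L):
            bad = int(np.argmax(R < L))
            raise ValueError(f"subject {bad}: R={R[bad]} < L={L[bad]}")

    @property
    def n(self) -> int:
        return self.left.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_samples(cls, samples: list[IntervalSample]) -> "SurvivalDataset":
        return cls(
            left=np.array([s.left for s in samples], dtype=float),
            right=np.array([s.right for s in samples], dtype=float),
            X=np.vstack([np.atleast_1d(s.covariates) for s in samples]),
        )

    def drop(self, i: int) -> "SurvivalDataset":
        """Leave-one-out copy without subject ``i``."""
        keep = np.arange(self.n) != i
        return SurvivalDataset(self.left[keep], self.right[keep], self.X[keep])


@dataclass
class TurnbullGrid:
    """NPMLE state on the Turnbull support.

    ``support`` holds the ordered points ``s_0 < s_1 < ... < s_m`` (``s_0 = 0``;
    ``s_m`` may be ``inf`` when right-censored subjects are present).  Mass
    ``rho_j`` sits on the gap ``(s_{j-1}, s_j]`` for ``j = 1..m``; subject ``i``
    is compatible with columns ``lo_i .. hi_i`` (inclusive, 1-based in the
    support, stored 0-based in ``rho``), the contiguous block of support
    points falling in ``(L_i, R_i]``.  ``beta_j = sum_{l<=j} rho_l`` is the
    CDF at ``s_j``.
    """

    support: np.ndarray  # (m+1,) ordered, support[0] == 0
    lo: np.ndarray       # (n,) first compatible column per subject (0-based)
    hi: np.ndarray       # (n,) last compatible column per subject (0-based)
    rho: np.ndarray      # (m,) nonnegative, sums to 1

    @property
    def m(self) -> int:
        return self.rho.shape[0]

    @property
    def n(self) -> int:
        return self.lo.shape[0]

    @property
    def beta(self) -> np.ndarray:
        return np.cumsum(self.rho)

    def membership(self) -> np.ndarray:
        """Dense n×m indicator matrix alpha_ij = I(s_j in (L_i, R_i])."""
        cols = np.arange(self.m)
        return ((cols >= self.lo[:, None]) & (cols <= self.hi[:, None])).astype(float)

    def interval_masses(self) -> np.ndarray:
        """P(T_i in (L_i, R_i]) under the current rho, per subject."""
        cum = np.concatenate(([0.0], np.cumsum(self.rho)))
        return cum[self.hi + 1] - cum[self.lo]

    def drop_subject(self, i: int) -> "TurnbullGrid":
        keep = np.arange(self.n) != i
        return TurnbullGrid(self.support, self.lo[keep], self.hi[keep],
                            self.rho.copy())


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step estimate of S(t) = P(T > t), with S(0) = 1.

    ``breakpoints`` are the support points ``s_0..s_m`` and ``values[j]`` is
    the estimate at ``s_j`` (so ``S(t) = values[j]`` for
    ``t in [s_j, s_{j+1})``).  When mass is assigned to a terminal
    ``(t_max, inf)`` interval the curve plateaus above zero.
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)
        if bp.shape != v.shape:
            raise ValueError("breakpoints/values length mismatch")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("survival values must be nonincreasing")

    def __call__(self, t) -> np.ndarray:
        """Evaluate S(t) (vectorized, right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, len(self.values) - 1)])
        return out if out.ndim else float(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.breakpoints, "survival": self.values})


@dataclass
class FitResult:
    curve: SurvivalCurve
    grid: TurnbullGrid
    log_likelihoods: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def build_turnbull_grid(dataset: SurvivalDataset) -> TurnbullGrid:
    """Build the Turnbull support and membership blocks; rho starts uniform.

    The support is the ordered unique set {0} ∪ {L_i} ∪ {finite R_i}, plus an
    ``inf`` sentinel when any subject is right-censored.  Exact observations
    (L == R == t) occupy the single column whose support point equals ``t``.
    """
    pts = {0.0}
    pts.update(dataset.left.tolist())
    pts.update(dataset.right[np.isfinite(dataset.right)].tolist())
    support = np.array(sorted(pts), dtype=float)
    if np.any(np.isinf(dataset.right)):
        support = np.append(support, np.inf)
    m = len(support) - 1
    if m < 1:
        raise ValueError("degenerate dataset: no positive support points")

    # column j (0-based) carries mass on (support[j], support[j+1]];
    # subject i is compatible with columns whose right end support[j+1]
    # lies in (L_i, R_i].  Exact obs: the column ending exactly at t.
    ends = support[1:]
    lo = np.searchsorted(ends, dataset.left, side="right")
    exact = dataset.left == dataset.right
    R_eff = np.where(exact, dataset.left, dataset.right)
    hi = np.searchsorted(ends, R_eff, side="left")
    # exact time t: (t-, t] column is the one ending at t
    lo = np.where(exact, hi, lo)
    if np.any(lo > hi):
        bad = int(np.argmax(lo > hi))
        raise ValueError(
            f"subject {bad} with interval [{dataset.left[bad]}, "
            f"{dataset.right[bad]}] matches no support column"
        )
    rho = np.full(m, 1.0 / m)
    return TurnbullGrid(support=support, lo=lo, hi=hi, rho=rho)


def log_likelihood(grid: TurnbullGrid) -> float:
    """Sum of log P(T_i in (L_i, R_i]); -inf if any subject has zero mass."""
    P = grid.interval_masses()
    if np.any(P <= 0):
        return -np.inf
    return float(np.sum(np.log(P)))


def em_step(grid: TurnbullGrid) -> TurnbullGrid:
    """One self-consistency sweep: rho_j <- d_j / n.

    ``d_j`` is the expected number of events in column ``j`` given the
    current masses: d_j = sum_i alpha_ij rho_j / sum_l alpha_il rho_l.
    """
    P = grid.interval_masses()
    if np.any(P <= 0):
        bad = int(np.argmax(P <= 0))
        raise DegenerateLikelihoodError(
            f"subject {bad} has zero probability mass on its interval"
        )
    invP = 1.0 / P
    # column weight = sum over subjects whose block covers the column
    w = np.zeros(grid.m + 1)
    np.add.at(w, grid.lo, invP)
    np.add.at(w, grid.hi + 1, -invP)
    colw = np.cumsum(w[:-1])
    d = grid.rho * colw
    return replace(grid, rho=d / grid.n)


def pava(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted least-squares isotonic (nondecreasing) fit."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty input to pava")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return isotonic_regression(values, weights=weights, increasing=True).x


def _beta_grad_curv(grid: TurnbullGrid) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and diagonal curvature of the log-likelihood in beta.

    Subject i contributes log(beta_{hi_i} - beta_{lo_i - 1}) (beta_{-1}=0,
    beta_{m-1}=1 fixed).  Returns arrays over the m free-or-fixed beta
    coordinates (0-based, coordinate j is beta at column j).
    """
    P = grid.interval_masses()
    c = 1.0 / P
    g = np.zeros(grid.m)
    h = np.zeros(grid.m)
    np.add.at(g, grid.hi, c)
    np.add.at(h, grid.hi, c * c)
    inner = grid.lo > 0
    np.add.at(g, grid.lo[inner] - 1, -c[inner])
    np.add.at(h, grid.lo[inner] - 1, c[inner] * c[inner])
    return g, h


def icm_step(grid: TurnbullGrid) -> TurnbullGrid:
    """One projected-Newton ICM step on the CDF beta.

    Takes a diagonal-Newton step (gradient over curvature, curvature floored),
    projects onto the monotone cone with curvature-weighted PAVA, clips into
    [eps, 1], pins the terminal CDF value at 1, and step-halves until the
    log-likelihood does not decrease.
    """
    beta = grid.beta
    ll0 = log_likelihood(grid)
    g, h = _beta_grad_curv(grid)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(h))):
        raise DegenerateLikelihoodError("non-finite gradient in ICM step")
    h = np.maximum(h, _CURV_FLOOR)
    step = g / h
    scale = 1.0
    for _ in range(30):
        prop = beta + scale * step
        prop = pava(prop, weights=h)
        prop = np.clip(prop, _BETA_FLOOR, 1.0)
        prop = np.maximum.accumulate(prop)
        prop[-1] = 1.0
        rho = np.diff(np.concatenate(([0.0], prop)))
        cand = replace(grid, rho=rho)
        if log_likelihood(cand) >= ll0 - 1e-12:
            return cand
        scale *= 0.5
    return grid  # no improving step found; caller's EM sweep still progresses


def fit_npmle(
    dataset: SurvivalDataset | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    warm_start: np.ndarray | None = None,
    grid: TurnbullGrid | None = None,
) -> FitResult:
    """NPMLE of S(t) by alternating EM and ICM sweeps until convergence.

    Either ``dataset`` or a prebuilt ``grid`` must be given (the latter is
    used for warm-started leave-one-out refits on a shared support).  Stops
    when the log-likelihood gain falls below ``tol``; the likelihood sequence
    is nondecreasing by construction (ICM step-halving, EM monotonicity).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if grid is None:
        if dataset is None:
            raise ValueError("need dataset or grid")
        grid = build_turnbull_grid(dataset)
    if warm_start is not None:
        rho = np.asarray(warm_start, dtype=float)
        if rho.shape != grid.rho.shape:
            raise ValueError("warm_start shape mismatch with grid")
        # keep strictly inside the simplex so every denominator is positive
        rho = np.maximum(rho, _BETA_FLOOR)
        grid = replace(grid, rho=rho / rho.sum())

    lls = [log_likelihood(grid)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grid = em_step(grid)
        grid = icm_step(grid)
        ll = log_likelihood(grid)
        lls.append(ll)
        if ll - lls[-2] < tol and np.isfinite(ll):
            converged = True
            break
    if not converged:
        logger.warning("NPMLE did not converge in %d iterations "
                       "(last gain %.3g)", max_iter, lls[-1] - lls[-2])
    beta = grid.beta
    surv = np.concatenate(([1.0], 1.0 - beta))
    surv = np.clip(surv, 0.0, 1.0)
    curve = SurvivalCurve(breakpoints=grid.support, values=surv)
    return FitResult(curve=curve, grid=grid, log_likelihoods=lls,
                     converged=converged, n_iter=it)


def read_intervals(path, feature_path=None):
    """Read an interval table (columns id, L, R) and optional feature matrix.

    ``R`` empty, "inf" or "Inf" means right-censored; ``L == R`` means an
    exact event.  Returns a :class:`SurvivalDataset` (features default to a
    zero column when no feature table is supplied).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "L", "R"}
    if not required.issubset(df.columns):
        raise ValueError(f"interval table needs columns {sorted(required)}")
    L = df["L"].to_numpy(dtype=float)
    R = (
        df["R"]
        .astype(str)
        .str.strip()
        .replace({"": "inf", "nan": "inf"})
        .astype(float)
        .to_numpy()
    )
    bad = np.flatnonzero(R < L)
    if bad.size:
        raise ValueError(f"row {bad[0] + 2}: R < L")  # +2: header + 1-based
    if feature_path is not None:
        X = pd.read_csv(feature_path).drop(columns=["id"], errors="ignore").to_numpy(dtype=float)
    else:
        X = np.zeros((len(L), 1))
    return SurvivalDataset(left=L, right=R, X=X)
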