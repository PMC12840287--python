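"""Synthetic cohorts: correlated Gaussian covariates, exponential survival,
and a 10-visit interval-censoring mechanism.

Covariates are i.i.d. rows from MVN(0, Sigma) with the AR(1) structure
Sigma_lm = 0.5^|l-m|.  Event times are exponential with a subject-specific
rate eta(X), one of three designs:

  experiment 1:  eta1 = |X1| + (X2 - 0.5)^2 + |X3 - X4|          (nonlinear)
  experiment 2:  eta2 = sum_p gamma_p X_p                        (linear)
  experiment 3:  eta3 = sum_p gamma_p X_p + X3^2 + X4^2          (mixed)

with gamma ~ MVN(0.2·1, 0.01·Sigma) drawn once per cohort (experiments 2-3).
Gaussian covariates make eta2/eta3 nonpositive for a large fraction of
draws, under which an exponential event time is undefined; the generator
conditions on a valid design by redrawing each offending subject's
covariate row until its rate is positive (per-subject rejection sampling,
recorded in ``n_redrawn``).  A residual floor of 1e-6 guards against
numerically zero rates.

Censoring emulates a 10-visit clinical schedule per subject: V1 ~ U(0, 2),
V_k = V_{k-1} + U(0, 1).  An event before the first visit is left-censored
(0, V1]; after the last visit, right-censored (V10, inf); otherwise
interval-censored in the bracketing visit gap (V_{k-1}, V_k].  The latent
event time always lies in its reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

from gtsurv.npmle import SurvivalDataset

N_VISITS = 10
RATE_FLOOR = 1e-6


@dataclass(frozen=True)
class SimConfig:
    n: int = 200
    p: int = 50
    experiment: int = 1
    seed: int = 0
    gamma_seed: int | None = None  # default: spawned from ``seed``

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.p < 4:
            raise ValueError("p must be >= 4 (the rate designs use X1..X4)")
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2 or 3")


@dataclass
class SimulatedCohort:
    dataset: SurvivalDataset
    true_times: np.ndarray            # latent T_i, kept for testing
    censor_class: np.ndarray          # per subject: "left"|"interval"|"right"
    gammas: np.ndarray | None = None  # experiment 2-3 coefficient draw
    rates: np.ndarray | None = None   # eta(X_i), the true exponential rates
    n_redrawn: int = 0                # covariate rows resampled for eta > 0
    config: SimConfig | None = None

    @property
    def n(self) -> int:
        return self.dataset.n


def ar1_cholesky(p: int, rho: float = 0.5) -> np.ndarray:
    """Upper Cholesky factor of the AR(1) covariance Sigma_lm = rho^|l-m|."""
    idx = np.arange(p)
    sigma = rho ** np.abs(idx[:, None] - idx[None, :])
    return cholesky(sigma, lower=False)


def draw_covariates(n: int, p: int,
                    rng: np.random.Generator | int) -> np.ndarray:
    """n i.i.d. rows from MVN(0, Sigma), Sigma_lm = 0.5^|l-m|."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Z = rng.standard_normal((n, p))
    return Z @ ar1_cholesky(p)


def draw_gammas(p: int, rng: np.random.Generator | int) -> np.ndarray:
    """One coefficient vector gamma ~ MVN(0.2·1, 0.01·Sigma), shared by the
    whole cohort (experiments 2-3)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    z = rng.standard_normal(p)
    return 0.2 + 0.1 * (z @ ar1_cholesky(p))


def eta(X: np.ndarray, experiment: int,
        gammas: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Subject-specific exponential rates; returns (rates, n_clamped)."""
    X = np.asarray(X, float)
    if experiment == 1:
        rates = (np.abs(X[:, 0]) + (X[:, 1] - 0.5) ** 2
                 + np.abs(X[:, 2] - X[:, 3]))
    elif experiment in (2, 3):
        if gammas is None:
            raise ValueError(f"experiment {experiment} needs gamma coefficients")
        rates = X @ np.asarray(gammas, float)
        if experiment == 3:
            rates = rates + X[:, 2] ** 2 + X[:, 3] ** 2
    else:
        raise ValueError("experiment must be 1, 2 or 3")
    n_clamped = int(np.sum(rates < RATE_FLOOR))
    return np.maximum(rates, RATE_FLOOR), n_clamped


def draw_event_times(rates: np.ndarray,
                     rng: np.random.Generator | int) -> np.ndarray:
    """Inverse-CDF sampling from S(t|X) = exp(-eta(X) t):
    T = -log(U)/eta with U ~ Uniform(0,1)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rates = np.asarray(rates, float)
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    U = rng.uniform(size=rates.shape)
    return -np.log(U) / rates


def draw_visit_schedule(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-subject visit times: V1 ~ U(0,2), V_k = V_{k-1} + U(0,1)."""
    V = np.empty((n, N_VISITS))
    V[:, 0] = rng.uniform(0.0, 2.0, size=n)
    V[:, 1:] = rng.uniform(0.0, 1.0, size=(n, N_VISITS - 1))
    return np.cumsum(V, axis=1)


def censor_times(T: np.ndarray, rng: np.random.Generator | int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the 10-visit censoring mechanism.  Returns (L, R, class)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    T = np.asarray(T, float)
    n = T.shape[0]
    V = draw_visit_schedule(n, rng)
    L = np.empty(n)
    R = np.empty(n)
    cls = np.empty(n, dtype=object)
    left = T < V[:, 0]
    right = T > V[:, -1]
    mid = ~(left | right)
    L[left], R[left], cls[left] = 0.0, V[left, 0], "left"
    L[right], R[right], cls[right] = V[right, -1], np.inf, "right"
    if mid.any():
        # bracketing gap: boundary hits T == V_k go to (V_{k-1}, V_k]
        k = np.array([np.searchsorted(V[i], T[i], side="left")
                      for i in np.flatnonzero(mid)])
        rows = np.flatnonzero(mid)
        L[rows] = V[rows, k - 1]
        R[rows] = V[rows, k]
        cls[rows] = "interval"
    return L, R, cls.astype(str)


def conditional_rmst(rates: np.ndarray, taus) -> np.ndarray:
    """True subject-level RMST under the exponential model:
    mu(tau | X) = E[min(T, tau) | X] = (1 - exp(-eta tau)) / eta.

    Returns an (n, K) matrix; this is the simulation ground truth that
    predictions are scored against."""
    rates = np.asarray(rates, float)[:, None]
    taus = np.atleast_1d(np.asarray(taus, float))[None, :]
    return (1.0 - np.exp(-rates * taus)) / rates


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Compose covariates → rates → event times → censoring, with
    independent child streams spawned from the config seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_x, rng_gamma, rng_t, rng_v = (np.random.default_rng(s)
                                      for s in ss.spawn(4))
    if config.gamma_seed is not None:
        rng_gamma = np.random.default_rng(config.gamma_seed)
    X = draw_covariates(config.n, config.p, rng_x)
    gammas = (draw_gammas(config.p, rng_gamma)
              if config.experiment in (2, 3) else None)
    rates, _ = eta(X, config.experiment, gammas)
    # experiments 2-3: condition on a positive rate per subject
    n_redrawn = 0
    bad = np.flatnonzero(rates <= RATE_FLOOR)
    while bad.size:
        n_redrawn += bad.size
        X[bad] = draw_covariates(bad.size, config.p, rng_x)
        rates, _ = eta(X, config.experiment, gammas)
        bad = np.flatnonzero(rates <= RATE_FLOOR)
    T = draw_event_times(rates, rng_t)
    L, R, cls = censor_times(T, rng_v)
    dataset = SurvivalDataset(left=L, right=R, X=X)
    return SimulatedCohort(dataset=dataset, true_times=T, censor_class=cls,
                           gammas=gammas, rates=rates, n_redrawn=n_redrawn,
                           config=config)
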