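"""RMST integration and jackknife pseudo-observation construction.

The restricted mean survival time mu(tau) = E[min(T, tau)] is the area under
the survival curve on [0, tau].  Jackknife pseudo-observations

    y~_i(tau_k) = n * mu_hat(tau_k) - (n - 1) * mu_hat^(-i)(tau_k)

turn this censored-data functional into one fully observed regression
response per subject and horizon: mu_hat is the NPMLE-based RMST on the full
cohort and mu_hat^(-i) the leave-one-out version.  For exact (uncensored)
data the construction returns min(T_i, tau) exactly, since the NPMLE reduces
to the empirical distribution and the RMST to a sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gtsurv.npmle import (
    SurvivalCurve,
    SurvivalDataset,
    build_turnbull_grid,
    fit_npmle,
)


@dataclass(frozen=True)
class TauGrid:
    """Strictly increasing positive RMST horizons tau_1 < ... < tau_K."""

    taus: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.taus, dtype=float))
        object.__setattr__(self, "taus", t)
        if np.any(t <= 0):
            raise ValueError("all horizons must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("horizons must be strictly increasing")

    @property
    def K(self) -> int:
        return self.taus.shape[0]


@dataclass
class PseudoValueMatrix:
    """n×K pseudo-observations plus the population and leave-one-out RMSTs.

    Individual pseudo-values may fall outside [0, tau] (a jackknife artifact)
    and are deliberately not clipped.
    """

    values: np.ndarray           # (n, K)
    population_rmst: np.ndarray  # (K,)
    taus: TauGrid
    loo_rmst: np.ndarray | None = None  # (n, K)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        n, K = self.values.shape
        return pd.DataFrame({
            "id": np.repeat(np.arange(n), K),
            "tau": np.tile(self.taus.taus, n),
            "pseudo_value": self.values.ravel(),
        })


def rmst(curve: SurvivalCurve, tau: float) -> float:
    """Exact integral of the survival step function on [0, tau]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    bp = curve.breakpoints
    vals = curve.values
    finite = np.isfinite(bp)
    # integration knots: support points below tau, then tau itself
    cut = np.searchsorted(bp[finite], tau, side="left")
    knots = np.concatenate((bp[finite][:cut], [tau]))
    if knots[0] > 0.0:
        knots = np.concatenate(([0.0], knots))
    widths = np.diff(knots)
    heights = curve(knots[:-1])  # right-continuous: value on [knot, next)
    del vals
    return float(np.sum(widths * np.atleast_1d(heights)))


def jackknife_pseudovalues(
    dataset: SurvivalDataset,
    taus: TauGrid | np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 500,
    loo_max_iter: int = 100,
    keep_loo: bool = False,
) -> PseudoValueMatrix:
    """Jackknife RMST pseudo-observations for every subject and horizon.

    Fits the full-sample NPMLE once, then n leave-one-out NPMLEs warm-started
    from the full-sample masses on the shared full-sample Turnbull support
    (the excluded subject's membership row is dropped, the support is not
    rebuilt).  Deterministic given the data and settings.
    """
    if not isinstance(taus, TauGrid):
        taus = TauGrid(np.asarray(taus))
    n = dataset.n
    if n < 3:
        raise ValueError("jackknife needs at least 3 subjects")

    grid = build_turnbull_grid(dataset)
    full = fit_npmle(grid=grid, tol=tol, max_iter=max_iter)
    mu = np.array([rmst(full.curve, t) for t in taus.taus])

    loo = np.empty((n, taus.K))
    for i in range(n):
        sub = grid.drop_subject(i)
        try:
            fit_i = fit_npmle(grid=sub, tol=tol, max_iter=loo_max_iter,
                              warm_start=full.grid.rho)
        except Exception as exc:  # noqa: BLE001 - reraise with subject id
            raise RuntimeError(f"leave-one-out NPMLE failed excluding "
                               f"subject {i}") from exc
        loo[i] = [rmst(fit_i.curve, t) for t in taus.taus]

    values = n * mu[None, :] - (n - 1) * loo
    return PseudoValueMatrix(
        values=values,
        population_rmst=mu,
        taus=taus,
        loo_rmst=loo if keep_loo else None,
    )
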