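"""Maximum-likelihood logistic fits for one simulated trial.

Two models are fit to the four treatment-by-PF binomial cells:

* adjusted: ``logit P(D=1) = b0 + b1*T + b2*C`` -- the generating model;
* unadjusted: ``logit P(D=1) = a0 + a1*T`` -- the PF is omitted, so ``a1``
  targets the marginal (collapsed) treatment log odds ratio.

Fitting is Newton-Raphson on the aggregated binomial log-likelihood, which
is identical to the fit on the patient-level expansion.  The unadjusted
model has the closed form ``log[(a/(n1-a)) / (b/(n0-b))]`` with Wald SE
``sqrt(1/a + 1/(n1-a) + 1/b + 1/(n0-b))`` from the collapsed 2x2 table.

Zero cells make the MLE infinite (separation).  The fallback adds 0.5 to
the events and non-events of every cell in the model's design, refits, and
flags the replicate ``corrected``; replicates whose fit still fails are
flagged ``converged=False`` and reported, never silently dropped.

Batch variants vectorize the Newton iterations across replicates; they are
what the Monte-Carlo pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .trial_sim import TrialCounts

__all__ = [
    "FitResult",
    "FitBatch",
    "wald_ci",
    "fit_unadjusted",
    "fit_adjusted",
    "fit_unadjusted_batch",
    "fit_adjusted_batch",
]

Model = Literal["adjusted", "unadjusted"]

#: Design matrix of the adjusted model over the cells in CELL_ORDER
#: ((t, c) = (0,0), (0,1), (1,0), (1,1)); columns: intercept, T, C.
_X_ADJ = np.array(
    [[1.0, 0.0, 0.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0], [1.0, 1.0, 1.0]]
)

_NEWTON_TOL = 1e-10
_NEWTON_MAXITER = 100
#: |coefficient| beyond which the MLE is treated as diverging (separation).
_SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class FitResult:
    """One model fit: treatment-coefficient inference plus status flags.

    ``beta`` holds the full coefficient vector: (intercept, treatment) for
    the unadjusted model, (intercept, treatment, PF) for the adjusted one
    (the PF coefficient is NaN when the PF column was constant and dropped).
    """

    model: Model
    beta1_hat: float
    se1: float
    ci_low: float
    ci_high: float
    converged: bool
    corrected: bool
    beta: tuple[float, ...] = ()

    @property
    def orr_hat(self) -> float:
        """Estimated odds-ratio reduction, 1 - exp(beta1_hat)."""
        return 1.0 - float(np.exp(self.beta1_hat))


@dataclass(frozen=True)
class FitBatch:
    """Vectorized fit results over replicates (arrays share one length)."""

    model: Model
    beta1: np.ndarray
    se1: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    converged: np.ndarray
    corrected: np.ndarray
    beta: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.beta1)

    @property
    def orr(self) -> np.ndarray:
        return 1.0 - np.exp(self.beta1)

    def __getitem__(self, i: int) -> FitResult:
        return FitResult(
            model=self.model,
            beta1_hat=float(self.beta1[i]),
            se1=float(self.se1[i]),
            ci_low=float(self.ci_low[i]),
            ci_high=float(self.ci_high[i]),
            converged=bool(self.converged[i]),
            corrected=bool(self.corrected[i]),
            beta=() if self.beta is None else tuple(self.beta[i]),
        )


def wald_ci(beta: float, se: float, level: float = 0.95):
    """Symmetric Wald interval beta +/- z_{1-alpha/2} * se on the log-OR scale."""
    if np.any(np.asarray(se) <= 0):
        raise ValueError("standard error must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 + level / 2.0)
    return beta - z * se, beta + z * se


def _loglik(beta: np.ndarray, npat: np.ndarray, nev: np.ndarray, X: np.ndarray) -> np.ndarray:
    # binomial log-likelihood up to the constant binomial coefficients
    eta = beta @ X.T
    return np.sum(nev * eta - npat * np.logaddexp(0.0, eta), axis=-1)


def _newton_batch(npat: np.ndarray, nev: np.ndarray, X: np.ndarray):
    """Newton-Raphson over replicates; returns (beta, se, converged)."""
    R, _ = npat.shape
    p = X.shape[1]
    beta = np.zeros((R, p))
    ll = _loglik(beta, npat, nev, X)
    converged = np.zeros(R, dtype=bool)
    active = np.ones(R, dtype=bool)
    for _ in range(_NEWTON_MAXITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        b = beta[idx]
        eta = b @ X.T
        mu = expit(eta)
        w = npat[idx] * mu * (1.0 - mu)
        grad = (nev[idx] - npat[idx] * mu) @ X
        hess = np.einsum("rk,ki,kj->rij", w, X, X)
        # tiny ridge keeps near-singular replicates moving; diverging fits
        # are caught by the separation bound afterwards
        hess = hess + 1e-12 * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            hess = hess + 1e-6 * np.eye(p)
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        b_new = b + step
        ll_new = _loglik(b_new, npat[idx], nev[idx], X)
        # damped step if the likelihood decreased (rare, far from optimum)
        worse = ll_new < ll[idx] - 1e-12
        for _half in range(20):
            if not worse.any():
                break
            step[worse] *= 0.5
            b_new[worse] = b[worse] + step[worse]
            ll_new[worse] = _loglik(b_new[worse], npat[idx][worse], nev[idx][worse], X)
            worse = ll_new < ll[idx] - 1e-12
        beta[idx] = b_new
        rel = np.abs(ll_new - ll[idx]) / (np.abs(ll[idx]) + 1.0)
        done = rel < _NEWTON_TOL
        ll[idx] = ll_new
        converged[idx[done]] = True
        active[idx[done]] = False

    # Wald covariance from the observed information at the estimate
    eta = beta @ X.T
    mu = expit(eta)
    w = npat * mu * (1.0 - mu)
    hess = np.einsum("rk,ki,kj->rij", w, X, X)
    se = np.full((R, p), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            cov = np.linalg.inv(hess)
            diag = np.einsum("rii->ri", cov)
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            for r in range(R):
                try:
                    diag = np.diag(np.linalg.inv(hess[r]))
                    se[r] = np.sqrt(np.where(diag > 0, diag, np.nan))
                except np.linalg.LinAlgError:
                    pass
    return beta, se, converged


def _collapse_arms(npat: np.ndarray, nev: np.ndarray):
    """Collapse 4 cells to per-arm totals: (events1, n1, events0, n0)."""
    a = nev[:, 2] + nev[:, 3]
    n1 = npat[:, 2] + npat[:, 3]
    b = nev[:, 0] + nev[:, 1]
    n0 = npat[:, 0] + npat[:, 1]
    return a, n1, b, n0


def fit_unadjusted_batch(npat: np.ndarray, nev: np.ndarray, level: float = 0.95) -> FitBatch:
    """Closed-form treatment-only logistic fit per replicate.

    Estimate and SE come from the collapsed 2x2 table; if any of its four
    cells is zero, 0.5 is added to all four cells and the replicate is
    flagged ``corrected``.
    """
    npat = np.atleast_2d(np.asarray(npat, dtype=float))
    nev = np.atleast_2d(np.asarray(nev, dtype=float))
    a, n1, b, n0 = _collapse_arms(npat, nev)
    if (n1 == 0).any() or (n0 == 0).any():
        raise ValueError("both arms must contain at least one patient")
    cells = np.stack([a, n1 - a, b, n0 - b], axis=1)
    corrected = (cells == 0).any(axis=1)
    cells = cells + 0.5 * corrected[:, None]
    a_, na_, b_, nb_ = cells[:, 0], cells[:, 1], cells[:, 2], cells[:, 3]
    beta0 = np.log(b_ / nb_)
    beta1 = np.log(a_ / na_) - beta0
    se1 = np.sqrt(1.0 / a_ + 1.0 / na_ + 1.0 / b_ + 1.0 / nb_)
    lo, hi = wald_ci(beta1, se1, level)
    converged = np.isfinite(beta1) & np.isfinite(se1)
    return FitBatch(
        model="unadjusted", beta1=beta1, se1=se1, ci_low=lo, ci_high=hi,
        converged=converged, corrected=corrected,
        beta=np.stack([beta0, beta1], axis=1),
    )


def fit_adjusted_batch(npat: np.ndarray, nev: np.ndarray, level: float = 0.95) -> FitBatch:
    """Three-parameter ML fit (intercept, treatment, PF) per replicate.

    Replicates in which the PF column is constant (no PF-positive or no
    PF-negative patients at all) are fit with the treatment-only model,
    to which the adjusted model then reduces.  Replicates with a diverging
    or failed MLE are refit after adding 0.5 to the events and non-events
    of every cell (``corrected=True``).
    """
    npat = np.atleast_2d(np.asarray(npat, dtype=float))
    nev = np.atleast_2d(np.asarray(nev, dtype=float))
    R = npat.shape[0]
    _, n1, _, n0 = _collapse_arms(npat, nev)
    if (n1 == 0).any() or (n0 == 0).any():
        raise ValueError("both arms must contain at least one patient")

    beta1 = np.full(R, np.nan)
    se1 = np.full(R, np.nan)
    beta_full = np.full((R, 3), np.nan)
    converged = np.zeros(R, dtype=bool)
    corrected = np.zeros(R, dtype=bool)

    # constant PF column -> model is not identifiable in b2; drop it
    const_c = ((npat[:, 1] + npat[:, 3]) == 0) | ((npat[:, 0] + npat[:, 2]) == 0)
    if const_c.any():
        sub = fit_unadjusted_batch(npat[const_c], nev[const_c], level)
        beta1[const_c] = sub.beta1
        se1[const_c] = sub.se1
        beta_full[const_c, :2] = sub.beta
        converged[const_c] = sub.converged
        corrected[const_c] = sub.corrected

    todo = ~const_c
    if todo.any():
        b, s, conv = _newton_batch(npat[todo], nev[todo], _X_ADJ)
        bad = (
            ~conv
            | (np.abs(b).max(axis=1) > _SEPARATION_BOUND)
            | ~np.isfinite(s).all(axis=1)
        )
        if bad.any():
            idx_bad = np.flatnonzero(todo)[bad]
            npat_c = npat[idx_bad] + 1.0
            nev_c = nev[idx_bad] + 0.5
            b2, s2, conv2 = _newton_batch(npat_c, nev_c, _X_ADJ)
            b[bad], s[bad] = b2, s2
            conv = conv.copy()
            conv[bad] = conv2 & (np.abs(b2).max(axis=1) <= _SEPARATION_BOUND) & np.isfinite(
                s2
            ).all(axis=1)
            corrected[idx_bad] = True
        beta1[todo] = b[:, 1]
        se1[todo] = s[:, 1]
        beta_full[todo] = b
        converged[todo] = conv & np.isfinite(s[:, 1])

    with np.errstate(invalid="ignore"):
        safe_se = np.where(np.isfinite(se1) & (se1 > 0), se1, 1.0)
        lo, hi = wald_ci(beta1, safe_se, level)
        lo = np.where(np.isfinite(se1) & (se1 > 0), lo, np.nan)
        hi = np.where(np.isfinite(se1) & (se1 > 0), hi, np.nan)
    return FitBatch(
        model="adjusted", beta1=beta1, se1=se1, ci_low=lo, ci_high=hi,
        converged=converged, corrected=corrected, beta=beta_full,
    )


def fit_unadjusted(counts: TrialCounts, level: float = 0.95) -> FitResult:
    """Fit the treatment-only model to one trial."""
    npat, nev = counts.flat()
    return fit_unadjusted_batch(npat[None, :], nev[None, :], level)[0]


def fit_adjusted(counts: TrialCounts, level: float = 0.95) -> FitResult:
    """Fit the treatment + PF model to one trial."""
    npat, nev = counts.flat()
    return fit_adjusted_batch(npat[None, :], nev[None, :], level)[0]
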