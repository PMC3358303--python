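"""Between-arm imbalance in a binary prognostic factor.

Two measures are used, both computed on continuity-corrected prevalences
``(m + 0.5) / (n + 1)`` (0.5 added to each treatment-by-PF cell, keeping
proportions strictly inside (0, 1) even for empty cells):

* the absolute difference ``D1 = |p1 - p0|``, intuitive for clinicians, and
* the standardized difference ``D2 = D1 / sqrt[(p1(1-p1) + p0(1-p0)) / 2]``,
  the usual two-group standardized difference for a binary covariate, which
  is approximately invariant to the PF prevalence.

Exceedance curves ``Pr(D >= d)`` over a threshold grid are available either
by Monte Carlo over simulated trials or exactly, by enumerating the pair of
independent ``Binomial(n, lam)`` PF counts (O(n^2) terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import binom

from .trial_sim import TrialCounts

__all__ = [
    "ImbalanceDistribution",
    "DEFAULT_D1_THRESHOLDS",
    "corrected_prevalence",
    "d1",
    "d2",
    "imbalance_curve_mc",
    "imbalance_curve_exact",
]

Measure = Literal["absolute", "standardized"]

#: Default threshold grid for the exceedance curves.
DEFAULT_D1_THRESHOLDS: tuple[float, ...] = (0.005, 0.01, 0.025, 0.05, 0.10, 0.15, 0.20)

#: Tolerance used when testing ``D >= d`` so that exact ties on the
#: threshold are counted despite floating-point rounding.
_TIE_EPS = 1e-12

#: Largest per-arm size accepted by the exact enumeration (O(n^2) memory).
EXACT_ENUMERATION_MAX_N = 5000


@dataclass(frozen=True)
class ImbalanceDistribution:
    """Exceedance probabilities Pr(D >= d) for one (prevalence, arm size)."""

    lam: float
    n: int
    measure: Measure
    thresholds: tuple[float, ...]
    probabilities: tuple[float, ...]
    method: Literal["monte_carlo", "exact"]
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities)
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        order = np.argsort(self.thresholds)
        if (np.diff(probs[order]) > 1e-12).any():
            raise ValueError("exceedance probabilities must be non-increasing in d")


def corrected_prevalence(m: int, n: int) -> float:
    """Continuity-corrected PF prevalence (m + 0.5) / (n + 1) for one arm."""
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    return (m + 0.5) / (n + 1.0)


def _measures_from_counts(
    m1: np.ndarray, n1: int, m0: np.ndarray, n0: int
) -> tuple[np.ndarray, np.ndarray]:
    p1 = (np.asarray(m1) + 0.5) / (n1 + 1.0)
    p0 = (np.asarray(m0) + 0.5) / (n0 + 1.0)
    d1v = np.abs(p1 - p0)
    pooled_sd = np.sqrt((p1 * (1.0 - p1) + p0 * (1.0 - p0)) / 2.0)
    return d1v, d1v / pooled_sd


def d1(counts: TrialCounts) -> float:
    """Absolute difference of corrected PF prevalences between arms."""
    m0, m1 = counts.pf_counts
    val, _ = _measures_from_counts(np.int64(m1), counts.n1, np.int64(m0), counts.n0)
    return float(val)


def d2(counts: TrialCounts) -> float:
    """Standardized difference of corrected PF prevalences between arms."""
    m0, m1 = counts.pf_counts
    _, val = _measures_from_counts(np.int64(m1), counts.n1, np.int64(m0), counts.n0)
    return float(val)


def _exceedance(values: np.ndarray, weights: np.ndarray | None, thresholds: Sequence[float]) -> list[float]:
    out = []
    for d in thresholds:
        mask = values >= d - _TIE_EPS
        if weights is None:
            out.append(float(mask.mean()))
        else:
            out.append(float(weights[mask].sum()))
    return out


def imbalance_curve_mc(
    lam: float,
    n: int,
    thresholds: Sequence[float] = DEFAULT_D1_THRESHOLDS,
    n_replicates: int = 10_000,
    rng: np.random.Generator | None = None,
    measure: Measure = "absolute",
) -> ImbalanceDistribution:
    """Monte-Carlo exceedance curve over replicated unconditional trials.

    Only the PF counts are needed, so outcomes are not simulated: the two
    arms' PF-positive counts are drawn ``Binomial(n, lam)`` independently.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    m0 = rng.binomial(n, lam, size=n_replicates)
    m1 = rng.binomial(n, lam, size=n_replicates)
    d1v, d2v = _measures_from_counts(m1, n, m0, n)
    values = d1v if measure == "absolute" else d2v
    probs = _exceedance(values, None, thresholds)
    return ImbalanceDistribution(
        lam=lam, n=n, measure=measure, thresholds=tuple(thresholds),
        probabilities=tuple(probs), method="monte_carlo", n_replicates=n_replicates,
    )


def imbalance_curve_exact(
    lam: float,
    n: int,
    thresholds: Sequence[float] = DEFAULT_D1_THRESHOLDS,
    measure: Measure = "absolute",
) -> ImbalanceDistribution:
    """Exact exceedance curve by double-binomial enumeration.

    ``Pr(D >= d) = sum_{k1,k0} Bin(k1; n, lam) Bin(k0; n, lam)
    1[D(k1,k0) >= d]`` over all ``(n+1)^2`` count pairs.
    """
    if n > EXACT_ENUMERATION_MAX_N:
        raise ValueError(
            f"exact enumeration supported up to n={EXACT_ENUMERATION_MAX_N}, got {n}"
        )
    k = np.arange(n + 1)
    pmf = binom.pmf(k, n, lam)
    weights = np.outer(pmf, pmf).ravel()
    k1 = np.repeat(k, n + 1)
    k0 = np.tile(k, n + 1)
    d1v, d2v = _measures_from_counts(k1, n, k0, n)
    values = d1v if measure == "absolute" else d2v
    probs = _exceedance(values, weights, thresholds)
    probs = [min(1.0, p) for p in probs]  # guard pmf round-off
    return ImbalanceDistribution(
        lam=lam, n=n, measure=measure, thresholds=tuple(thresholds),
        probabilities=tuple(probs), method="exact",
    )
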