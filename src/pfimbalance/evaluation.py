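"""Monte-Carlo performance metrics and the sample-size calculation.

Replicate-level fits are aggregated into the usual simulation-study
metrics for the treatment coefficient: bias (mean estimate minus the true
conditional log OR), empirical SD, MSE, coverage of the 95% CI, and power
(the proportion of CIs excluding 0).  Coverage and bias for *both* models
are evaluated against the conditional ``b1`` of the generating model; with
a prognostic PF this is exactly what makes the unadjusted model's
under-coverage visible, since its estimand is the attenuated marginal OR.

Deviation tables summarize the difference ``D_ORR`` between the estimated
odds-ratio reduction (ORR = 1 - OR) and the true ORR; positive deviations
mean the treatment is made to look better than it is.

``required_sample_size`` is the standard two-proportion normal-
approximation calculation used to anchor the sample-size grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .estimation import FitBatch, FitResult

__all__ = [
    "PerformanceSummary",
    "DeviationTable",
    "DEFAULT_D2_THRESHOLDS",
    "summarize",
    "power_loss",
    "deviation_table",
    "required_sample_size",
]

#: Default threshold grid for ORR-deviation tables.
DEFAULT_D2_THRESHOLDS: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PerformanceSummary:
    """Per (scenario, setting, model, prevalence, n) performance metrics."""

    model: str
    bias: float
    empirical_sd: float
    mse: float
    coverage: float
    power: float
    n_effective: int
    n_corrected: int
    n_nonconverged: int
    scenario_id: int | None = None
    setting: str | None = None
    lam: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class DeviationTable:
    """Exceedance probabilities of ORR deviations, split by direction."""

    model: str
    thresholds: tuple[float, ...]
    prob_over: tuple[float, ...]
    prob_under: tuple[float, ...]
    prob_overall: tuple[float, ...]
    n_effective: int
    lam: float | None = None
    n: int | None = None


def _as_arrays(fits: FitBatch | Iterable[FitResult]):
    if isinstance(fits, FitBatch):
        return (
            fits.model,
            np.asarray(fits.beta1, dtype=float),
            np.asarray(fits.ci_low, dtype=float),
            np.asarray(fits.ci_high, dtype=float),
            np.asarray(fits.converged, dtype=bool),
            np.asarray(fits.corrected, dtype=bool),
        )
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    return (
        fits[0].model,
        np.array([f.beta1_hat for f in fits]),
        np.array([f.ci_low for f in fits]),
        np.array([f.ci_high for f in fits]),
        np.array([f.converged for f in fits]),
        np.array([f.corrected for f in fits]),
    )


def summarize(
    fits: FitBatch | Iterable[FitResult],
    true_beta1: float,
    include_nonconverged: bool = False,
    **meta,
) -> PerformanceSummary:
    """Aggregate replicate fits into bias / SD / MSE / coverage / power.

    Non-converged replicates are excluded (and counted) unless
    ``include_nonconverged`` is set; corrected replicates always contribute
    but are counted separately.
    """
    model, beta1, lo, hi, conv, corr = _as_arrays(fits)
    if len(beta1) == 0:
        raise ValueError("no fits supplied")
    keep = np.ones(len(beta1), dtype=bool) if include_nonconverged else conv
    keep &= np.isfinite(beta1) & np.isfinite(lo) & np.isfinite(hi)
    m = int(keep.sum())
    if m < 2:
        raise ValueError(f"need >= 2 contributing replicates, got {m}")
    b = beta1[keep]
    bias = float(b.mean() - true_beta1)
    sd = float(b.std(ddof=1))
    mse = float(np.mean((b - true_beta1) ** 2))
    coverage = float(((lo[keep] <= true_beta1) & (true_beta1 <= hi[keep])).mean())
    power = float(((lo[keep] > 0.0) | (hi[keep] < 0.0)).mean())
    return PerformanceSummary(
        model=model,
        bias=bias,
        empirical_sd=sd,
        mse=mse,
        coverage=coverage,
        power=power,
        n_effective=m,
        n_corrected=int(corr[keep].sum()),
        n_nonconverged=int((~conv).sum()),
        **meta,
    )


def power_loss(
    summary_unadj: PerformanceSummary,
    summary_adj: PerformanceSummary,
    relative: bool = False,
) -> float:
    """Power lost by omitting the PF, as a percentage.

    With ``relative=False`` (default) this is the absolute difference
    ``(power_adj - power_unadj) * 100`` in percentage points.  With
    ``relative=True`` it is expressed relative to the adjusted model's
    power, ``(power_adj - power_unadj) / power_adj * 100`` -- the loss *of
    the unadjusted model relative to the adjusted model*, which is how the
    quantity is conventionally reported.
    """
    for attr in ("scenario_id", "setting", "lam", "n"):
        a, u = getattr(summary_adj, attr), getattr(summary_unadj, attr)
        if a is not None and u is not None and a != u:
            raise ValueError(f"summaries disagree on {attr}: {u!r} vs {a!r}")
    if relative:
        if summary_adj.power <= 0:
            raise ValueError("relative power loss undefined: adjusted power is 0")
        return (summary_adj.power - summary_unadj.power) / summary_adj.power * 100.0
    return (summary_adj.power - summary_unadj.power) * 100.0


def deviation_table(
    fits: FitBatch | Iterable[FitResult],
    true_or: float,
    thresholds: Sequence[float] = DEFAULT_D2_THRESHOLDS,
    include_nonconverged: bool = False,
    **meta,
) -> DeviationTable:
    """Exceedance probabilities of D_ORR = estimated ORR - true ORR.

    ``prob_over[d]``  = Pr(D_ORR >= d)   (treatment overestimated),
    ``prob_under[d]`` = Pr(D_ORR <= -d)  (treatment underestimated),
    ``prob_overall[d]`` = Pr(|D_ORR| >= d).  At d = 0 the overall
    probability is 1 by convention and over/under split at
    Pr(D_ORR >= 0) / Pr(D_ORR < 0).
    """
    if not 0.0 < true_or < math.inf:
        raise ValueError(f"true odds ratio must be in (0, inf), got {true_or}")
    model, beta1, lo, hi, conv, corr = _as_arrays(fits)
    keep = np.ones(len(beta1), dtype=bool) if include_nonconverged else conv
    keep &= np.isfinite(beta1)
    if not keep.any():
        raise ValueError("no contributing replicates")
    # ORR = 1 - OR, so D_ORR = (1 - exp(beta1)) - (1 - true_or) = true_or - exp(beta1)
    d_orr = true_or - np.exp(beta1[keep])
    over, under, overall = [], [], []
    for d in thresholds:
        if d <= _TIE_EPS:
            p_over = float((d_orr >= 0.0).mean())
            p_under = 1.0 - p_over
            p_all = 1.0
        else:
            p_over = float((d_orr >= d - _TIE_EPS).mean())
            p_under = float((d_orr <= -d + _TIE_EPS).mean())
            p_all = p_over + p_under
        over.append(p_over)
        under.append(p_under)
        overall.append(p_all)
    return DeviationTable(
        model=model,
        thresholds=tuple(thresholds),
        prob_over=tuple(over),
        prob_under=tuple(under),
        prob_overall=tuple(overall),
        n_effective=int(keep.sum()),
        **meta,
    )


def required_sample_size(
    p0: float,
    rr: float,
    alpha: float = 0.05,
    power: float = 0.80,
    variance: str = "unpooled",
) -> int:
    """Per-arm size for a two-proportion comparison, normal approximation.

    Unpooled form (default)::

        n >= (z_{1-a/2} + z_{1-b})^2 [p0(1-p0) + p1(1-p1)] / (p1 - p0)^2

    with ``p1 = rr * p0``.  The pooled-variance alternative uses
    ``z_{1-a/2} * sqrt(2 p_bar q_bar)`` in place of the first term inside
    the square.  No continuity correction is applied.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    p1 = rr * p0
    if not 0.0 < p1 < 1.0:
        raise ValueError(f"rr * p0 must be in (0, 1), got {p1}")
    if p1 == p0:
        raise ValueError("zero effect (rr = 1): required sample size diverges")
    za = norm.ppf(1.0 - alpha / 2.0)
    zb = norm.ppf(power)
    v_unpooled = p0 * (1.0 - p0) + p1 * (1.0 - p1)
    if variance == "unpooled":
        n = (za + zb) ** 2 * v_unpooled / (p1 - p0) ** 2
    elif variance == "pooled":
        pbar = (p0 + p1) / 2.0
        n = (za * math.sqrt(2.0 * pbar * (1.0 - pbar)) + zb * math.sqrt(v_unpooled)) ** 2 / (
            p1 - p0
        ) ** 2
    else:
        raise ValueError(f"variance must be 'unpooled' or 'pooled', got {variance!r}")
    return int(math.ceil(n - 1e-9))
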