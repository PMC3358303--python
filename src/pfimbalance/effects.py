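"""Scenario parameterization for the trial simulator.

Trials are generated from a logistic model for the probability of a binary
outcome given treatment assignment ``T`` and a single binary prognostic
factor (PF) ``C``::

    logit P(D = 1 | T = t, C = c) = b0 + b1 * t + b2 * c

``b0`` is the log odds of the outcome for control patients without the PF,
``b1`` the conditional (subject-specific) treatment log odds ratio, and
``b2`` the prognostic-factor log odds ratio.  Scenarios are specified on a
clinical scale -- a control-arm baseline risk plus relative risks for the
treatment and for the PF -- and converted to logistic coefficients here, so
that the generating model and its clinical framing stay consistent by
construction.

The module also provides the analytic marginal (collapsed) treatment log
odds ratio, the quantity the unadjusted model estimates in large samples.
Because the odds ratio is non-collapsible, this marginal effect is
attenuated toward the null relative to ``b1`` whenever both ``b1`` and
``b2`` are non-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from scipy.special import expit, logit

__all__ = [
    "EffectSpec",
    "ScenarioSpec",
    "Setting",
    "rr_to_log_or",
    "build_scenario",
    "cell_probability",
    "marginal_log_or",
    "SCENARIO_TABLE",
    "UNCONDITIONAL_LAMBDA_GRID",
    "CONDITIONAL_LAMBDA_GRID",
    "DEFAULT_N_GRID",
    "CONDITIONAL_IMBALANCE_DELTA",
]

Setting = Literal["unconditional", "conditional"]

#: PF prevalence grid for the unconditional design (PF sampled at random).
UNCONDITIONAL_LAMBDA_GRID: tuple[float, ...] = (
    0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.995,
)
#: PF prevalence grid for the conditional design (5-point imbalance imposed);
#: extreme prevalences are excluded because a 5% imbalance is then infeasible
#: or vanishingly rare.
CONDITIONAL_LAMBDA_GRID: tuple[float, ...] = (
    0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95,
)
#: Per-arm sample sizes studied by default.
DEFAULT_N_GRID: tuple[int, ...] = (25, 50, 125, 500, 1000, 2000)
#: Between-arm PF prevalence difference imposed in the conditional design.
CONDITIONAL_IMBALANCE_DELTA: float = 0.05

#: The eight default scenarios: (baseline risk, treatment RR, PF RR).
#: Scenarios 1-4 use a moderate control-arm risk (0.10), 5-8 a low risk
#: (0.05); within each block the treatment RR alternates between a moderate
#: benefit (0.75) and the null (1), crossed with a strong (5) or moderate
#: (2) prognostic factor.
SCENARIO_TABLE: dict[int, tuple[float, float, float]] = {
    1: (0.10, 0.75, 5.0),
    2: (0.10, 0.75, 2.0),
    3: (0.10, 1.0, 5.0),
    4: (0.10, 1.0, 2.0),
    5: (0.05, 0.75, 5.0),
    6: (0.05, 0.75, 2.0),
    7: (0.05, 1.0, 5.0),
    8: (0.05, 1.0, 2.0),
}


def rr_to_log_or(rr: float, baseline_risk: float) -> float:
    """Convert a relative risk at a given baseline risk to a log odds ratio.

    Returns ``log{[rr*p/(1-rr*p)] / [p/(1-p)]}`` with ``p`` the baseline
    risk: the log of the odds ratio whose risk ratio at baseline ``p``
    equals ``rr``.

    Raises
    ------
    ValueError
        If the implied risk ``rr * baseline_risk`` is not below 1, or the
        inputs are out of range.
    """
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError(f"baseline_risk must be in (0, 1), got {baseline_risk}")
    if rr <= 0.0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    p1 = rr * baseline_risk
    if p1 >= 1.0:
        raise ValueError(
            f"relative risk {rr} at baseline risk {baseline_risk} implies a "
            f"probability {p1} >= 1"
        )
    return math.log(p1 / (1.0 - p1)) - math.log(baseline_risk / (1.0 - baseline_risk))


@dataclass(frozen=True)
class EffectSpec:
    """Generating effects of one scenario, on both clinical and logit scales.

    Attributes
    ----------
    baseline_risk : float
        Risk of the outcome in control patients without the PF.
    treatment_rr : float
        Relative risk of the outcome under treatment vs control, among
        patients without the PF.
    pf_rr : float
        Relative risk of the outcome for PF-positive vs PF-negative
        patients, in the control arm.
    b0, b1, b2 : float
        The corresponding logistic coefficients (log odds / log odds
        ratios), stored at full double precision.
    """

    baseline_risk: float
    treatment_rr: float
    pf_rr: float
    b0: float = field(init=False)
    b1: float = field(init=False)
    b2: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "b0", float(logit(self.baseline_risk)))
        object.__setattr__(self, "b1", rr_to_log_or(self.treatment_rr, self.baseline_risk))
        object.__setattr__(self, "b2", rr_to_log_or(self.pf_rr, self.baseline_risk))

    @property
    def true_or(self) -> float:
        """Conditional treatment odds ratio, exp(b1)."""
        return math.exp(self.b1)

    @property
    def true_orr(self) -> float:
        """Conditional odds-ratio reduction, 1 - exp(b1)."""
        return 1.0 - math.exp(self.b1)


def cell_probability(effects: EffectSpec, t: int, c: int) -> float:
    """Outcome probability for the (treatment=t, PF=c) cell, t, c in {0, 1}."""
    if t not in (0, 1) or c not in (0, 1):
        raise ValueError(f"t and c must be 0 or 1, got t={t}, c={c}")
    return float(expit(effects.b0 + effects.b1 * t + effects.b2 * c))


def marginal_log_or(effects: EffectSpec, lam: float) -> float:
    """Analytic marginal (collapsed) treatment log odds ratio at prevalence lam.

    Collapses the true 2x2x2 probability table over the PF, assuming the PF
    has prevalence ``lam`` in both arms, and returns the log odds ratio of
    the two marginal risks.  Equals ``b1`` when ``b2 == 0`` or ``lam`` is 0
    or 1; otherwise lies between 0 and ``b1`` (attenuation toward the null
    -- non-collapsibility of the odds ratio).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {lam}")
    r0 = (1.0 - lam) * cell_probability(effects, 0, 0) + lam * cell_probability(effects, 0, 1)
    r1 = (1.0 - lam) * cell_probability(effects, 1, 0) + lam * cell_probability(effects, 1, 1)
    return math.log(r1 / (1.0 - r1)) - math.log(r0 / (1.0 - r0))


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: effects plus the design grids.

    ``imbalance_delta`` is 0 in the unconditional setting (PF counts are
    random) and 0.05 in the conditional setting (a fixed 5-percentage-point
    PF excess in the control arm).
    """

    scenario_id: int
    effects: EffectSpec
    lambda_grid: tuple[float, ...]
    n_grid: tuple[int, ...]
    setting: Setting
    imbalance_delta: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        lams = self.lambda_grid
        if any(not 0.0 < l < 1.0 for l in lams):
            raise ValueError("lambda grid values must be strictly in (0, 1)")
        if list(lams) != sorted(lams):
            raise ValueError("lambda grid must be sorted ascending")
        if any(n < 1 for n in self.n_grid):
            raise ValueError("per-arm sizes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def build_scenario(
    scenario_id: int,
    setting: Setting = "unconditional",
    n_replicates: int = 10_000,
    seed: int = 0,
    lambda_grid: Sequence[float] | None = None,
    n_grid: Sequence[int] | None = None,
) -> ScenarioSpec:
    """Build one of the eight default scenarios.

    Coefficients are recomputed from the clinical inputs via
    :func:`rr_to_log_or`, never hard-coded.  The prevalence grid follows the
    setting unless overridden.
    """
    if scenario_id not in SCENARIO_TABLE:
        raise ValueError(f"unknown scenario_id {scenario_id}; expected 1-8")
    if setting not in ("unconditional", "conditional"):
        raise ValueError(f"unknown setting {setting!r}")
    baseline_risk, treatment_rr, pf_rr = SCENARIO_TABLE[scenario_id]
    if lambda_grid is None:
        lambda_grid = (
            UNCONDITIONAL_LAMBDA_GRID if setting == "unconditional" else CONDITIONAL_LAMBDA_GRID
        )
    if n_grid is None:
        n_grid = DEFAULT_N_GRID
    delta = 0.0 if setting == "unconditional" else CONDITIONAL_IMBALANCE_DELTA
    return ScenarioSpec(
        scenario_id=scenario_id,
        effects=EffectSpec(baseline_risk, treatment_rr, pf_rr),
        lambda_grid=tuple(float(l) for l in lambda_grid),
        n_grid=tuple(int(n) for n in n_grid),
        setting=setting,
        imbalance_delta=delta,
        n_replicates=int(n_replicates),
        seed=int(seed),
    )
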