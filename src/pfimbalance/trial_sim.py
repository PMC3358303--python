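"""Trial generator: one parallel-group RCT as four treatment-by-PF cells.

Equal allocation puts ``n`` patients in each arm.  In the *unconditional*
design the number of PF-positive patients in each arm is drawn
``Binomial(n, lam)`` independently of treatment, so between-arm imbalance in
the PF arises purely by chance.  In the *conditional* design the PF counts
are fixed constants chosen so the control arm has a 5-percentage-point PF
excess at a given overall prevalence -- the design deliberately conditions
on an imbalanced randomization.

Given the PF split, the event count in each (t, c) cell is Binomial with
the cell probability from the generating logistic model.  Sampling cells as
binomials is distributionally identical to simulating each patient as a
Bernoulli draw, because patients within a cell are i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effects import EffectSpec, ScenarioSpec, cell_probability

__all__ = [
    "TrialCounts",
    "conditional_pf_counts",
    "simulate_unconditional",
    "simulate_conditional",
    "simulate_unconditional_batch",
    "simulate_conditional_batch",
    "CELL_ORDER",
]

#: Column order of the flattened cell arrays used throughout: (t, c) pairs.
CELL_ORDER: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class TrialCounts:
    """Aggregated counts of one simulated trial.

    ``n_patients[t, c]`` and ``n_events[t, c]`` are 2x2 integer arrays
    indexed by treatment ``t`` and PF status ``c``.
    """

    n_patients: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        npat = np.asarray(self.n_patients, dtype=np.int64)
        nev = np.asarray(self.n_events, dtype=np.int64)
        if npat.shape != (2, 2) or nev.shape != (2, 2):
            raise ValueError("n_patients and n_events must be 2x2 arrays")
        if (npat < 0).any() or (nev < 0).any() or (nev > npat).any():
            raise ValueError("counts must satisfy 0 <= events <= patients per cell")
        object.__setattr__(self, "n_patients", npat)
        object.__setattr__(self, "n_events", nev)

    @property
    def n0(self) -> int:
        """Control-arm size."""
        return int(self.n_patients[0].sum())

    @property
    def n1(self) -> int:
        """Treatment-arm size."""
        return int(self.n_patients[1].sum())

    @property
    def pf_counts(self) -> tuple[int, int]:
        """(control, treatment) PF-positive counts."""
        return int(self.n_patients[0, 1]), int(self.n_patients[1, 1])

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Cells flattened in :data:`CELL_ORDER` as (patients, events)."""
        idx = tuple(zip(*CELL_ORDER))
        return self.n_patients[idx], self.n_events[idx]


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; numpy/python round are half-to-even
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def conditional_pf_counts(lam: float, n: int, delta: float = 0.05) -> tuple[int, int]:
    """Fixed PF-positive counts (control, treatment) for the conditional design.

    The control arm gets ``round(n*(lam + delta/2))`` PF-positive patients
    and the treatment arm ``round(n*(lam - delta/2))`` (round half away from
    zero).  When rounding breaks the between-arm difference, the treatment
    count is adjusted so that ``m_control - m_treat == round(n*delta)``: the
    imposed imbalance is the design constraint, the overall prevalence is
    matched only up to rounding.

    Raises
    ------
    ValueError
        If the target counts are infeasible for the arm size.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {lam}")
    m_control = _round_half_away(n * (lam + delta / 2.0))
    m_treat = _round_half_away(n * (lam - delta / 2.0))
    target_diff = _round_half_away(n * delta)
    if m_control - m_treat != target_diff:
        m_treat = m_control - target_diff
    if m_treat < 0 or m_control > n:
        raise ValueError(
            f"infeasible conditional design: lam={lam}, n={n}, delta={delta} "
            f"gives PF counts ({m_control}, {m_treat})"
        )
    return m_control, m_treat


def _cell_probs(effects: EffectSpec) -> np.ndarray:
    return np.array([cell_probability(effects, t, c) for t, c in CELL_ORDER])


def simulate_unconditional_batch(
    effects: EffectSpec,
    lam: float,
    n: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many unconditional trials at once.

    Returns ``(n_patients, n_events)``, each of shape
    ``(n_replicates, 4)`` with columns in :data:`CELL_ORDER`.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {lam}")
    if n < 1:
        raise ValueError(f"per-arm size must be >= 1, got {n}")
    m0 = rng.binomial(n, lam, size=n_replicates)  # PF-positive, control
    m1 = rng.binomial(n, lam, size=n_replicates)  # PF-positive, treatment
    npat = np.column_stack([n - m0, m0, n - m1, m1]).astype(np.int64)
    probs = _cell_probs(effects)
    nev = rng.binomial(npat, probs[None, :])
    return npat, nev.astype(np.int64)


def simulate_conditional_batch(
    effects: EffectSpec,
    lam: float,
    n: int,
    n_replicates: int,
    rng: np.random.Generator,
    delta: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many conditional trials (fixed PF split) at once."""
    m_control, m_treat = conditional_pf_counts(lam, n, delta)
    row = np.array([n - m_control, m_control, n - m_treat, m_treat], dtype=np.int64)
    npat = np.broadcast_to(row, (n_replicates, 4)).copy()
    probs = _cell_probs(effects)
    nev = rng.binomial(npat, probs[None, :])
    return npat, nev.astype(np.int64)


def _to_trial(npat_row: np.ndarray, nev_row: np.ndarray) -> TrialCounts:
    npat = np.zeros((2, 2), dtype=np.int64)
    nev = np.zeros((2, 2), dtype=np.int64)
    for j, (t, c) in enumerate(CELL_ORDER):
        npat[t, c] = npat_row[j]
        nev[t, c] = nev_row[j]
    return TrialCounts(npat, nev)


def simulate_unconditional(
    spec: ScenarioSpec | EffectSpec,
    lam: float,
    n: int,
    rng: np.random.Generator,
) -> TrialCounts:
    """Simulate one trial with PF counts drawn Binomial(n, lam) per arm."""
    effects = spec.effects if isinstance(spec, ScenarioSpec) else spec
    npat, nev = simulate_unconditional_batch(effects, lam, n, 1, rng)
    return _to_trial(npat[0], nev[0])


def simulate_conditional(
    spec: ScenarioSpec | EffectSpec,
    lam: float,
    n: int,
    rng: np.random.Generator,
    delta: float | None = None,
) -> TrialCounts:
    """Simulate one trial with a fixed between-arm PF imbalance."""
    if isinstance(spec, ScenarioSpec):
        effects = spec.effects
        if delta is None:
            delta = spec.imbalance_delta
    else:
        effects = spec
        if delta is None:
            delta = 0.05
    npat, nev = simulate_conditional_batch(effects, lam, n, 1, rng, delta)
    return _to_trial(npat[0], nev[0])
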