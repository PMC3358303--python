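"""Trial generator: PF splits, event generation, and the per-patient oracle."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from pfimbalance import (
    TrialCounts,
    build_scenario,
    cell_probability,
    conditional_pf_counts,
    simulate_conditional,
    simulate_unconditional,
)
from pfimbalance.trial_sim import (
    CELL_ORDER,
    simulate_conditional_batch,
    simulate_unconditional_batch,
)


class TestTrialCounts:
    def test_rejects_events_exceeding_patients(self):
        with pytest.raises(ValueError):
            TrialCounts(np.ones((2, 2)), np.full((2, 2), 2))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            TrialCounts(np.full((2, 2), -1), np.zeros((2, 2)))

    def test_arm_totals(self):
        tc = TrialCounts([[3, 2], [4, 1]], [[1, 1], [0, 0]])
        assert tc.n0 == 5 and tc.n1 == 5
        assert tc.pf_counts == (2, 1)


class TestConditionalCounts:
    @pytest.mark.parametrize(
        "lam, n, expected",
        [
            (0.5, 1000, (525, 475)),
            (0.05, 2000, (150, 50)),
            (0.5, 2000, (1050, 950)),
        ],
    )
    def test_reference_splits(self, lam, n, expected):
        assert conditional_pf_counts(lam, n) == expected

    def test_zero_delta_reduces_to_balanced_design(self):
        m0, m1 = conditional_pf_counts(0.3, 200, delta=0.0)
        assert m0 == m1 == round(200 * 0.3)

    def test_difference_is_design_constraint(self):
        """m_control - m_treat equals round(0.05 n) even when rounding fights it."""
        for n in (25, 50, 125, 500, 1000, 2000):
            for lam in (0.05, 0.1, 0.3, 0.5, 0.7, 0.95):
                m0, m1 = conditional_pf_counts(lam, n)
                assert m0 - m1 == int(np.floor(0.05 * n + 0.5))
                # pooled prevalence matches lam up to integer rounding
                assert abs((m0 + m1) / (2 * n) - lam) <= 1.0 / n

    def test_exact_five_percent_when_quarter_integer(self):
        for n in (1000, 2000):
            m0, m1 = conditional_pf_counts(0.5, n)
            assert (m0 - m1) / n == pytest.approx(0.05, abs=1e-15)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            conditional_pf_counts(0.99, 100)


class TestUnconditional:
    def test_rare_pf_limit_puts_everyone_in_baseline_cells(self, effects1):
        rng = np.random.default_rng(0)
        tc = simulate_unconditional(effects1, 1e-12, 100, rng)
        assert tc.pf_counts == (0, 0)
        assert tc.n_patients[0, 0] == tc.n_patients[1, 0] == 100

    def test_pooled_pf_prevalence_converges(self, effects1):
        rng = np.random.default_rng(1)
        lam, n, reps = 0.3, 200, 10_000
        npat, _ = simulate_unconditional_batch(effects1, lam, n, reps, rng)
        pooled = (npat[:, 1] + npat[:, 3]).sum() / (2 * n * reps)
        se = np.sqrt(lam * (1 - lam) / (2 * n * reps))
        assert abs(pooled - lam) < 3 * se

    @pytest.mark.parametrize("cell, expected", [(1, 0.50), (3, 0.421875)])
    def test_cell_event_rates_match_generating_model(self, effects1, cell, expected):
        rng = np.random.default_rng(2)
        npat, nev = simulate_unconditional_batch(effects1, 0.5, 2000, 1000, rng)
        rate = nev[:, cell].sum() / npat[:, cell].sum()
        se = np.sqrt(expected * (1 - expected) / npat[:, cell].sum())
        assert abs(rate - expected) < 3 * se

    def test_invalid_inputs(self, effects1):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_unconditional(effects1, 0.0, 100, rng)
        with pytest.raises(ValueError):
            simulate_unconditional(effects1, 0.5, 0, rng)


class TestConditionalSimulation:
    def test_pf_counts_are_fixed_constants(self, effects1):
        rng = np.random.default_rng(3)
        npat, _ = simulate_conditional_batch(effects1, 0.5, 1000, 50, rng)
        assert (npat[:, 1] == 525).all()  # control PF-positive
        assert (npat[:, 3] == 475).all()  # treatment PF-positive

    def test_single_trial_wrapper(self, scenario1):
        spec = build_scenario(1, "conditional")
        rng = np.random.default_rng(4)
        tc = simulate_conditional(spec, 0.05, 2000, rng)
        assert tc.pf_counts == (150, 50)


def _per_patient_oracle(effects, lam, n, reps, rng):
    """Independent patient-level Bernoulli simulation of one arm (t fixed).

    Returns per-replicate (pf_count, events_pf, events_nopf) for arm t=0.
    """
    out = np.empty((reps, 3), dtype=np.int64)
    p0 = cell_probability(effects, 0, 0)
    p1 = cell_probability(effects, 0, 1)
    for r in range(reps):
        c = rng.random(n) < lam
        y = rng.random(n) < np.where(c, p1, p0)
        out[r] = (c.sum(), int(y[c].sum()), int(y[~c].sum()))
    return out


def test_cellwise_binomial_matches_per_patient_bernoulli(effects1):
    """The 4-cell binomial shortcut and patient-level simulation agree in law.

    Compared on the full joint outcome (PF count, events by PF status) of a
    5-patient arm via a chi-square homogeneity test at alpha = 0.001.
    """
    lam, n, reps = 0.3, 5, 100_000
    rng = np.random.default_rng(5)
    oracle = _per_patient_oracle(effects1, lam, n, reps, rng)
    npat, nev = simulate_unconditional_batch(effects1, lam, n, reps, rng)
    cellwise = np.column_stack([npat[:, 1], nev[:, 1], nev[:, 0]])

    # categorize each replicate by its (m, y_pf, y_nopf) triple
    keys = oracle[:, 0] * 100 + oracle[:, 1] * 10 + oracle[:, 2]
    keys2 = cellwise[:, 0] * 100 + cellwise[:, 1] * 10 + cellwise[:, 2]
    cats = np.union1d(keys, keys2)
    count1 = np.array([(keys == k).sum() for k in cats])
    count2 = np.array([(keys2 == k).sum() for k in cats])
    # pool sparse categories so the chi-square approximation holds
    big = (count1 + count2) >= 20
    table = np.array(
        [
            np.append(count1[big], count1[~big].sum()),
            np.append(count2[big], count2[~big].sum()),
        ]
    )
    table = table[:, table.sum(axis=0) > 0]
    _, pvalue, _, _ = chi2_contingency(table)
    assert pvalue > 0.001


def test_cell_order_is_t_major():
    assert CELL_ORDER == ((0, 0), (0, 1), (1, 0), (1, 1))
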