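"""Logistic fits: closed forms, likelihood optimality, and library cross-checks."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from pfimbalance import (
    EffectSpec,
    TrialCounts,
    fit_adjusted,
    fit_adjusted_batch,
    fit_unadjusted,
    fit_unadjusted_batch,
    marginal_log_or,
    wald_ci,
)
from pfimbalance.trial_sim import CELL_ORDER, simulate_unconditional_batch


def _trial(cells):
    """cells: dict (t, c) -> (n_patients, n_events)."""
    npat = np.zeros((2, 2), dtype=int)
    nev = np.zeros((2, 2), dtype=int)
    for (t, c), (np_, ne_) in cells.items():
        npat[t, c] = np_
        nev[t, c] = ne_
    return TrialCounts(npat, nev)


class TestWaldCI:
    def test_standard_normal_interval(self):
        lo, hi = wald_ci(0.0, 1.0)
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    def test_shifted_scaled(self):
        lo, hi = wald_ci(-0.315, 0.1)
        assert lo == pytest.approx(-0.511, abs=5e-4)
        assert hi == pytest.approx(-0.119, abs=5e-4)

    def test_ci_excludes_zero_iff_wald_statistic_exceeds_z(self):
        for beta, se in [(0.2, 0.1), (0.19, 0.1), (0.196, 0.1), (-0.5, 0.3)]:
            lo, hi = wald_ci(beta, se)
            excludes = lo > 0 or hi < 0
            assert excludes == (abs(beta / se) > 1.959964)

    def test_invalid(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, 0.0)
        with pytest.raises(ValueError):
            wald_ci(0.0, 1.0, level=1.5)


class TestUnadjusted:
    def test_closed_form_two_by_two(self):
        # 10/100 events treated vs 20/100 control
        tc = _trial({(1, 0): (100, 10), (0, 0): (100, 20)})
        fit = fit_unadjusted(tc)
        assert fit.beta1_hat == pytest.approx(-0.810930, abs=1e-6)
        assert fit.se1 == pytest.approx(0.416667, abs=1e-6)
        assert not fit.corrected and fit.converged

    def test_equal_arms_give_zero(self):
        tc = _trial({(1, 0): (80, 12), (0, 0): (80, 12)})
        assert fit_unadjusted(tc).beta1_hat == 0.0

    def test_zero_cell_triggers_continuity_correction(self):
        tc = _trial({(1, 0): (50, 0), (0, 0): (50, 5)})
        fit = fit_unadjusted(tc)
        assert fit.corrected and fit.converged
        assert np.isfinite(fit.beta1_hat) and np.isfinite(fit.se1)
        # 0.5-augmented table: log[(0.5/50.5)/(5.5/45.5)]
        expected = np.log(0.5 / 50.5) - np.log(5.5 / 45.5)
        assert fit.beta1_hat == pytest.approx(expected, abs=1e-10)

    def test_empty_arm_raises(self):
        with pytest.raises(ValueError):
            fit_unadjusted(_trial({(0, 0): (100, 10)}))

    def test_orr_definition(self):
        tc = _trial({(1, 0): (100, 10), (0, 0): (100, 20)})
        fit = fit_unadjusted(tc)
        assert fit.orr_hat == pytest.approx(1 - np.exp(fit.beta1_hat), abs=1e-12)


class TestAdjusted:
    def test_reduces_to_unadjusted_when_pf_absent(self):
        tc = _trial({(1, 0): (100, 10), (0, 0): (100, 20)})
        fa, fu = fit_adjusted(tc), fit_unadjusted(tc)
        assert fa.beta1_hat == pytest.approx(fu.beta1_hat, abs=1e-10)
        assert fa.se1 == pytest.approx(fu.se1, abs=1e-10)

    def test_consistency_at_idealized_expectation(self, effects1):
        """Cell events set to their expectation at huge n recover the truth."""
        n = 10**6
        half = n // 2
        cells = {}
        for t, c in CELL_ORDER:
            p = expit(effects1.b0 + effects1.b1 * t + effects1.b2 * c)
            cells[(t, c)] = (half, round(p * half))
        tc = _trial(cells)
        fa = fit_adjusted(tc)
        assert fa.beta1_hat == pytest.approx(-0.315, abs=5e-4)
        # the unadjusted fit targets the attenuated marginal log OR instead
        fu = fit_unadjusted(tc)
        assert fu.beta1_hat == pytest.approx(marginal_log_or(effects1, 0.5), abs=1e-3)

    def test_separation_falls_back_to_corrected_fit(self):
        # no events at all among treated -> infinite treatment MLE
        tc = _trial({(1, 0): (20, 0), (1, 1): (20, 0), (0, 0): (20, 5), (0, 1): (20, 10)})
        fit = fit_adjusted(tc)
        assert fit.corrected
        assert fit.converged
        assert np.isfinite(fit.beta1_hat) and np.isfinite(fit.se1)

    def test_fit_matches_statsmodels_on_aggregated_cells(self, effects1, rng):
        """Independent route: statsmodels GLM on the same binomial cells."""
        npat, nev = simulate_unconditional_batch(effects1, 0.3, 125, 20, rng)
        fits = fit_adjusted_batch(npat, nev)
        X = sm.add_constant(np.array([[t, c] for t, c in CELL_ORDER], dtype=float))
        for r in range(20):
            if fits.corrected[r] or not fits.converged[r]:
                continue
            endog = np.column_stack([nev[r], npat[r] - nev[r]])
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(tol=1e-12)
            assert fits.beta1[r] == pytest.approx(res.params[1], rel=1e-6, abs=1e-6)
            assert fits.se1[r] == pytest.approx(res.bse[1], rel=1e-5)

    def test_aggregation_invariance_patient_level(self, effects1, rng):
        """Fitting the patient-level expansion gives identical inference."""
        npat, nev = simulate_unconditional_batch(effects1, 0.4, 25, 10, rng)
        fits = fit_adjusted_batch(npat, nev)
        for r in range(10):
            if fits.corrected[r] or not fits.converged[r]:
                continue
            rows, ys = [], []
            for j, (t, c) in enumerate(CELL_ORDER):
                for i in range(int(npat[r, j])):
                    rows.append([1.0, t, c])
                    ys.append(1.0 if i < nev[r, j] else 0.0)
            res = sm.Logit(np.array(ys), np.array(rows)).fit(disp=False)
            assert fits.beta1[r] == pytest.approx(res.params[1], abs=1e-5)
            assert fits.se1[r] == pytest.approx(res.bse[1], abs=1e-5)

    def test_likelihood_is_maximal_on_grid(self, effects1, rng):
        """ML oracle: no point on a grid around the estimate beats its log-likelihood."""
        npat, nev = simulate_unconditional_batch(effects1, 0.3, 25, 50, rng)
        fits = fit_adjusted_batch(npat, nev)
        X = np.array([[1.0, t, c] for t, c in CELL_ORDER])
        offsets = np.linspace(-0.5, 0.5, 21)
        g = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1).reshape(-1, 3)
        checked = 0
        for r in range(50):
            if fits.corrected[r] or not fits.converged[r]:
                continue
            beta_hat = np.asarray(fits.beta[r])

            def loglik(betas):
                eta = betas @ X.T
                return np.sum(nev[r] * eta - npat[r] * np.logaddexp(0.0, eta), axis=-1)

            assert loglik(beta_hat[None, :])[0] >= loglik(beta_hat + g).max() - 1e-8
            checked += 1
        assert checked >= 25

    def test_collapsibility_when_pf_not_prognostic(self, rng):
        """With b2 = 0 the two models estimate the same quantity on average."""
        effects = EffectSpec(0.10, 0.75, 1.0)
        assert effects.b2 == 0.0
        npat, nev = simulate_unconditional_batch(effects, 0.5, 500, 2000, rng)
        fa = fit_adjusted_batch(npat, nev)
        fu = fit_unadjusted_batch(npat, nev)
        keep = fa.converged & fu.converged
        diff = fa.beta1[keep].mean() - fu.beta1[keep].mean()
        se = np.std(fa.beta1[keep] - fu.beta1[keep], ddof=1) / np.sqrt(keep.sum())
        assert abs(diff) < max(3 * se, 1e-3)
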