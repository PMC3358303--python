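"""What if a trial actually randomized 5% unevenly?

The conditional design fixes a 5-percentage-point excess of the
prognostic factor in the control arm.  Ignoring that factor in the
analysis then overestimates the treatment benefit (negative bias on the
log-OR scale).  Scenario: control risk 0.10, treatment RR 0.75, strong
prognostic factor (RR 5), 125 patients per arm.
"""

import numpy as np

from pfimbalance import build_scenario, fit_adjusted_batch, fit_unadjusted_batch, summarize
from pfimbalance.trial_sim import simulate_conditional_batch

REPS = 10_000
spec = build_scenario(1, "conditional")
e = spec.effects
rng = np.random.default_rng(1)

print(f"true conditional log OR: {e.b1:+.4f}; 5% PF excess in the control arm")
print(f"{'prevalence':>10} {'unadj bias':>11} {'adj bias':>9}")
for lam in (0.05, 0.1, 0.2, 0.5, 0.8):
    npat, nev = simulate_conditional_batch(e, lam, 125, REPS, rng, spec.imbalance_delta)
    su = summarize(fit_unadjusted_batch(npat, nev), e.b1)
    sa = summarize(fit_adjusted_batch(npat, nev), e.b1)
    print(f"{lam:>10.2f} {su.bias:>+11.3f} {sa.bias:>+9.3f}")

print()
print("Unadjusted estimates are too favourable to the treatment (bias down to")
print("about -0.19 when the factor is rare); adjustment removes nearly all of")
print("the chance confounding.")
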