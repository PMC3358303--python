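"""Does adjusting for a strong prognostic factor pay off?

Simulates trials with control risk 0.10, treatment RR 0.75 and a strong
prognostic factor (RR 5, prevalence 0.5), fits logistic models with and
without the factor, and compares bias, CI coverage and power against the
true conditional log OR (-0.315).
"""

import numpy as np

from pfimbalance import (
    build_scenario,
    fit_adjusted_batch,
    fit_unadjusted_batch,
    power_loss,
    summarize,
)
from pfimbalance.trial_sim import simulate_unconditional_batch

REPS = 10_000
spec = build_scenario(1)
e = spec.effects
rng = np.random.default_rng(0)

print(f"true conditional log OR: {e.b1:+.4f};  {REPS} simulated trials per cell")
print(f"{'n/arm':>6} {'model':>10} {'bias':>8} {'SD':>7} {'coverage':>9} {'power':>7}")
for n in (125, 500, 2000):
    npat, nev = simulate_unconditional_batch(e, 0.5, n, REPS, rng)
    su = summarize(fit_unadjusted_batch(npat, nev), e.b1)
    sa = summarize(fit_adjusted_batch(npat, nev), e.b1)
    for s, name in ((su, "unadjusted"), (sa, "adjusted")):
        print(
            f"{n:>6} {name:>10} {s.bias:>+8.3f} {s.empirical_sd:>7.3f} "
            f"{s.coverage:>9.4f} {s.power:>7.4f}"
        )
    print(f"       relative power loss of unadjusted: "
          f"{power_loss(su, sa, relative=True):.2f}%")

print()
print("Omitting the factor biases the estimate toward the null (~ -0.26 vs")
print("-0.315); its CI then under-covers the conditional effect as n grows,")
print("while the adjusted model stays near 95% coverage with more power.")
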