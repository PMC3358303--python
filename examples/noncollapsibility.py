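"""Marginal vs conditional odds ratio: non-collapsibility without confounding.

Even with the prognostic factor perfectly balanced between arms, the odds
ratio collapsed over the factor differs from the within-stratum odds
ratio.  This script evaluates both analytically for a trial with control
risk 0.10, treatment relative risk 0.75 and a strong prognostic factor
(relative risk 5) across the factor's prevalence.
"""

import math

from pfimbalance import build_scenario, marginal_log_or

effects = build_scenario(1).effects
print(f"conditional log OR (b1): {effects.b1:+.4f}   OR {math.exp(effects.b1):.3f}")
print()
print(f"{'prevalence':>10}  {'marginal log OR':>15}  {'marginal OR':>11}")
for lam in (0.0, 0.05, 0.2, 0.5, 0.8, 0.95, 1.0):
    m = marginal_log_or(effects, lam)
    print(f"{lam:>10.2f}  {m:>+15.4f}  {math.exp(m):>11.3f}")

print()
print("The marginal effect is attenuated toward the null (largest attenuation")
print("near prevalence 0.5) and coincides with the conditional effect only")
print("when one stratum is empty.  An unadjusted logistic model estimates the")
print("marginal quantity, so it under-states the subject-specific effect.")
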