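"""Two-proportion sample-size anchor for the simulation grid.

A trial aiming to detect a moderate treatment effect (relative risk 0.75)
against a 10% control-arm risk, with two-sided alpha 0.05 and 80% power,
needs about 2000 patients per arm by the unpooled normal-approximation
formula.  The study's sample-size grid is built around this anchor.
"""

from pfimbalance import required_sample_size

n = required_sample_size(p0=0.10, rr=0.75, alpha=0.05, power=0.80)
n_pooled = required_sample_size(p0=0.10, rr=0.75, variance="pooled")
print(f"unpooled variance: {n} per arm ({2 * n} total)")
print(f"pooled variance:   {n_pooled} per arm ({2 * n_pooled} total)")
print()
print("The grid 25, 50, 125, 500, 1000, 2000 per arm spans 1/16 to 1x of")
print("this requirement, plus two deliberately under-powered small-trial sizes.")
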