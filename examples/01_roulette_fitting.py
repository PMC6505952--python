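"""Fit a parametric subjective distribution to one trial-roulette histogram.

An expert believes forb richness in reference-condition grassy woodland lies
between 8 and 32 species per plot and allocates 100 chips over 10 equal bins.
We fit a normal by least squares on the cumulative bin probabilities, then
draw Monte-Carlo samples from it.
"""

import numpy as np

import offsetgain as og

record = og.RouletteElicitation(
    expert_id="E01", scenario_id="demo", attribute="forb_richness",
    state="reference", theta_min=8.0, theta_max=32.0,
    chips=(0, 2, 8, 18, 26, 22, 14, 7, 2, 1),
)
og.validate_elicitation(record)

dist = og.fit_distribution(record)
print(f"family: {dist.family}")
print(f"mu = {dist.params[0]:.2f} species, sigma = {dist.params[1]:.2f}")
print(f"CDF-matching SSE at the 9 interior bin edges: {dist.fit_sse:.2e}")

draws = og.sample(dist, 1000, rng=np.random.default_rng(1))
print(f"1000 draws: mean {draws.mean():.2f}, min {draws.min():.2f} "
      "(count attributes are floored at 0)")
# The fitted mean is the expert's central estimate of reference-state forb
# richness; sigma quantifies their uncertainty, and the tiny SSE shows the
# normal family reproduces the elicited histogram almost exactly.
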