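"""Fit the mixed-effects Emax model and run the OFV-based covariate search.

Simulates a corpus in which only baseline ESSDAI truly drives the maximum
placebo response, then checks that forward inclusion (delta-OFV > 3.84) and
backward elimination (delta-OFV >= 6.63) recover exactly that covariate.
"""

from placebo_mbma import (
    FitConfig,
    forward_backward,
    reference_parameters,
    sample_design,
    simulate_dataset,
)

truth = reference_parameters()
ds = simulate_dataset(sample_design(13, seed=0), truth, seed=1000)

selected, log, result = forward_backward(
    ds, ["baseline_essdai", "male_pct"], FitConfig()
)

print(log.to_frame().to_string(index=False))
print()
print(f"selected covariates: {selected or '(none)'}")
print()
print(result.summary())
print()
print("theta_emax is the typical maximum placebo response at this corpus's")
print("median baseline; the baseline coefficient (truth 0.552 points/point)")
print("says how much that maximum grows per point of baseline ESSDAI.")
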