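"""Qualify a fitted model: GOF residuals, VPC coverage, SIR uncertainty.

Runs the diagnostics at reduced Monte-Carlo sizes so the example finishes in
well under a minute; production sizes are n_sim=1000 (VPC) and 5000/1000
(SIR proposals/resamples).
"""

from placebo_mbma import (
    FitConfig,
    fit,
    gof_table,
    reference_parameters,
    sample_design,
    simulate_dataset,
    sir,
    vpc,
)

truth = reference_parameters()
ds = simulate_dataset(sample_design(13, seed=7), truth, seed=8)
result = fit(ds, ["baseline_essdai"], FitConfig())

gof = gof_table(result, ds)
print(f"CWRES mean {gof['cwres'].mean():+.3f}, SD {gof['cwres'].std():.3f} "
      "(a well-specified model gives ~0 and ~1)")

v = vpc(result, ds, n_sim=500, seed=9)
print(f"VPC: {100 * v.fraction_inside():.1f}% of observations inside the "
      "simulated 2.5-97.5% band (target ~95%)")

s = sir(result, ds, n_proposal=1000, n_resample=250, seed=10)
print(f"SIR effective sample size: {s.ess:.0f}")
print(s.summary.round(3).to_string())
print("SIR medians close to the point estimates indicate robust parameters;")
print("the 95% columns are the resampling-based confidence limits.")
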