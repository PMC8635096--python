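"""Generate a synthetic corpus of placebo arms and write it as a long CSV.

The design distributions mirror the pooled corpus of randomized Sjögren
trials: 13 placebo arms, arm sizes 4-95 (median ~19), durations 12-48 weeks,
baseline ESSDAI 2.5-13.1.
"""

from placebo_mbma import reference_parameters, sample_design, simulate_dataset, write_dataset

params = reference_parameters()
design = sample_design(n_trials=13, seed=1)
ds = simulate_dataset(design, params, seed=2)
path = write_dataset(ds, "synthetic_corpus.csv")

print(f"wrote {ds.n_trials} trials / {ds.n_obs} arm-level observations to {path}")
for trial in ds.trials[:3]:
    cov = trial.covariates
    print(f"  {trial.trial_id}: N={trial.observations[0].n_subjects}, "
          f"baseline ESSDAI {cov.baseline_essdai:.1f}, "
          f"visits at weeks {[o.time_weeks for o in trial.observations]}")
print("each row holds the arm's mean ESSDAI change from baseline at one visit;")
print("negative change = clinical improvement under placebo.")
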