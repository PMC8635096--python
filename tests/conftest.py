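import numpy as np
import pytest

from placebo_mbma import (
    MetaDataset,
    ObservationRecord,
    Trial,
    TrialCovariates,
    reference_parameters,
    sample_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def ref_params():
    """Pooled-model parameter estimates used as simulation truth."""
    return reference_parameters()


@pytest.fixture(scope="session")
def corpus3(ref_params):
    """Small 3-trial synthetic corpus at the pooled-model truth."""
    design = sample_design(3, seed=101)
    return simulate_dataset(design, ref_params, seed=201)


@pytest.fixture(scope="session")
def corpus13(ref_params):
    """Corpus-sized (13-trial) synthetic dataset at the pooled-model truth."""
    design = sample_design(13, seed=11)
    return simulate_dataset(design, ref_params, seed=111)


def make_trial(trial_id="T1", baseline=10.0, times=(12.0, 24.0), changes=(-1.0, -2.0),
               n=20, duration=24.0, **cov):
    observations = tuple(
        ObservationRecord(t, c, n) for t, c in zip(times, changes)
    )
    covariates = TrialCovariates(baseline_essdai=baseline, duration_weeks=duration,
                                 **cov)
    return Trial(trial_id, covariates, observations)


@pytest.fixture
def two_trial_dataset():
    return MetaDataset(
        (
            make_trial("T1", baseline=8.0, times=(4.0, 12.0, 24.0),
                       changes=(-0.5, -1.2, -1.8), n=15, age_years=55.0),
            make_trial("T2", baseline=11.5, times=(12.0, 24.0, 48.0),
                       changes=(-1.0, -2.4, -3.1), n=40, duration=48.0),
        )
    )
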