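"""Dataset model, CSV round-trips, and the covariate missingness rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from placebo_mbma import (
    DataFormatError,
    DataValidationError,
    MetaDataset,
    ObservationRecord,
    Trial,
    TrialCovariates,
    prepare_covariates,
    read_dataset,
    write_dataset,
)

from conftest import make_trial


def test_read_groups_and_sorts(tmp_path, two_trial_dataset):
    path = write_dataset(two_trial_dataset, tmp_path / "ds.csv")
    ds = read_dataset(path)
    assert ds.n_trials == 2 and ds.n_obs == 6
    assert [t.trial_id for t in ds.trials] == ["T1", "T2"]
    for t in ds.trials:
        assert np.all(np.diff(t.times) > 0)


def test_round_trip_identity(tmp_path, two_trial_dataset):
    path = write_dataset(two_trial_dataset, tmp_path / "ds.csv")
    once = read_dataset(path)
    path2 = write_dataset(once, tmp_path / "ds2.csv")
    assert read_dataset(path2).to_frame().equals(once.to_frame())
    # missing covariates survive as missing
    assert once.trial("T1").covariates.male_pct is None
    assert once.trial("T1").covariates.age_years == 55.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(
        st.floats(2.6, 13.0),                      # baseline
        st.integers(4, 95),                        # arm size
        st.lists(st.sampled_from([4.0, 8.0, 12.0, 24.0, 48.0]),
                 min_size=1, max_size=4, unique=True),
        st.one_of(st.none(), st.floats(40.0, 70.0)),   # age, possibly missing
    ),
    min_size=1, max_size=5,
))
def test_round_trip_property(tmp_path_factory, trials):
    built = []
    for i, (baseline, n, times, age) in enumerate(trials):
        times = sorted(times)
        obs = tuple(ObservationRecord(t, -0.1 * t, n) for t in times)
        cov = TrialCovariates(baseline_essdai=baseline, duration_weeks=48.0,
                              age_years=age)
        built.append(Trial(f"T{i}", cov, obs))
    ds = MetaDataset(tuple(built))
    path = tmp_path_factory.mktemp("rt") / "ds.csv"
    write_dataset(ds, path)
    back = read_dataset(path)
    assert back.to_frame().equals(ds.to_frame())


@pytest.mark.parametrize(
    "mutation, error, match",
    [
        (lambda df: df.drop(columns=["n_subjects"]), DataFormatError, "n_subjects"),
        (lambda df: df.assign(change_essdai=["x"] + list(df["change_essdai"][1:])),
         DataFormatError, "line 2"),
        (lambda df: pd.concat([df, df.iloc[[0]]]), DataValidationError, "duplicate"),
    ],
)
def test_read_errors(tmp_path, two_trial_dataset, mutation, error, match):
    df = mutation(two_trial_dataset.to_frame())
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(error, match=match):
        read_dataset(path)


def test_missing_n_subjects_carried_forward(tmp_path, two_trial_dataset):
    df = two_trial_dataset.to_frame()
    df.loc[df.index[1], "n_subjects"] = np.nan  # second visit of T1
    path = tmp_path / "locf.csv"
    df.to_csv(path, index=False)
    ds = read_dataset(path)
    assert ds.trial("T1").observations[1].n_subjects == 15


def test_empty_trial_rejected():
    cov = TrialCovariates(baseline_essdai=8.0, duration_weeks=24.0)
    with pytest.raises(DataValidationError, match="no observations"):
        Trial("T1", cov, ())


def test_invariant_violations_rejected():
    with pytest.raises(DataValidationError):
        ObservationRecord(-1.0, 0.0, 10)
    with pytest.raises(DataValidationError):
        ObservationRecord(4.0, 0.0, 0)
    with pytest.raises(DataValidationError):
        TrialCovariates(baseline_essdai=8.0, duration_weeks=24.0, male_pct=120.0)


class TestPrepareCovariates:
    def _corpus(self, ages):
        trials = tuple(
            make_trial(f"T{i}", baseline=8.0 + i * 0.1, age_years=a)
            for i, a in enumerate(ages)
        )
        return MetaDataset(trials)

    def test_forty_percent_missing_is_dropped(self):
        # 4 of 10 missing: the >= 40% rule is inclusive
        ds = self._corpus([50.0] * 6 + [None] * 4)
        out, report = prepare_covariates(ds)
        assert "age_years" in report.dropped
        assert "age_years" not in report.usable
        assert out.trial("T6").covariates.age_years is None

    def test_below_threshold_is_median_imputed(self):
        ds = MetaDataset(tuple(
            make_trial(f"T{i}", diagnosis_years=v)
            for i, v in enumerate([1.0, 3.0, None, 7.0, 9.0])
        ))
        out, report = prepare_covariates(ds)
        median, trial_ids = report.imputed["diagnosis_years"]
        assert median == 5.0 and trial_ids == ("T2",)
        assert out.trial("T2").covariates.diagnosis_years == 5.0

    def test_no_missing_is_identity(self):
        ds = MetaDataset(tuple(
            make_trial(f"T{i}", age_years=50.0 + i, male_pct=5.0,
                       diagnosis_years=4.0, base_therapy_pct=70.0)
            for i in range(3)
        ))
        out, report = prepare_covariates(ds)
        assert out is ds
        assert not report.dropped and not report.imputed
        assert set(report.usable) == {
            "baseline_essdai", "duration_weeks", "age_years", "male_pct",
            "diagnosis_years", "base_therapy_pct",
        }

    def test_idempotent_and_observations_untouched(self):
        ds = self._corpus([50.0, 52.0, None, 54.0, 56.0])
        once, _ = prepare_covariates(ds)
        twice, report2 = prepare_covariates(once)
        assert twice.to_frame().equals(once.to_frame())
        assert not report2.imputed
        for before, after in zip(ds.trials, once.trials):
            assert before.observations == after.observations
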