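"""Dataset I/O: Cockcroft-Gault, validation, round-trips, dialects."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vancopk.datasets import (
    SchemaError,
    StudyDataset,
    ValidationError,
    canonical_sex,
    cockcroft_gault,
    read_dataset,
    write_dataset,
)


class TestCockcroftGault:
    def test_study_median_male(self):
        expected = (140.0 - 54.0) * 75.0 / (72.0 * 0.935)
        got = cockcroft_gault(54, 75, 0.935, "male")
        assert got == pytest.approx(expected, rel=1e-12)
        assert round(got, 2) == 95.81

    def test_female_is_exactly_085_of_male(self):
        male = cockcroft_gault(54, 75, 0.935, "M")
        female = cockcroft_gault(54, 75, 0.935, "F")
        assert female == pytest.approx(0.85 * male, rel=1e-15)
        assert round(female, 2) == 81.44

    def test_vanishes_at_age_140(self):
        assert cockcroft_gault(140, 75, 1.0, "male") == 0.0

    def test_nonpositive_scr_rejected(self):
        with pytest.raises(ValueError):
            cockcroft_gault(54, 75, 0.0, "male")

    @given(
        age=st.floats(20, 90),
        wt=st.floats(40, 140),
        scr=st.floats(0.3, 5.0),
        d_age=st.floats(0.5, 10),
        d_wt=st.floats(0.5, 10),
        d_scr=st.floats(0.05, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotonicity(self, age, wt, scr, d_age, d_wt, d_scr):
        base = cockcroft_gault(age, wt, scr, "male")
        assert cockcroft_gault(age + d_age, wt, scr, "male") < base
        assert cockcroft_gault(age, wt + d_wt, scr, "male") > base
        assert cockcroft_gault(age, wt, scr + d_scr, "male") < base

    def test_sex_codings_canonicalized(self):
        assert canonical_sex(0) == "male"
        assert canonical_sex(1) == "female"
        assert canonical_sex("M") == "male"
        assert canonical_sex("Female") == "female"
        with pytest.raises(ValidationError):
            canonical_sex("x")


def _minimal_frame(**overrides):
    base = pd.DataFrame(
        {
            "ID": [1, 1],
            "TIME": [0.0, 2.0],
            "EVID": [1, 0],
            "AMT": [1000.0, np.nan],
            "RATE": [2000.0, np.nan],
            "DV": [np.nan, 25.0],
            "MDV": [1, 0],
            "AGE": [54.0, 54.0],
            "WT": [75.0, 75.0],
            "SEX": ["male", "male"],
            "SCR": [0.935, 0.935],
        }
    )
    for col, vals in overrides.items():
        base[col] = vals
    return base


class TestValidation:
    def test_minimal_dataset_counts(self):
        ds = StudyDataset(_minimal_frame())
        assert ds.subject_count == 1
        assert ds.observation_count == 1

    def test_crcl_derived_when_absent(self):
        ds = StudyDataset(_minimal_frame())
        expected = cockcroft_gault(54, 75, 0.935, "male")
        assert ds.frame["CRCL"].iloc[0] == pytest.approx(expected)

    def test_crcl_authoritative_when_present(self):
        ds = StudyDataset(_minimal_frame(CRCL=[88.0, 88.0]))
        assert ds.frame["CRCL"].iloc[0] == 88.0

    def test_negative_time_rejected_with_row_diagnostics(self):
        with pytest.raises(ValidationError, match="time"):
            StudyDataset(_minimal_frame(TIME=[-1.0, 2.0]))

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValidationError, match="amt"):
            StudyDataset(_minimal_frame(AMT=[0.0, np.nan]))

    def test_subject_without_observation_rejected(self):
        with pytest.raises(ValidationError, match="no observation"):
            StudyDataset(_minimal_frame(EVID=[1, 1], AMT=[1000.0, 1000.0],
                                        RATE=[2000.0, 2000.0], MDV=[1, 1]))

    def test_time_ordering_enforced_within_subject(self):
        with pytest.raises(ValidationError, match="non-decreasing"):
            StudyDataset(_minimal_frame(TIME=[2.0, 0.0]))

    def test_varying_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            StudyDataset(_minimal_frame(WT=[75.0, 80.0]))

    def test_empty_frame_rejected(self):
        with pytest.raises(SchemaError):
            StudyDataset(pd.DataFrame())


class TestReadWrite:
    def test_empty_file_raises_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_dataset(path)

    def test_missing_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME\n1,0\n")
        with pytest.raises(SchemaError, match="missing"):
            read_dataset(path)

    def test_dialect_renames_columns(self, tmp_path):
        frame = _minimal_frame().rename(columns={"ID": "SUBJ"})
        path = tmp_path / "dialect.csv"
        frame.to_csv(path, index=False)
        ds = read_dataset(path, dialect={"SUBJ": "ID"})
        assert ds.subject_count == 1

    def test_round_trip_study_dataset(self, tmp_path, study_ds):
        path = tmp_path / "cohort.csv"
        write_dataset(study_ds, path)
        back = read_dataset(path)
        assert back.subject_count == study_ds.subject_count == 58
        assert back.observation_count == study_ds.observation_count == 176
        for col in ("TIME", "DV", "AMT", "RATE", "AGE", "WT", "SCR", "CRCL"):
            a = study_ds.frame[col].to_numpy(dtype=float)
            b = back.frame[col].to_numpy(dtype=float)
            np.testing.assert_array_equal(np.nan_to_num(a, nan=-1), np.nan_to_num(b, nan=-1))

    def test_missing_values_as_dot_accepted(self, tmp_path):
        text = (
            "ID,TIME,EVID,AMT,RATE,DV,MDV,AGE,WT,SEX,SCR\n"
            "1,0,1,1000,2000,.,1,54,75,M,0.935\n"
            "1,2,0,.,.,25.0,0,54,75,M,0.935\n"
        )
        path = tmp_path / "dots.csv"
        path.write_text(text)
        ds = read_dataset(path)
        assert ds.observation_count == 1

    def test_subject_arrays_prepared(self, study_ds):
        subj = study_ds.subjects()[0]
        assert subj.n_obs >= 1
        assert np.all(subj.dose_amounts > 0)
        assert np.all(subj.dose_durations == 0.5)
        assert set(subj.covariates) == {"AGE", "WT", "SEX", "SCR", "CRCL"}
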