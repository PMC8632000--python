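"""NONMEM-style rectangular event datasets: reading, validation, writing.

One row per event per subject.  Dose rows (EVID 1) carry AMT (mg) and RATE
(mg/h); observation rows (EVID 0) carry DV (mg/l) and MDV 0.  Covariates
(AGE years, WT kg, SEX, SCR mg/dl, CRCL ml/min) are constant within subject.
If CRCL is absent it is derived from the other covariates with the
Cockcroft-Gault equation; if present it is taken as authoritative.

Units are fixed (mg, L, h, mg/l, ml/min); no unit inference is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "EventRecord",
    "SubjectData",
    "StudyDataset",
    "cockcroft_gault",
    "read_dataset",
    "write_dataset",
    "canonical_sex",
]

CANONICAL_COLUMNS = (
    "ID",
    "TIME",
    "EVID",
    "AMT",
    "RATE",
    "DV",
    "MDV",
    "AGE",
    "WT",
    "SEX",
    "SCR",
    "CRCL",
)
REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV", "AGE", "WT", "SEX", "SCR")
COVARIATE_COLUMNS = ("AGE", "WT", "SEX", "SCR", "CRCL")


class SchemaError(ValueError):
    """Structural problem with the input file (missing columns, empty file)."""


class ValidationError(ValueError):
    """Rows violating dataset invariants; message lists the offending rows."""


def canonical_sex(value) -> str:
    """Canonicalize sex coding to 'male'/'female' (accepts 0/1, M/F, male/female).

    Numeric coding follows the convention 1 = female.
    """
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("m", "male", "0"):
            return "male"
        if v in ("f", "female", "1"):
            return "female"
        raise ValidationError(f"unrecognized sex code {value!r}")
    f = float(value)
    if f == 0.0:
        return "male"
    if f == 1.0:
        return "female"
    raise ValidationError(f"unrecognized sex code {value!r}")


def cockcroft_gault(age, wt, scr, sex):
    """Creatinine clearance (ml/min) by the Cockcroft-Gault equation.

    CRCL = (140 - age) * wt / (72 * scr), times 0.85 for females.
    Accepts scalars or arrays; ``sex`` as any accepted coding.
    """
    age = np.asarray(age, dtype=float)
    wt = np.asarray(wt, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("scr must be positive")
    if np.any(age <= 0) or np.any(wt <= 0):
        raise ValueError("age and wt must be positive")
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    female = np.array([canonical_sex(s) == "female" for s in sex_arr.ravel()]).reshape(
        sex_arr.shape
    )
    crcl = (140.0 - age) * wt / (72.0 * scr)
    crcl = np.where(female, 0.85 * crcl, crcl)
    return float(crcl.ravel()[0]) if crcl.size == 1 else crcl


@dataclass(frozen=True)
class EventRecord:
    """One dose or observation event (convenience view of a dataset row)."""

    subject_id: int
    time: float
    evid: int
    amt: float | None
    rate: float | None
    dv: float | None
    mdv: int
    age: float
    wt: float
    sex: str
    scr: float
    crcl: float


@dataclass(frozen=True)
class SubjectData:
    """All events of one subject, prepared as arrays for fast evaluation."""

    subject_id: int
    obs_times: np.ndarray  # (n_obs,) h since first dose
    dv: np.ndarray  # (n_obs,) mg/l
    dose_times: np.ndarray  # (n_dose,)
    dose_amounts: np.ndarray  # mg
    dose_durations: np.ndarray  # h
    covariates: dict

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)


class StudyDataset:
    """Validated event dataset; the lingua franca of every pipeline stage."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame)
        self._subjects: list[SubjectData] | None = None

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def subject_ids(self) -> np.ndarray:
        return self._frame["ID"].unique()

    @property
    def subject_count(self) -> int:
        return len(self.subject_ids)

    @property
    def observation_count(self) -> int:
        return int((self._frame["EVID"] == 0).sum())

    def subjects(self) -> list[SubjectData]:
        if self._subjects is None:
            self._subjects = [
                _subject_from_block(sid, block)
                for sid, block in self._frame.groupby("ID", sort=False)
            ]
        return self._subjects

    def records(self) -> list[EventRecord]:
        out = []
        for row in self._frame.itertuples(index=False):
            out.append(
                EventRecord(
                    subject_id=int(row.ID),
                    time=float(row.TIME),
                    evid=int(row.EVID),
                    amt=None if row.EVID == 0 else float(row.AMT),
                    rate=None if row.EVID == 0 else float(row.RATE),
                    dv=None if row.EVID == 1 else float(row.DV),
                    mdv=int(row.MDV),
                    age=float(row.AGE),
                    wt=float(row.WT),
                    sex=str(row.SEX),
                    scr=float(row.SCR),
                    crcl=float(row.CRCL),
                )
            )
        return out

    def subset(self, subject_ids: Sequence[int], relabel: bool = True) -> "StudyDataset":
        """Dataset restricted to (possibly repeated) subjects, e.g. a bootstrap
        resample.  With ``relabel`` each occurrence gets a fresh sequential ID."""
        blocks = []
        by_id = {sid: block for sid, block in self._frame.groupby("ID", sort=False)}
        for new_id, sid in enumerate(subject_ids, start=1):
            block = by_id[sid].copy()
            if relabel:
                block["ID"] = new_id
            blocks.append(block)
        return StudyDataset(pd.concat(blocks, ignore_index=True))


def _subject_from_block(sid, block: pd.DataFrame) -> SubjectData:
    doses = block[block["EVID"] == 1]
    obs = block[block["EVID"] == 0]
    amounts = doses["AMT"].to_numpy(dtype=float)
    rates = doses["RATE"].to_numpy(dtype=float)
    first = block.iloc[0]
    return SubjectData(
        subject_id=int(sid),
        obs_times=obs["TIME"].to_numpy(dtype=float),
        dv=obs["DV"].to_numpy(dtype=float),
        dose_times=doses["TIME"].to_numpy(dtype=float),
        dose_amounts=amounts,
        dose_durations=amounts / rates,
        covariates={
            "AGE": float(first["AGE"]),
            "WT": float(first["WT"]),
            "SEX": str(first["SEX"]),
            "SCR": float(first["SCR"]),
            "CRCL": float(first["CRCL"]),
        },
    )


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    if frame is None or len(frame) == 0:
        raise SchemaError("dataset is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = frame.copy()
    for col in ("TIME", "AMT", "RATE", "DV", "AGE", "WT", "SCR"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ID"] = pd.to_numeric(df["ID"], errors="coerce").astype("Int64")
    df["EVID"] = pd.to_numeric(df["EVID"], errors="coerce").astype("Int64")
    df["MDV"] = pd.to_numeric(df["MDV"], errors="coerce").fillna(0).astype("Int64")
    df["SEX"] = [canonical_sex(s) for s in df["SEX"]]

    bad: list[str] = []

    def flag(mask, why):
        for idx in df.index[np.asarray(mask, dtype=bool)]:
            bad.append(f"row {idx}: {why}")

    flag(df["ID"].isna() | (df["ID"] <= 0), "subject_id must be a positive integer")
    flag(df["TIME"].isna() | (df["TIME"] < 0), "time must be >= 0")
    flag(~df["EVID"].isin([0, 1]), "evid must be 0 (observation) or 1 (dose)")
    is_dose = df["EVID"] == 1
    is_obs = df["EVID"] == 0
    flag(is_dose & (df["AMT"].isna() | (df["AMT"] <= 0)), "dose rows need amt > 0")
    flag(is_dose & (df["RATE"].isna() | (df["RATE"] <= 0)), "dose rows need rate > 0")
    flag(is_obs & (df["DV"].isna() | (df["DV"] < 0)), "observation rows need dv >= 0")
    flag(is_obs & (df["MDV"] != 0), "observation rows must have mdv = 0")
    for col in ("AGE", "WT", "SCR"):
        flag(df[col].isna() | (df[col] <= 0), f"{col.lower()} must be positive")
    if bad:
        raise ValidationError("invalid rows:\n" + "\n".join(bad))

    # CRCL: authoritative when present; derived via Cockcroft-Gault otherwise
    if "CRCL" not in df.columns or df["CRCL"].isna().all():
        df["CRCL"] = cockcroft_gault(df["AGE"], df["WT"], df["SCR"], df["SEX"].to_numpy())
    else:
        df["CRCL"] = pd.to_numeric(df["CRCL"], errors="coerce")
        na = df["CRCL"].isna()
        if na.any():
            df.loc[na, "CRCL"] = cockcroft_gault(
                df.loc[na, "AGE"], df.loc[na, "WT"], df.loc[na, "SCR"], df.loc[na, "SEX"].to_numpy()
            )

    for sid, block in df.groupby("ID", sort=False):
        t = block["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            bad.append(f"subject {sid}: times not non-decreasing")
        for col in COVARIATE_COLUMNS:
            if block[col].nunique() > 1:
                bad.append(f"subject {sid}: covariate {col} not constant")
        if not (block["EVID"] == 1).any():
            bad.append(f"subject {sid}: no dose record")
        if not (block["EVID"] == 0).any():
            bad.append(f"subject {sid}: no observation record")
    if bad:
        raise ValidationError("invalid dataset:\n" + "\n".join(bad))

    keep = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in keep]
    return df[keep + extra].reset_index(drop=True)


def read_dataset(path, dialect: Mapping[str, str] | None = None) -> StudyDataset:
    """Read a CSV event dataset.

    ``dialect`` maps file column names to canonical names (ID, TIME, DV, AMT,
    RATE, EVID, MDV, AGE, WT, SEX, SCR, CRCL).  Missing values may be empty
    cells or '.'.
    """
    try:
        frame = pd.read_csv(
            path, na_values=["."], skip_blank_lines=True, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    frame = frame.rename(columns={c: c.upper() for c in frame.columns})
    return StudyDataset(frame)


def write_dataset(ds: StudyDataset, path) -> None:
    """Write a dataset as CSV; ``read_dataset(write_dataset(ds))`` round-trips
    numeric fields bit-exactly (floats are written with full repr precision)."""
    if ds.subject_count == 0:
        raise ValidationError("refusing to write a dataset with no subjects")
    # %.17g guarantees bit-exact float round-trips
    ds.frame.to_csv(path, index=False, float_format="%.17g")
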