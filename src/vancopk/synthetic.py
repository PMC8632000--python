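"""Study-like synthetic cohorts with known ground truth.

The generator emulates the design of the source study: 58 adult surgical
patients, 176 vancomycin concentrations sampled after the first dose (1-7
samples per subject, ~3 on average), doses of 500-1,000 mg infused over
0.5 h, and covariates matching the published demographics (age median 54,
range 25-86 y; weight 75, 53-129 kg; serum creatinine 0.935, 0.4-4.7 mg/dl;
39 male / 19 female).  Creatinine clearance is always derived with
Cockcroft-Gault from the sampled covariates, never drawn independently.

Continuous covariates are drawn from truncated normals on the log scale,
centered at the published medians with hard truncation at the published
ranges; the log-scale SDs (documented constants below) were chosen once so
the generated medians approximate the published ones.  Sampling times come
from a plausible first-dose TDM grid (0.5, 1, 2, 4, 6, 8, 12 h), drawn
without replacement per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import StudyDataset, cockcroft_gault
from .model import PopulationModel, final_model

__all__ = ["CohortSpec", "sample_cohort", "simulate_observations", "make_study_dataset", "LLOQ"]

LLOQ = 0.25  # assay lower limit of quantification, mg/l

# log-scale SDs of the truncated covariate distributions (chosen once to
# reproduce the published medians within their ranges)
_AGE_LOG_SD = 0.25
_WT_LOG_SD = 0.16
_SCR_LOG_SD = 0.35


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort; defaults reproduce the study design."""

    n_subjects: int = 58
    total_samples: int | None = 176  # exact total; None = unconstrained
    samples_min: int = 1
    samples_max: int = 7
    # per-subject sample-count probabilities for 1..7 samples (mean ~= 3)
    samples_probs: tuple[float, ...] = (0.14, 0.26, 0.25, 0.15, 0.10, 0.06, 0.04)
    age_median: float = 54.0
    age_range: tuple[float, float] = (25.0, 86.0)
    wt_median: float = 75.0
    wt_range: tuple[float, float] = (53.0, 129.0)
    scr_median: float = 0.935
    scr_range: tuple[float, float] = (0.4, 4.7)
    female_fraction: float = 19.0 / 58.0
    # dose policy: 1,000 mg with probability 0.7, else 500 or 750 mg
    dose_choices: tuple[float, ...] = (1000.0, 500.0, 750.0)
    dose_probs: tuple[float, ...] = (0.7, 0.15, 0.15)
    infusion_duration: float = 0.5
    sampling_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.samples_probs) - 1.0) > 1e-9:
            raise ValueError("samples_probs must sum to 1")
        if abs(sum(self.dose_probs) - 1.0) > 1e-9:
            raise ValueError("dose_probs must sum to 1")
        for lo, hi in (self.age_range, self.wt_range, self.scr_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must be positive and increasing")
        if self.total_samples is not None:
            cap = min(self.samples_max, len(self.sampling_grid))
            if not (self.n_subjects * self.samples_min
                    <= self.total_samples
                    <= self.n_subjects * cap):
                raise ValueError(
                    f"total_samples={self.total_samples} unreachable for "
                    f"{self.n_subjects} subjects with {self.samples_min}-{cap} samples each"
                )


def _truncated_lognormal(rng, median, lo, hi, log_sd, size):
    """Normal on the log scale centered at log(median), hard-truncated to
    [lo, hi] by resampling."""
    mu = np.log(median)
    out = np.empty(size)
    pending = np.ones(size, dtype=bool)
    while pending.any():
        draw = np.exp(mu + log_sd * rng.standard_normal(pending.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(pending)[ok]
        out[idx] = draw[ok]
        pending[idx] = False
    return out


@dataclass
class SubjectDesign:
    """Covariates plus dose/observation schedule of one synthetic subject."""

    subject_id: int
    age: float
    wt: float
    sex: str
    scr: float
    crcl: float
    dose: float
    infusion_duration: float
    sample_times: np.ndarray


def sample_cohort(spec: CohortSpec = CohortSpec(), seed=0) -> list[SubjectDesign]:
    """Draw a cohort of subject designs (no concentrations yet)."""
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    age = _truncated_lognormal(rng, spec.age_median, *spec.age_range, _AGE_LOG_SD, n)
    wt = _truncated_lognormal(rng, spec.wt_median, *spec.wt_range, _WT_LOG_SD, n)
    scr = _truncated_lognormal(rng, spec.scr_median, *spec.scr_range, _SCR_LOG_SD, n)
    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")
    doses = rng.choice(spec.dose_choices, size=n, p=spec.dose_probs)
    support = np.arange(spec.samples_min, spec.samples_max + 1)
    probs = np.asarray(spec.samples_probs[: len(support)], dtype=float)
    probs = probs / probs.sum()
    counts = rng.choice(support, size=n, p=probs)
    counts = np.minimum(counts, len(spec.sampling_grid))
    if spec.total_samples is not None:
        counts = _adjust_counts(
            rng, counts, spec.total_samples, spec.samples_min,
            min(spec.samples_max, len(spec.sampling_grid)),
        )
    crcl = cockcroft_gault(age, wt, scr, sex)
    cohort = []
    for i in range(n):
        times = np.sort(rng.choice(spec.sampling_grid, size=counts[i], replace=False))
        cohort.append(
            SubjectDesign(
                subject_id=i + 1,
                age=float(age[i]),
                wt=float(wt[i]),
                sex=str(sex[i]),
                scr=float(scr[i]),
                crcl=float(np.atleast_1d(crcl)[i]),
                dose=float(doses[i]),
                infusion_duration=spec.infusion_duration,
                sample_times=times,
            )
        )
    return cohort


def _adjust_counts(rng, counts, target, lo, hi):
    """Nudge per-subject sample counts (within [lo, hi]) to an exact total."""
    counts = counts.copy()
    for _ in range(100000):
        diff = int(counts.sum()) - int(target)
        if diff == 0:
            break
        if diff > 0:
            candidates = np.flatnonzero(counts > lo)
            counts[rng.choice(candidates)] -= 1
        else:
            candidates = np.flatnonzero(counts < hi)
            counts[rng.choice(candidates)] += 1
    return counts


def simulate_observations(
    cohort: list[SubjectDesign],
    model: PopulationModel,
    seed=0,
) -> tuple[StudyDataset, dict]:
    """Forward-simulate concentrations for a cohort under a population model.

    Draws one eta pair per subject, computes individual CL/V, evaluates the
    closed-form one-compartment solution at the scheduled times and adds
    residual error per the model's error structure.  Concentrations are
    floored at 0; values below the assay LLOQ (0.25 mg/l) are retained and
    flagged in the BLQ column.  Returns the fit-ready dataset plus a
    ground-truth sidecar (parameters and per-subject etas).
    """
    rng = np.random.default_rng(seed)
    etas = model.draw_etas(len(cohort), rng)
    rows = []
    truth_subjects = []
    for i, subj in enumerate(cohort):
        cov = {
            "AGE": subj.age,
            "WT": subj.wt,
            "SEX": subj.sex,
            "SCR": subj.scr,
            "CRCL": subj.crcl,
        }
        params = model.individual(cov, etas[i])
        k = params.k
        t = subj.sample_times
        rate = subj.dose / subj.infusion_duration
        infused = np.clip(t, 0.0, subj.infusion_duration)
        tpost = np.maximum(t - subj.infusion_duration, 0.0)
        f = (rate / params.cl) * (1.0 - np.exp(-k * infused)) * np.exp(-k * tpost)
        var = model.sigma.variance(f)
        dv = np.maximum(f + rng.standard_normal(len(t)) * np.sqrt(var), 0.0)
        base = {
            "ID": subj.subject_id,
            "AGE": subj.age,
            "WT": subj.wt,
            "SEX": subj.sex,
            "SCR": subj.scr,
            "CRCL": subj.crcl,
        }
        rows.append(
            {
                **base,
                "TIME": 0.0,
                "EVID": 1,
                "AMT": subj.dose,
                "RATE": rate,
                "DV": np.nan,
                "MDV": 1,
                "BLQ": 0,
            }
        )
        for tj, dvj in zip(t, dv):
            rows.append(
                {
                    **base,
                    "TIME": float(tj),
                    "EVID": 0,
                    "AMT": np.nan,
                    "RATE": np.nan,
                    "DV": float(dvj),
                    "MDV": 0,
                    "BLQ": int(dvj < LLOQ),
                }
            )
        truth_subjects.append(
            {
                "id": subj.subject_id,
                "eta1": float(etas[i, 0]),
                "eta2": float(etas[i, 1]),
                "cl": params.cl,
                "v": params.v,
            }
        )
    frame = pd.DataFrame(rows)
    truth = {
        "theta": {
            "tvcl": model.theta.tvcl,
            "tvv": model.theta.tvv,
            "beta": {f"{p}_{c}": b for (p, c), b in model.theta.beta.items()},
        },
        "omega2": {"cl": model.omega.omega2_cl, "v": model.omega.omega2_v},
        "sigma": {
            "kind": model.sigma.kind,
            "sigma_add": model.sigma.sigma_add,
            "sigma_prop": model.sigma.sigma_prop,
        },
        "subjects": truth_subjects,
    }
    return StudyDataset(frame), truth


def make_study_dataset(
    seed=0,
    spec: CohortSpec = CohortSpec(),
    model: PopulationModel | None = None,
) -> tuple[StudyDataset, dict]:
    """Convenience: sample a cohort and simulate observations in one call.

    Defaults to the study design and the published final model; the two
    stages use independent streams derived from ``seed``.
    """
    if model is None:
        model = final_model()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_obs = ss.spawn(2)
    cohort = sample_cohort(spec, s_cohort)
    return simulate_observations(cohort, model, s_obs)
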