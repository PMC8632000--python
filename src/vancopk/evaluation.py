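"""Model evaluation: nonparametric bootstrap, visual predictive check, GOF.

Bootstrap: replicates resample subjects with replacement to the original
subject count and refit the model; summaries are the per-parameter median,
2.5th/97.5th percentile CI and bias% = 100*(final - bootstrap median)/final
on unrounded medians (positive when the original estimate exceeds the
bootstrap median).  Non-converged replicates are dropped and counted.

VPC: a plain (non-prediction-corrected) visual predictive check; the model
is simulated at the original design (same subjects, doses, times and
covariates, fresh eta and residual draws) n_sim times, and the observed
5th/50th/95th percentiles per time bin are compared against the 90%
prediction interval (5th-95th percentile over simulations) of the same
percentiles.  Bins are quantile-based in time so each holds roughly equal
numbers of observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .datasets import StudyDataset
from .estimation import FitResult, compute_cwres, fit_model
from .model import PopulationModel

__all__ = ["BootstrapResult", "VpcResult", "bootstrap_run", "vpc_run", "gof_tables"]

_PERCENTILES = (5.0, 50.0, 95.0)


@dataclass
class BootstrapResult:
    n_replicates: int
    n_converged: int
    table: pd.DataFrame  # parameter, final, median, ci_low, ci_high, bias_percent
    warning: str | None = None

    def __post_init__(self) -> None:
        bad = self.table[
            (self.table["ci_low"] > self.table["median"])
            | (self.table["median"] > self.table["ci_high"])
        ]
        if len(bad):
            raise ValueError("bootstrap summary violates ci_low <= median <= ci_high")


def bootstrap_run(
    spec,
    ds: StudyDataset,
    n: int = 1000,
    seed=0,
    fitter: Callable[..., FitResult] | None = None,
    original_fit: FitResult | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the model fit (resampling unit: subject).

    Replicate fits are warm-started at the original estimates.  Deterministic
    for a fixed seed.  A >20% replicate failure rate sets a warning on the
    result rather than failing.
    """
    if fitter is None:
        def fitter(s, data, init=None):
            return fit_model(s, data, init=init, estimate_rse=False, diagnostics=False)

    if original_fit is None:
        original_fit = fitter(spec, ds, init=None)
    if not original_fit.converged:
        raise RuntimeError("original fit did not converge; bootstrap aborted")
    rng = np.random.default_rng(seed)
    ids = np.asarray(ds.subject_ids)
    estimates: list[dict] = []
    n_failed = 0
    for _ in range(n):
        resampled = rng.choice(ids, size=len(ids), replace=True)
        rep_ds = ds.subset(resampled, relabel=True)
        try:
            rep_fit = fitter(spec, rep_ds, init=dict(original_fit.estimates))
        except Exception:
            rep_fit = None
        if rep_fit is None or not rep_fit.converged:
            n_failed += 1
            continue
        estimates.append(rep_fit.estimates)
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    frame = pd.DataFrame(estimates)
    rows = []
    for name in original_fit.estimates:
        final = original_fit.estimates[name]
        col = frame[name].to_numpy(dtype=float)
        med = float(np.median(col))
        rows.append(
            {
                "parameter": name,
                "final": final,
                "median": med,
                "ci_low": float(np.percentile(col, 2.5)),
                "ci_high": float(np.percentile(col, 97.5)),
                "bias_percent": 100.0 * (final - med) / final if final != 0 else np.nan,
            }
        )
    warning = None
    if n_failed > 0.2 * n:
        warning = f"{n_failed}/{n} bootstrap replicates failed to converge"
    return BootstrapResult(
        n_replicates=n, n_converged=n - n_failed, table=pd.DataFrame(rows), warning=warning
    )


@dataclass
class VpcResult:
    n_simulations: int
    bins: pd.DataFrame
    """Per-bin: t_lo, t_hi, t_mid, n_obs, obs_p5/p50/p95, and for each
    observed percentile the 90% prediction interval sim_pXX_lo / sim_pXX_hi
    plus the simulated median sim_pXX_mid."""

    def __post_init__(self) -> None:
        for p in (5, 50, 95):
            if np.any(self.bins[f"sim_p{p}_lo"] > self.bins[f"sim_p{p}_hi"]):
                raise ValueError("prediction interval lower bound exceeds upper bound")


def _simulate_at_design(model: PopulationModel, ds: StudyDataset, rng) -> np.ndarray:
    """One simulated replicate of the dataset's observations (flat array in
    dataset observation order)."""
    out = []
    subjects = ds.subjects()
    etas = model.draw_etas(len(subjects), rng)
    for i, s in enumerate(subjects):
        params = model.individual(s.covariates, etas[i])
        k = params.k
        t = s.obs_times[:, None] - s.dose_times[None, :]
        infused = np.clip(t, 0.0, s.dose_durations[None, :])
        tpost = np.maximum(t - s.dose_durations[None, :], 0.0)
        rate = (s.dose_amounts / s.dose_durations)[None, :]
        f = ((rate / params.cl) * (1.0 - np.exp(-k * infused)) * np.exp(-k * tpost)).sum(axis=1)
        var = model.sigma.variance(f)
        out.append(np.maximum(f + rng.standard_normal(len(f)) * np.sqrt(var), 0.0))
    return np.concatenate(out)


def vpc_run(
    fit: FitResult | PopulationModel,
    ds: StudyDataset,
    n_sim: int = 500,
    seed=0,
    n_bins: int = 6,
) -> VpcResult:
    """Visual predictive check of a fitted model at the original design."""
    model = fit.model if isinstance(fit, FitResult) else fit
    obs_frame = ds.frame[ds.frame["EVID"] == 0]
    times = obs_frame["TIME"].to_numpy(dtype=float)
    dv = obs_frame["DV"].to_numpy(dtype=float)
    edges = np.unique(np.quantile(times, np.linspace(0, 1, n_bins + 1)))
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)

    rng = np.random.default_rng(seed)
    sim_percentiles = np.empty((n_sim, len(edges) - 1, len(_PERCENTILES)))
    for r in range(n_sim):
        sim_dv = _simulate_at_design(model, ds, rng)
        for b in range(len(edges) - 1):
            sel = sim_dv[bin_idx == b]
            sim_percentiles[r, b, :] = np.percentile(sel, _PERCENTILES)

    rows = []
    for b in range(len(edges) - 1):
        sel = dv[bin_idx == b]
        row = {
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "t_mid": float(np.median(times[bin_idx == b])),
            "n_obs": int(np.sum(bin_idx == b)),
        }
        for j, p in enumerate((5, 50, 95)):
            row[f"obs_p{p}"] = float(np.percentile(sel, _PERCENTILES[j]))
            row[f"sim_p{p}_lo"] = float(np.percentile(sim_percentiles[:, b, j], 5.0))
            row[f"sim_p{p}_mid"] = float(np.percentile(sim_percentiles[:, b, j], 50.0))
            row[f"sim_p{p}_hi"] = float(np.percentile(sim_percentiles[:, b, j], 95.0))
        rows.append(row)
    return VpcResult(n_simulations=n_sim, bins=pd.DataFrame(rows))


def gof_tables(fit: FitResult, ds: StudyDataset) -> pd.DataFrame:
    """Goodness-of-fit table: one row per observation with DV, PRED, IPRED,
    CWRES and time after dose (time since the most recent dose start)."""
    table = compute_cwres(fit, ds)
    tad = []
    for s in ds.subjects():
        for t in s.obs_times:
            prior = s.dose_times[s.dose_times <= t]
            tad.append(float(t - prior.max()) if len(prior) else np.nan)
    table["TAD"] = tad
    return table[["ID", "TIME", "TAD", "DV", "PRED", "IPRED", "CWRES"]]
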