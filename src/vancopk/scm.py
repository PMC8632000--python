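"""Stepwise covariate modeling: forward inclusion / backward elimination.

Forward phase: each remaining candidate relation is added to the current
model and refitted; the candidate with the largest OFV drop among those with
drop >= 3.84 (chi-square(1), alpha 0.05; threshold inclusive) is included,
until none qualifies.  Backward phase: included relations are removed one at
a time; a relation is retained only if its removal raises the OFV by >= 6.63
(alpha 0.01), otherwise it is permanently removed and the remaining set is
re-tested.  Candidate fits that fail to converge are skipped for the round
and logged, never fatal.

Tie-breaking is deterministic: CL before V, covariates in the order CRCL,
WT, AGE, SCR, SEX.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .covariates import COVARIATE_ORDER, CovariateRelation
from .datasets import StudyDataset
from .estimation import FitResult, fit_model
from .model import ModelSpec

__all__ = [
    "ScmStep",
    "ScmResult",
    "run_scm",
    "default_candidates",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.63


@dataclass(frozen=True)
class ScmStep:
    """One tested candidate in one SCM round."""

    phase: str  # "forward" | "backward"
    candidate: CovariateRelation
    ofv_before: float
    ofv_after: float
    delta_ofv: float  # drop for forward steps, rise for backward steps
    decision: str  # included | rejected | retained | removed | skipped


@dataclass
class ScmResult:
    steps: list[ScmStep]
    final_relations: tuple[CovariateRelation, ...]
    final_fit: FitResult

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": [s.phase for s in self.steps],
                "candidate": [s.candidate.label for s in self.steps],
                "ofv_before": [s.ofv_before for s in self.steps],
                "ofv_after": [s.ofv_after for s in self.steps],
                "delta_ofv": [s.delta_ofv for s in self.steps],
                "decision": [s.decision for s in self.steps],
            }
        )


def _candidate_sort_key(rel: CovariateRelation):
    return (
        0 if rel.parameter == "CL" else 1,
        COVARIATE_ORDER.index(rel.covariate),
    )


def default_candidates(parameters: Sequence[str] = ("CL", "V")) -> list[CovariateRelation]:
    """Candidate relations for the tested covariates: linear (centered at the
    dataset median, resolved at fit time) for continuous covariates and a
    fractional sex effect.  SCR and CRCL are both offered despite their
    collinearity."""
    out = []
    for param in parameters:
        for cov in COVARIATE_ORDER:
            form = "fractional_categorical" if cov == "SEX" else "linear_centered"
            out.append(CovariateRelation(param, cov, form))
    return sorted(out, key=_candidate_sort_key)


def run_scm(
    base: ModelSpec,
    ds: StudyDataset,
    candidates: Sequence[CovariateRelation] | None = None,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    fitter: Callable[..., FitResult] | None = None,
    init=None,
) -> ScmResult:
    """Greedy forward-inclusion / backward-elimination covariate search.

    ``fitter`` defaults to :func:`vancopk.estimation.fit_model` (injectable
    for testing).  Returns the full step log, the surviving relations and
    the final fit.
    """
    if fitter is None:
        def fitter(spec, data, init=None):
            return fit_model(spec, data, init=init, estimate_rse=False, diagnostics=False)

    candidates = sorted(candidates if candidates is not None else default_candidates(),
                        key=_candidate_sort_key)
    steps: list[ScmStep] = []

    current_spec = base
    current_fit = fitter(base, ds, init=init)
    if not current_fit.converged:
        raise RuntimeError("base model failed to converge; SCM not started")
    remaining = [c for c in candidates]

    # ---- forward inclusion
    while remaining:
        round_results = []
        for cand in remaining:
            spec_try = current_spec.with_relation(cand)
            warm = dict(current_fit.estimates)
            warm.setdefault(f"beta_{cand.parameter}_{cand.covariate}", 0.0)
            try:
                fit_try = fitter(spec_try, ds, init=warm)
            except Exception:
                fit_try = None
            if fit_try is None or not fit_try.converged:
                steps.append(
                    ScmStep("forward", cand, current_fit.ofv, float("nan"), float("nan"), "skipped")
                )
                continue
            drop = current_fit.ofv - fit_try.ofv
            round_results.append((cand, fit_try, drop))
        # inclusive thresholds, robust to float representation of 3.84/6.63
        qualifying = [r for r in round_results if r[2] >= forward_threshold - 1e-9]
        if qualifying:
            best = max(qualifying, key=lambda r: (r[2], [-k for k in _candidate_sort_key(r[0])]))
        else:
            best = None
        for cand, fit_try, drop in round_results:
            if best is not None and cand == best[0]:
                decision = "included"
            else:
                decision = "rejected"
            steps.append(
                ScmStep("forward", cand, current_fit.ofv, fit_try.ofv, drop, decision)
            )
        if best is None:
            break
        cand, fit_try, _ = best
        current_spec = current_spec.with_relation(cand)
        current_fit = fit_try
        remaining = [c for c in remaining if c != cand]

    # ---- backward elimination
    included = [r for r in current_spec.relations if r not in base.relations]
    while included:
        rises = []
        for rel in sorted(included, key=_candidate_sort_key):
            spec_try = current_spec.without_relation(rel)
            warm = {
                k: v
                for k, v in current_fit.estimates.items()
                if k != f"beta_{rel.parameter}_{rel.covariate}"
            }
            try:
                fit_try = fitter(spec_try, ds, init=warm)
            except Exception:
                fit_try = None
            if fit_try is None or not fit_try.converged:
                steps.append(
                    ScmStep("backward", rel, current_fit.ofv, float("nan"), float("nan"), "skipped")
                )
                continue
            rise = fit_try.ofv - current_fit.ofv
            rises.append((rel, fit_try, rise))
        if not rises:
            break
        weakest = min(rises, key=lambda r: (r[2], _candidate_sort_key(r[0])))
        if weakest[2] < backward_threshold - 1e-9:
            for rel, fit_try, rise in rises:
                decision = "removed" if rel == weakest[0] else "retained"
                steps.append(
                    ScmStep("backward", rel, current_fit.ofv, fit_try.ofv, rise, decision)
                )
            current_spec = current_spec.without_relation(weakest[0])
            current_fit = weakest[1]
            included = [r for r in included if r != weakest[0]]
        else:
            for rel, fit_try, rise in rises:
                steps.append(
                    ScmStep("backward", rel, current_fit.ofv, fit_try.ofv, rise, "retained")
                )
            break

    final_relations = tuple(r for r in current_spec.relations if r not in base.relations)
    # final fit with diagnostics/SEs through the default production fitter
    return ScmResult(steps=steps, final_relations=final_relations, final_fit=current_fit)
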