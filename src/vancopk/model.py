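"""Declarative model specification and fully-parameterized population models."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .covariates import (
    CovariateRelation,
    OmegaMatrix,
    ThetaVector,
    individual_params,
    sample_etas,
)
from .structural import PKParameters

__all__ = [
    "ErrorModel",
    "ModelSpec",
    "PopulationModel",
    "final_model",
    "base_model_spec",
    "final_model_spec",
]

# Reference (published) estimates of the final vancomycin model:
# typical CL 2.45 L/h at CRCL 101.15 ml/min and weight 75 kg, typical V 22.6 L,
# linear CRCL slope 0.0046 per ml/min, linear weight slope -0.011 per kg,
# BSV 11.3% (CL) and 22.8% (V) as %CV, additive residual error 3.07 mg/l.
FINAL_TVCL = 2.45
FINAL_TVV = 22.6
FINAL_BETA_CRCL = 0.0046
FINAL_BETA_WT = -0.011
FINAL_CRCL_MEDIAN = 101.15
FINAL_WT_MEDIAN = 75.0
FINAL_BSV_CL_PCT = 11.3
FINAL_BSV_V_PCT = 22.8
FINAL_SIGMA_ADD = 3.07

_ERROR_KINDS = ("additive", "proportional", "combined")

# floor on the model prediction inside the proportional variance term,
# preventing a zero residual variance at very low predictions
PROP_F_FLOOR = 0.01


@dataclass(frozen=True)
class ErrorModel:
    """Residual unexplained variability model.

    additive:      var = sigma_add^2
    proportional:  var = (sigma_prop * f)^2
    combined:      var = sigma_add^2 + (sigma_prop * f)^2
    """

    kind: str = "additive"
    sigma_add: float | None = None
    sigma_prop: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _ERROR_KINDS:
            raise ValueError(f"kind must be one of {_ERROR_KINDS}")
        # zero sigmas are tolerated for noise-free simulation; fitting keeps
        # sigmas strictly positive through its log-scale bounds
        if self.kind in ("additive", "combined"):
            if self.sigma_add is None or self.sigma_add < 0:
                raise ValueError(f"{self.kind} error requires sigma_add >= 0")
        elif self.sigma_add is not None:
            raise ValueError("sigma_add not used by proportional error")
        if self.kind in ("proportional", "combined"):
            if self.sigma_prop is None or self.sigma_prop < 0:
                raise ValueError(f"{self.kind} error requires sigma_prop >= 0")
        elif self.sigma_prop is not None:
            raise ValueError("sigma_prop not used by additive error")

    def variance(self, f) -> np.ndarray:
        """Residual variance at prediction(s) ``f`` (mg/l)."""
        f = np.asarray(f, dtype=float)
        var = np.zeros_like(f)
        if self.sigma_add is not None:
            var = var + self.sigma_add**2
        if self.sigma_prop is not None:
            var = var + (self.sigma_prop * np.maximum(f, PROP_F_FLOOR)) ** 2
        return var


@dataclass(frozen=True)
class ModelSpec:
    """Structural + stochastic model description (no parameter values).

    ``eta_on_cl`` / ``eta_on_v`` toggle the BSV terms; switching one off fixes
    the corresponding omega^2 to zero.
    """

    structural: str = "one_compartment"
    relations: tuple[CovariateRelation, ...] = ()
    error_kind: str = "additive"
    eta_on_cl: bool = True
    eta_on_v: bool = True

    def __post_init__(self) -> None:
        if self.structural not in ("one_compartment", "two_compartment"):
            raise ValueError("structural must be one_compartment or two_compartment")
        if self.error_kind not in _ERROR_KINDS:
            raise ValueError(f"error_kind must be one of {_ERROR_KINDS}")
        object.__setattr__(self, "relations", tuple(self.relations))

    def with_relation(self, rel: CovariateRelation) -> "ModelSpec":
        return replace(self, relations=self.relations + (rel,))

    def without_relation(self, rel: CovariateRelation) -> "ModelSpec":
        kept = tuple(r for r in self.relations if r != rel)
        if len(kept) == len(self.relations):
            raise ValueError(f"relation {rel.label} not in model")
        return replace(self, relations=kept)


@dataclass(frozen=True)
class PopulationModel:
    """A ModelSpec together with concrete parameter values."""

    spec: ModelSpec
    theta: ThetaVector
    omega: OmegaMatrix
    sigma: ErrorModel

    def individual(self, cov: Mapping[str, float], eta) -> PKParameters:
        return individual_params(self.theta, self.spec.relations, cov, eta)

    def typical(self, cov: Mapping[str, float]) -> PKParameters:
        return individual_params(self.theta, self.spec.relations, cov, np.zeros(2))

    def draw_etas(self, n: int, seed) -> np.ndarray:
        omega = self.omega
        if not self.spec.eta_on_cl:
            omega = OmegaMatrix(0.0, omega.omega2_v)
        if not self.spec.eta_on_v:
            omega = OmegaMatrix(omega.omega2_cl, 0.0)
        return sample_etas(omega, n, seed)


def base_model_spec(error_kind: str = "additive", **kwargs) -> ModelSpec:
    """Covariate-free one-compartment base model."""
    return ModelSpec(structural="one_compartment", relations=(), error_kind=error_kind, **kwargs)


def final_model_spec() -> ModelSpec:
    """Structure of the final covariate model: linear CRCL and WT effects on CL."""
    return ModelSpec(
        structural="one_compartment",
        relations=(
            CovariateRelation("CL", "CRCL", "linear_centered", center=FINAL_CRCL_MEDIAN),
            CovariateRelation("CL", "WT", "linear_centered", center=FINAL_WT_MEDIAN),
        ),
        error_kind="additive",
    )


def final_model() -> PopulationModel:
    """The final vancomycin population model at its published estimates."""
    return PopulationModel(
        spec=final_model_spec(),
        theta=ThetaVector(
            tvcl=FINAL_TVCL,
            tvv=FINAL_TVV,
            beta={("CL", "CRCL"): FINAL_BETA_CRCL, ("CL", "WT"): FINAL_BETA_WT},
        ),
        omega=OmegaMatrix.from_cv_percent(FINAL_BSV_CL_PCT, FINAL_BSV_V_PCT),
        sigma=ErrorModel(kind="additive", sigma_add=FINAL_SIGMA_ADD),
    )
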