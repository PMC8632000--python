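"""Covariate model: population fixed effects -> individual PK parameters.

Individual clearance and volume follow the standard multiplicative form

    CL_j = tvcl * prod(covariate factors on CL) * exp(eta1)
    V_j  = tvv  * prod(covariate factors on V)  * exp(eta2)

with between-subject variability (BSV) modeled as independent zero-mean normal
random effects on the log scale, reported as %CV = 100 * sqrt(omega^2).

Covariate factor forms:

* ``linear_centered``: 1 + beta * (x - center)  (the published vancomycin
  model uses this for CRCL and weight on CL, centered at the population
  medians 101.15 ml/min and 75 kg)
* ``power_allometric``: (x / center) ** exponent, exponent 0.75 on CL and
  1.0 on V by convention
* ``fractional_categorical``: 1 + beta * indicator (indicator = 1 for female)

Linear factors are floored at 0.01 (with a logged warning) because the linear
form is unbounded below under extrapolation — e.g. the weight factor on CL
crosses zero near 165.9 kg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .structural import PKParameters

__all__ = [
    "CovariateRelation",
    "ThetaVector",
    "OmegaMatrix",
    "individual_params",
    "typical_params",
    "sample_etas",
    "FACTOR_FLOOR",
]

logger = logging.getLogger(__name__)

FACTOR_FLOOR = 0.01

_PARAMETERS = ("CL", "V")
_COVARIATES = ("AGE", "SEX", "WT", "SCR", "CRCL")
_FORMS = ("linear_centered", "power_allometric", "fractional_categorical")

# deterministic ordering used for tie-breaking in covariate search
COVARIATE_ORDER = ("CRCL", "WT", "AGE", "SCR", "SEX")


@dataclass(frozen=True)
class CovariateRelation:
    """One parameter-covariate relation in the model.

    ``center`` is the reference covariate value (population median); for
    ``power_allometric`` the exponent defaults to 0.75 on CL and 1.0 on V.
    """

    parameter: str
    covariate: str
    form: str = "linear_centered"
    center: float | None = None
    exponent: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in _PARAMETERS:
            raise ValueError(f"parameter must be one of {_PARAMETERS}")
        if self.covariate not in _COVARIATES:
            raise ValueError(f"covariate must be one of {_COVARIATES}")
        if self.form not in _FORMS:
            raise ValueError(f"form must be one of {_FORMS}")
        if self.form != "fractional_categorical" and self.center is not None:
            if self.center <= 0:
                raise ValueError("center must be positive for continuous covariates")

    @property
    def key(self) -> tuple[str, str]:
        return (self.parameter, self.covariate)

    @property
    def label(self) -> str:
        return f"{self.parameter}-{self.covariate}"

    def allometric_exponent(self) -> float:
        if self.exponent is not None:
            return self.exponent
        return 0.75 if self.parameter == "CL" else 1.0

    def factor(self, beta: float, value) -> np.ndarray | float:
        """Multiplicative factor for covariate value(s) ``value``."""
        if self.form == "linear_centered":
            if self.center is None:
                raise ValueError(f"relation {self.label} has no center")
            raw = 1.0 + beta * (np.asarray(value, dtype=float) - self.center)
            if np.any(raw < FACTOR_FLOOR):
                logger.warning(
                    "linear covariate factor %s floored at %.2f (extrapolation)",
                    self.label,
                    FACTOR_FLOOR,
                )
            return np.maximum(raw, FACTOR_FLOOR)
        if self.form == "power_allometric":
            if self.center is None:
                raise ValueError(f"relation {self.label} has no center")
            return (np.asarray(value, dtype=float) / self.center) ** self.allometric_exponent()
        # fractional_categorical: indicator = 1 for female
        ind = _female_indicator(value)
        raw = 1.0 + beta * ind
        if np.any(raw < FACTOR_FLOOR):
            logger.warning("categorical factor %s floored", self.label)
        return np.maximum(raw, FACTOR_FLOOR)


def _female_indicator(value) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=object))
    out = np.zeros(arr.shape, dtype=float)
    for i, v in enumerate(arr.ravel()):
        if isinstance(v, str):
            out.ravel()[i] = 1.0 if v.lower().startswith("f") else 0.0
        else:
            out.ravel()[i] = 1.0 if float(v) == 1.0 else 0.0
    return out if arr.shape != (1,) else out[0]


@dataclass(frozen=True)
class ThetaVector:
    """Population fixed effects: typical CL/V and covariate slopes.

    ``beta`` maps (parameter, covariate) -> slope; allometric relations need
    no slope.
    """

    tvcl: float
    tvv: float
    beta: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tvcl <= 0 or self.tvv <= 0:
            raise ValueError("tvcl and tvv must be positive")

    def slope(self, relation: CovariateRelation) -> float:
        if relation.form == "power_allometric":
            return 0.0
        try:
            return self.beta[relation.key]
        except KeyError as exc:
            raise KeyError(f"no slope for relation {relation.label}") from exc


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal BSV variances (log scale) for CL and V."""

    omega2_cl: float = 0.0
    omega2_v: float = 0.0

    def __post_init__(self) -> None:
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("variances must be >= 0")

    @property
    def bsv_cl_percent(self) -> float:
        """BSV on CL as %CV = 100 * sqrt(omega2)."""
        return 100.0 * float(np.sqrt(self.omega2_cl))

    @property
    def bsv_v_percent(self) -> float:
        return 100.0 * float(np.sqrt(self.omega2_v))

    @classmethod
    def from_cv_percent(cls, cv_cl: float, cv_v: float) -> "OmegaMatrix":
        return cls(omega2_cl=(cv_cl / 100.0) ** 2, omega2_v=(cv_v / 100.0) ** 2)

    def as_array(self) -> np.ndarray:
        return np.array([self.omega2_cl, self.omega2_v])


def _param_factor(
    theta: ThetaVector,
    relations,
    parameter: str,
    cov: Mapping[str, float],
) -> float | np.ndarray:
    factor = 1.0
    for rel in relations:
        if rel.parameter != parameter:
            continue
        if rel.covariate not in cov:
            raise KeyError(
                f"covariate {rel.covariate} required by relation {rel.label} "
                "is missing from the covariate vector"
            )
        factor = factor * rel.factor(theta.slope(rel), cov[rel.covariate])
    return factor


def typical_params(
    theta: ThetaVector, relations, cov: Mapping[str, float]
) -> PKParameters:
    """Typical-value (eta = 0) parameters for a covariate vector."""
    return individual_params(theta, relations, cov, np.zeros(2))


def individual_params(
    theta: ThetaVector,
    relations,
    cov: Mapping[str, float],
    eta,
) -> PKParameters:
    """Individual parameters for one subject.

    ``eta`` is the 2-vector of random effects (CL, V) on the log scale.
    """
    eta = np.asarray(eta, dtype=float)
    cl = theta.tvcl * _param_factor(theta, relations, "CL", cov) * np.exp(eta[0])
    v = theta.tvv * _param_factor(theta, relations, "V", cov) * np.exp(eta[1])
    return PKParameters(cl=float(cl), v=float(v))


def sample_etas(omega: OmegaMatrix, n: int, seed) -> np.ndarray:
    """Draw ``n`` independent eta pairs ~ N(0, diag(omega)); shape (n, 2).

    ``seed`` may be an int or a ``numpy.random.Generator``; draws are
    reproducible for a fixed seed.  Zero variance yields exact zeros.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = np.sqrt(omega.as_array())
    etas = rng.standard_normal((n, 2)) * sd[None, :]
    return etas
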