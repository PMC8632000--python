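"""Closed-form concentration-time solutions for IV-infusion compartmental models.

The production path everywhere in this package is analytic superposition of
single-infusion solutions (no ODE integration, no time grid).  For a
one-compartment model with first-order elimination (rate constant k = CL/V),
a single infusion of rate R starting at t0 with duration T gives

    C(t) = (R/CL) * (1 - exp(-k * min(t - t0, T))) * exp(-k * max(t - t0 - T, 0))

which covers both the on-infusion and post-infusion branches and is continuous
in t.  Multiple doses superpose linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "InfusionDose",
    "conc_one_cmt",
    "conc_two_cmt",
    "ss_trough_one_cmt",
]


@dataclass(frozen=True)
class PKParameters:
    """Individual PK parameters: clearance (L/h) and central volume (L).

    ``q`` / ``v2`` (inter-compartmental clearance and peripheral volume) are
    either both present (two-compartment model) or both absent.
    """

    cl: float
    v: float
    q: float | None = None
    v2: float | None = None

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v <= 0:
            raise ValueError(f"cl and v must be positive, got cl={self.cl}, v={self.v}")
        if (self.q is None) != (self.v2 is None):
            raise ValueError("q and v2 must be both present or both absent")
        if self.q is not None and (self.q <= 0 or self.v2 <= 0):
            raise ValueError("q and v2 must be positive when present")

    @property
    def k(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class InfusionDose:
    """A constant-rate IV infusion: amount in mg delivered over ``duration`` h."""

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration


def _one_cmt_profile(
    cl: float,
    v: float,
    t: np.ndarray,
    t0: np.ndarray,
    rate: np.ndarray,
    dur: np.ndarray,
    grad: bool = False,
):
    """Vectorized one-compartment superposition over observation times x doses.

    ``t`` has shape (n,); dose arrays have shape (m,).  Returns concentration
    of shape (n,), and when ``grad`` is true also dC/dCL and dC/dV (used by
    the FOCE-I engine, where d f/d eta follows by the chain rule).
    Padding doses with rate 0 contributes exactly zero.
    """
    k = cl / v
    te = t[:, None] - t0[None, :]
    infused = np.clip(te, 0.0, dur[None, :])  # infusion time elapsed so far
    tpost = np.maximum(te - dur[None, :], 0.0)  # decay time since infusion end
    E = np.exp(-k * infused)
    D = np.exp(-k * tpost)
    base = (rate[None, :] / cl) * (1.0 - E)
    C = base * D
    if not grad:
        return C.sum(axis=1)
    # dC/dk for each (t, dose) pair, then chain to CL and V
    dC_dk = D * (rate[None, :] / cl) * (infused * E) - base * tpost * D
    dC_dcl = -C / cl + dC_dk / v
    dC_dv = -dC_dk * cl / v**2
    return C.sum(axis=1), dC_dcl.sum(axis=1), dC_dv.sum(axis=1)


def conc_one_cmt(
    params: PKParameters, doses: Sequence[InfusionDose], t
) -> float | np.ndarray:
    """One-compartment concentration (mg/l) at time(s) ``t`` (h).

    Linear superposition over all doses; returns 0 before any drug is given.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if len(doses) == 0:
        out = np.zeros_like(t_arr)
    else:
        t0 = np.array([d.start_time for d in doses], dtype=float)
        rate = np.array([d.rate for d in doses], dtype=float)
        dur = np.array([d.duration for d in doses], dtype=float)
        out = _one_cmt_profile(params.cl, params.v, t_arr, t0, rate, dur)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def _ss_trough(cl, v, dose, tau, t_inf):
    """Steady-state pre-dose concentration, vectorized over cl/v/dose arrays."""
    k = cl / v
    rate_term = dose / (t_inf * cl)
    accumulation = (1.0 - np.exp(-k * t_inf)) / (1.0 - np.exp(-k * tau))
    return rate_term * accumulation * np.exp(-k * (tau - t_inf))


def ss_trough_one_cmt(
    params: PKParameters, dose: float, tau: float, t_inf: float
) -> float:
    """Steady-state trough (mg/l) for repeated infusions of ``dose`` mg q``tau``h.

    Trough is taken at t = tau after infusion start, i.e. the instant before
    the next dose.  Closed form; strictly increasing in dose and decreasing
    in clearance.
    """
    if not (tau > t_inf > 0):
        raise ValueError(f"need tau > t_inf > 0, got tau={tau}, t_inf={t_inf}")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return float(_ss_trough(params.cl, params.v, dose, tau, t_inf))


def _two_cmt_macro(cl: float, v: float, q: float, v2: float):
    """Macro-constants (alpha, beta, A, B) of the bi-exponential unit response."""
    k10 = cl / v
    k12 = q / v
    k21 = q / v2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(max(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = p / alpha  # stable for small q
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    return alpha, beta, A, B


def conc_two_cmt(
    params: PKParameters, doses: Sequence[InfusionDose], t
) -> float | np.ndarray:
    """Two-compartment (central observation) concentration for IV infusions.

    Standard bi-exponential solution via macro rate constants; reduces to the
    one-compartment solution as q -> 0.
    """
    if params.q is None or params.v2 is None:
        raise ValueError("two-compartment model requires q and v2")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    alpha, beta, A, B = _two_cmt_macro(params.cl, params.v, params.q, params.v2)
    out = np.zeros_like(t_arr)
    for d in doses:
        te = t_arr - d.start_time
        infused = np.clip(te, 0.0, d.duration)
        tpost = np.maximum(te - d.duration, 0.0)
        coef = d.rate / params.v
        out += coef * (
            (A / alpha) * (1.0 - np.exp(-alpha * infused)) * np.exp(-alpha * tpost)
            + (B / beta) * (1.0 - np.exp(-beta * infused)) * np.exp(-beta * tpost)
        )
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out
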