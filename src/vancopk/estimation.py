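"""FOCE-I estimation of the nonlinear mixed-effects population PK model.

The objective function value (OFV) is the first-order-conditional (with
interaction) approximation to -2 log marginal likelihood, summed over
subjects and omitting the n*log(2*pi) constant (the reporting convention of
the standard popPK tools).  For subject i with observations y_i:

1. the conditional mode eta_hat minimizes the penalized objective
       sum_j [ (y_ij - f_ij(eta))^2 / g_ij(eta) + log g_ij(eta) ]
           + eta' Omega^-1 eta
   where f is the structural prediction and g the residual variance,
   evaluated at eta (the "interaction");
2. the contribution is  log|V_i| + r_i' V_i^-1 r_i  with
       V_i = G_i Omega G_i' + diag(g(eta_hat)),
       G_i = df/deta at eta_hat,
       r_i = y_i - f_i(eta_hat) + G_i eta_hat.

Two implementations coexist deliberately: a transparent per-subject scalar
path (`foce_i_contribution`, `subject_ofv_foce_i`) used in verification, and
a padded-array vectorized engine used by `fit_model`; a test asserts their
agreement.

The inner problem is solved by a damped Newton iteration (Gauss-Newton
Hessian, Armijo backtracking) started at eta = 0, with analytic df/deta from
the closed-form one-compartment solution.  The outer problem is quasi-Newton
(L-BFGS-B) on a transformed scale: log for tvcl/tvv/variances/sigmas,
a fixed linear rescaling for covariate slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .covariates import CovariateRelation, OmegaMatrix, ThetaVector
from .datasets import StudyDataset, SubjectData
from .model import ErrorModel, ModelSpec, PopulationModel, PROP_F_FLOOR
from .structural import _one_cmt_profile

__all__ = [
    "EstimationError",
    "FitResult",
    "fit_model",
    "compute_cwres",
    "subject_ofv_foce_i",
    "foce_i_contribution",
    "make_predict_fn",
]

_INNER_GRAD_TOL = 1e-9
_INNER_MAX_ITER = 80
_PENALTY = 1e10


class EstimationError(RuntimeError):
    """Numerical failure during estimation (e.g. singular subject covariance)."""


# ----------------------------------------------------------------------------
# residual-variance helpers


def _variance_terms(sigma: ErrorModel, f: np.ndarray):
    """Residual variance g(f) and its derivative dg/df."""
    g = np.zeros_like(f)
    dg = np.zeros_like(f)
    if sigma.sigma_add is not None:
        g = g + sigma.sigma_add**2
    if sigma.sigma_prop is not None:
        fm = np.maximum(f, PROP_F_FLOOR)
        g = g + (sigma.sigma_prop * fm) ** 2
        dg = dg + 2.0 * sigma.sigma_prop**2 * fm * (f > PROP_F_FLOOR)
    return g, dg


# ----------------------------------------------------------------------------
# scalar (per-subject) reference path


def make_predict_fn(
    spec: ModelSpec,
    subject: SubjectData,
    theta: ThetaVector,
) -> Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Prediction function f(eta) -> (f, df/deta) for one subject.

    df/deta follows from the analytic dC/dCL, dC/dV of the closed-form
    one-compartment solution by the chain rule (CL = CL_typ * exp(eta1)).
    """
    if spec.structural != "one_compartment":
        raise NotImplementedError("estimation supports the one-compartment model")
    from .covariates import _param_factor  # shared factor logic

    cl_typ = theta.tvcl * float(_param_factor(theta, spec.relations, "CL", subject.covariates))
    v_typ = theta.tvv * float(_param_factor(theta, spec.relations, "V", subject.covariates))
    t = subject.obs_times
    t0 = subject.dose_times
    rate = subject.dose_amounts / subject.dose_durations
    dur = subject.dose_durations

    def predict(eta: np.ndarray):
        cl = cl_typ * np.exp(eta[0])
        v = v_typ * np.exp(eta[1])
        f, dcl, dv = _one_cmt_profile(cl, v, t, t0, rate, dur, grad=True)
        J = np.column_stack([dcl * cl, dv * v])
        return f, J

    return predict


def _inner_objective(eta, predict_fn, y, omega2, sigma, active):
    f, J = predict_fn(eta)
    g, _ = _variance_terms(sigma, f)
    r = y - f
    h = float(np.sum(r**2 / g + np.log(g)))
    for a in active:
        h += eta[a] ** 2 / omega2[a]
    return h, f, J, g, r


def foce_i_contribution(
    predict_fn: Callable,
    y: np.ndarray,
    omega2: Sequence[float],
    sigma: ErrorModel,
    eta0: np.ndarray | None = None,
    label: str = "subject",
):
    """FOCE-I contribution for one subject given a generic prediction function.

    Returns ``(contribution, eta_hat, info)`` where info carries f, J, g and V
    at the conditional mode.  With all omega2 zero this reduces exactly to
    sum[(y - f(0))^2/g(0) + log g(0)].
    """
    y = np.asarray(y, dtype=float)
    omega2 = np.asarray(omega2, dtype=float)
    active = [a for a in range(2) if omega2[a] > 0]
    eta = np.zeros(2) if eta0 is None else np.array(eta0, dtype=float)
    for a in range(2):
        if a not in active:
            eta[a] = 0.0

    h, f, J, g, r = _inner_objective(eta, predict_fn, y, omega2, sigma, active)
    for _ in range(_INNER_MAX_ITER):
        if not active:
            break
        _, dg = _variance_terms(sigma, f)
        grad = np.zeros(len(active))
        H = np.zeros((len(active), len(active)))
        for ia, a in enumerate(active):
            Ja = J[:, a]
            dga = dg * Ja
            grad[ia] = float(
                np.sum(-2.0 * r / g * Ja + (1.0 / g - r**2 / g**2) * dga)
            ) + 2.0 * eta[a] / omega2[a]
            for ib, b in enumerate(active):
                H[ia, ib] = float(np.sum(2.0 * J[:, a] * J[:, b] / g))
            H[ia, ia] += 2.0 / omega2[a]
        if np.max(np.abs(grad)) < _INNER_GRAD_TOL * max(1.0, abs(h)):
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.diag(H) + 1e-8)
        alpha = 1.0
        improved = False
        for _ls in range(30):
            eta_try = eta.copy()
            for ia, a in enumerate(active):
                eta_try[a] = np.clip(eta[a] - alpha * step[ia], -15.0, 15.0)
            h_try, f_t, J_t, g_t, r_t = _inner_objective(
                eta_try, predict_fn, y, omega2, sigma, active
            )
            if h_try <= h - 1e-4 * alpha * float(grad @ step):
                eta, h, f, J, g, r = eta_try, h_try, f_t, J_t, g_t, r_t
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break

    G = J.copy()
    for a in range(2):
        if a not in active:
            G[:, a] = 0.0
    V = (G * omega2[None, :]) @ G.T + np.diag(g)
    try:
        L, low = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular conditional covariance for {label}") from exc
    resid = y - f + G @ eta
    quad = float(resid @ scipy.linalg.cho_solve((L, low), resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    contribution = logdet + quad
    info = {"f": f, "J": J, "G": G, "g": g, "V": V, "resid": resid}
    return contribution, eta, info


def subject_ofv_foce_i(
    spec: ModelSpec,
    subject: SubjectData,
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: ErrorModel,
):
    """FOCE-I OFV contribution, conditional mode and gradient matrix G for one
    subject of a one-compartment population model."""
    if subject.n_obs < 1:
        raise ValueError(f"subject {subject.subject_id} has no observations")
    omega2 = omega.as_array().copy()
    if not spec.eta_on_cl:
        omega2[0] = 0.0
    if not spec.eta_on_v:
        omega2[1] = 0.0
    predict = make_predict_fn(spec, subject, theta)
    contribution, eta_hat, info = foce_i_contribution(
        predict, subject.dv, omega2, sigma, label=f"subject {subject.subject_id}"
    )
    return contribution, eta_hat, info["G"]


# ----------------------------------------------------------------------------
# vectorized engine (production path of fit_model)


class _FoceEngine:
    """Padded-array FOCE-I evaluator over all subjects simultaneously."""

    def __init__(self, spec: ModelSpec, ds: StudyDataset):
        if spec.structural != "one_compartment":
            raise NotImplementedError("estimation supports the one-compartment model")
        self.spec = spec
        subjects = ds.subjects()
        self.subject_ids = np.array([s.subject_id for s in subjects])
        S = len(subjects)
        M = max(s.n_obs for s in subjects)
        K = max(len(s.dose_times) for s in subjects)
        self.S, self.M, self.K = S, M, K
        self.Y = np.zeros((S, M))
        self.T = np.zeros((S, M))
        self.W = np.zeros((S, M))
        self.D0 = np.zeros((S, K))
        self.RATE = np.zeros((S, K))
        self.DUR = np.ones((S, K))
        self.n_obs_per_subject = np.array([s.n_obs for s in subjects])
        self.cov = {
            name: np.array([s.covariates[name] for s in subjects], dtype=object)
            for name in ("AGE", "WT", "SEX", "SCR", "CRCL")
        }
        for name in ("AGE", "WT", "SCR", "CRCL"):
            self.cov[name] = self.cov[name].astype(float)
        self.female = np.array(
            [1.0 if s.covariates["SEX"] == "female" else 0.0 for s in subjects]
        )
        for i, s in enumerate(subjects):
            n, m = s.n_obs, len(s.dose_times)
            self.Y[i, :n] = s.dv
            self.T[i, :n] = s.obs_times
            self.W[i, :n] = 1.0
            self.D0[i, :m] = s.dose_times
            self.RATE[i, :m] = s.dose_amounts / s.dose_durations
            self.DUR[i, :m] = s.dose_durations
        self.n_obs_total = int(self.W.sum())
        self.eta_cache = np.zeros((S, 2))

    # -- covariate factors ---------------------------------------------------
    def typical_cl_v(self, theta_vals: Mapping[str, float]):
        cl = np.full(self.S, theta_vals["tvcl"])
        v = np.full(self.S, theta_vals["tvv"])
        for rel in self.spec.relations:
            if rel.form == "fractional_categorical":
                x = self.female
            else:
                x = self.cov[rel.covariate]
            if rel.form == "linear_centered":
                beta = theta_vals[f"beta_{rel.parameter}_{rel.covariate}"]
                fac = np.maximum(1.0 + beta * (x - rel.center), 0.01)
            elif rel.form == "power_allometric":
                fac = (x / rel.center) ** rel.allometric_exponent()
            else:
                beta = theta_vals[f"beta_{rel.parameter}_{rel.covariate}"]
                fac = np.maximum(1.0 + beta * x, 0.01)
            if rel.parameter == "CL":
                cl = cl * fac
            else:
                v = v * fac
        return cl, v

    # -- structural prediction ----------------------------------------------
    def predict(self, cl: np.ndarray, v: np.ndarray, grad: bool = True):
        """f and df/deta for per-subject (cl, v); shapes (S, M) and (S, M, 2)."""
        k = (cl / v)[:, None, None]
        te = self.T[:, :, None] - self.D0[:, None, :]
        infused = np.clip(te, 0.0, self.DUR[:, None, :])
        tpost = np.maximum(te - self.DUR[:, None, :], 0.0)
        E = np.exp(-k * infused)
        D = np.exp(-k * tpost)
        base = (self.RATE[:, None, :] / cl[:, None, None]) * (1.0 - E)
        C = base * D
        f = C.sum(axis=2)
        if not grad:
            return f, None
        dC_dk = D * (self.RATE[:, None, :] / cl[:, None, None]) * (infused * E) - base * tpost * D
        dk = dC_dk.sum(axis=2)
        d_cl = -f / cl[:, None] + dk / v[:, None]
        d_v = -dk * (cl / v**2)[:, None]
        J = np.stack([d_cl * cl[:, None], d_v * v[:, None]], axis=2)
        return f, J

    def _g(self, f, sigma):
        g, dg = _variance_terms(sigma, f)
        g = np.where(self.W > 0, g, 1.0)
        return g, dg

    def _inner_h(self, eta, cl_typ, v_typ, sigma, omega2, active, grad: bool = True):
        cl = cl_typ * np.exp(eta[:, 0])
        v = v_typ * np.exp(eta[:, 1])
        f, J = self.predict(cl, v, grad=grad)
        g, dg = self._g(f, sigma)
        r = (self.Y - f) * self.W
        h = np.sum(self.W * (r**2 / g + np.log(g)), axis=1)
        for a in active:
            h = h + eta[:, a] ** 2 / omega2[a]
        return h, f, J, g, dg, r

    def solve_inner(self, theta_vals, omega2, sigma, eta0=None):
        """Vectorized damped Newton for all subjects' conditional modes."""
        active = [a for a in range(2) if omega2[a] > 0]
        cl_typ, v_typ = self.typical_cl_v(theta_vals)
        eta = np.zeros((self.S, 2)) if eta0 is None else eta0.copy()
        for a in range(2):
            if a not in active:
                eta[:, a] = 0.0
        h, f, J, g, dg, r = self._inner_h(eta, cl_typ, v_typ, sigma, omega2, active)
        if active:
            na = len(active)
            for _ in range(_INNER_MAX_ITER):
                grad = np.zeros((self.S, na))
                H = np.zeros((self.S, na, na))
                for ia, a in enumerate(active):
                    Ja = J[:, :, a] * self.W
                    dga = dg * Ja
                    grad[:, ia] = (
                        np.sum(-2.0 * r / g * Ja + (1.0 / g - r**2 / g**2) * dga * self.W, axis=1)
                        + 2.0 * eta[:, a] / omega2[a]
                    )
                    for ib, b in enumerate(active):
                        H[:, ia, ib] = np.sum(2.0 * Ja * (J[:, :, b] * self.W) / g, axis=1)
                    H[:, ia, ia] += 2.0 / omega2[a]
                gmax = np.max(np.abs(grad), axis=1)
                converged = gmax < _INNER_GRAD_TOL * np.maximum(1.0, np.abs(h))
                if np.all(converged):
                    break
                if na == 1:
                    step = grad / np.maximum(H[:, :, 0], 1e-12)
                else:
                    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
                    det = np.maximum(det, 1e-12)
                    step = np.empty_like(grad)
                    step[:, 0] = (H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
                    step[:, 1] = (H[:, 0, 0] * grad[:, 1] - H[:, 0, 1] * grad[:, 0]) / det
                # freeze converged subjects so their line search accepts at once
                step[converged] = 0.0
                descent = np.sum(grad * step, axis=1)
                alpha = np.ones(self.S)
                best = h.copy()
                eta_new = eta.copy()
                pending = ~converged
                for _ls in range(25):
                    trial = eta.copy()
                    for ia, a in enumerate(active):
                        trial[:, a] = np.clip(
                            eta[:, a] - alpha * step[:, ia], -15.0, 15.0
                        )
                    h_t = self._inner_h(trial, cl_typ, v_typ, sigma, omega2, active, grad=False)[0]
                    ok = pending & (h_t <= h - 1e-4 * alpha * descent)
                    eta_new[ok] = trial[ok]
                    best[ok] = h_t[ok]
                    pending = pending & ~ok
                    if not pending.any():
                        break
                    alpha[pending] *= 0.5
                if np.allclose(eta_new, eta):
                    break
                eta = eta_new
                h, f, J, g, dg, r = self._inner_h(eta, cl_typ, v_typ, sigma, omega2, active)
        return eta, f, J, g, cl_typ, v_typ

    def ofv(self, theta_vals, omega2, sigma, warm=True):
        """Total FOCE-I OFV; also refreshes the eta warm-start cache."""
        eta0 = self.eta_cache if warm else None
        eta, f, J, g, _, _ = self.solve_inner(theta_vals, omega2, sigma, eta0)
        self.eta_cache = eta
        contrib = self._contributions(eta, f, J, g, omega2)
        return float(np.sum(contrib))

    def _contributions(self, eta, f, J, g, omega2):
        G = J * self.W[:, :, None]
        for a in range(2):
            if omega2[a] <= 0:
                G = G.copy()
                G[:, :, a] = 0.0
        V = np.einsum("sma,a,sna->smn", G, omega2, G)
        idx = np.arange(self.M)
        V[:, idx, idx] += g
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular conditional covariance") from exc
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        r = (self.Y - f) * self.W + np.einsum("sma,sa->sm", G, eta)
        sol = np.linalg.solve(V, r[:, :, None])[:, :, 0]
        quad = np.sum(r * sol, axis=1)
        return logdet + quad

    def diagnostics(self, theta_vals, omega2, sigma):
        """EBEs, PRED, IPRED and CWRES at fixed parameter values.

        CWRES_i = L_i^-1 (y_i - yhat_i) with yhat_i = f(eta_hat) - G eta_hat
        and V_i = L_i L_i' the FOCE-I observation covariance; PRED is the
        typical-value prediction (eta = 0)."""
        eta, f, J, g, cl_typ, v_typ = self.solve_inner(theta_vals, omega2, sigma)
        G = J * self.W[:, :, None]
        for a in range(2):
            if omega2[a] <= 0:
                G[:, :, a] = 0.0
        V = np.einsum("sma,a,sna->smn", G, omega2, G)
        idx = np.arange(self.M)
        V[:, idx, idx] += g
        L = np.linalg.cholesky(V)
        r = (self.Y - f) * self.W + np.einsum("sma,sa->sm", G, eta)
        cwres_mat = np.linalg.solve(L, r[:, :, None])[:, :, 0]
        pred_mat, _ = self.predict(cl_typ, v_typ)
        rows_pred, rows_ipred, rows_cwres = [], [], []
        for i in range(self.S):
            n = self.n_obs_per_subject[i]
            rows_pred.append(pred_mat[i, :n])
            rows_ipred.append(f[i, :n])
            rows_cwres.append(cwres_mat[i, :n])
        return (
            eta,
            np.concatenate(rows_pred),
            np.concatenate(rows_ipred),
            np.concatenate(rows_cwres),
        )


# ----------------------------------------------------------------------------
# parameter layout / transforms


# covariate slopes are optimized as beta / _SLOPE_SCALE so their curvature is
# comparable to the log-scale parameters (raw slopes ~0.005 per ml/min or kg
# would make the outer problem badly conditioned); 0.1 keeps the scaled
# finite-difference step large enough to resolve slope gradients above the
# inner-solver noise floor
_SLOPE_SCALE = 0.1


@dataclass
class _ParamLayout:
    names: list[str]
    log_scale: list[bool]

    @classmethod
    def for_spec(cls, spec: ModelSpec) -> "_ParamLayout":
        names = ["tvcl", "tvv"]
        logs = [True, True]
        for rel in spec.relations:
            if rel.form != "power_allometric":
                names.append(f"beta_{rel.parameter}_{rel.covariate}")
                logs.append(False)
        if spec.eta_on_cl:
            names.append("omega2_cl")
            logs.append(True)
        if spec.eta_on_v:
            names.append("omega2_v")
            logs.append(True)
        if spec.error_kind in ("additive", "combined"):
            names.append("sigma_add")
            logs.append(True)
        if spec.error_kind in ("proportional", "combined"):
            names.append("sigma_prop")
            logs.append(True)
        return cls(names, logs)

    def encode(self, values: Mapping[str, float]) -> np.ndarray:
        x = np.empty(len(self.names))
        for i, (n, lg) in enumerate(zip(self.names, self.log_scale)):
            x[i] = np.log(values[n]) if lg else values[n] / _SLOPE_SCALE
        return x

    def decode(self, x: np.ndarray) -> dict[str, float]:
        return {
            n: float(np.exp(xi) if lg else xi * _SLOPE_SCALE)
            for n, lg, xi in zip(self.names, self.log_scale, x)
        }

    def bounds(self):
        out = []
        for n, lg in zip(self.names, self.log_scale):
            if lg:
                out.append((np.log(1e-8), np.log(1e8)))
            else:
                out.append((-100.0, 100.0))
        return out


_DEFAULT_INIT = {
    "tvcl": 3.0,
    "tvv": 30.0,
    "omega2_cl": 0.04,
    "omega2_v": 0.04,
    "sigma_add": 2.0,
    "sigma_prop": 0.2,
}


def _values_to_model(spec: ModelSpec, values: Mapping[str, float]) -> PopulationModel:
    beta = {
        rel.key: values[f"beta_{rel.parameter}_{rel.covariate}"]
        for rel in spec.relations
        if rel.form != "power_allometric"
    }
    theta = ThetaVector(tvcl=values["tvcl"], tvv=values["tvv"], beta=beta)
    omega = OmegaMatrix(
        omega2_cl=values.get("omega2_cl", 0.0), omega2_v=values.get("omega2_v", 0.0)
    )
    sigma = ErrorModel(
        kind=spec.error_kind,
        sigma_add=values.get("sigma_add"),
        sigma_prop=values.get("sigma_prop"),
    )
    return PopulationModel(spec=spec, theta=theta, omega=omega, sigma=sigma)


def _omega2_from_values(spec: ModelSpec, values: Mapping[str, float]) -> np.ndarray:
    return np.array(
        [
            values.get("omega2_cl", 0.0) if spec.eta_on_cl else 0.0,
            values.get("omega2_v", 0.0) if spec.eta_on_v else 0.0,
        ]
    )


def _sigma_from_values(spec: ModelSpec, values: Mapping[str, float]) -> ErrorModel:
    return ErrorModel(
        kind=spec.error_kind,
        sigma_add=values.get("sigma_add"),
        sigma_prop=values.get("sigma_prop"),
    )


@dataclass
class FitResult:
    """Result of a population fit: estimates, OFV, diagnostics."""

    model: PopulationModel
    ofv: float
    converged: bool
    estimates: dict[str, float]
    rse: dict[str, float] | None
    ebes: pd.DataFrame
    pred: np.ndarray
    ipred: np.ndarray
    cwres: np.ndarray
    n_subjects: int
    n_obs: int
    boundary: bool = False
    message: str = ""
    n_function_evals: int = 0

    @property
    def theta(self) -> ThetaVector:
        return self.model.theta

    @property
    def omega(self) -> OmegaMatrix:
        return self.model.omega

    @property
    def sigma(self) -> ErrorModel:
        return self.model.sigma

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, value in self.estimates.items():
            rows.append(
                {
                    "parameter": name,
                    "estimate": value,
                    "rse_percent": (self.rse or {}).get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def to_record(self) -> dict:
        return {
            "ofv": self.ofv,
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "rse_percent": None
            if self.rse is None
            else {k: float(v) for k, v in self.rse.items()},
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "message": self.message,
        }


def _resolve_centers(spec: ModelSpec, ds: StudyDataset) -> ModelSpec:
    """Fill missing relation centers with dataset covariate medians."""
    from dataclasses import replace as _replace

    frame = ds.frame
    per_subject = frame.groupby("ID", sort=False).first()
    new_rels = []
    for rel in spec.relations:
        if rel.center is None and rel.form != "fractional_categorical":
            center = float(per_subject[rel.covariate].median())
            new_rels.append(_replace(rel, center=center))
        else:
            new_rels.append(rel)
    return _replace(spec, relations=tuple(new_rels))


def fit_model(
    spec: ModelSpec,
    ds: StudyDataset,
    init: Mapping[str, float] | None = None,
    *,
    estimate_rse: bool = True,
    diagnostics: bool = True,
    maxiter: int = 400,
) -> FitResult:
    """Fit the population model by FOCE-I.

    ``init`` overrides the generic default initial values (natural scale).
    Deterministic: the same dataset and initial values give the same OFV.
    """
    spec = _resolve_centers(spec, ds)
    layout = _ParamLayout.for_spec(spec)
    values0 = dict(_DEFAULT_INIT)
    for rel in spec.relations:
        if rel.form != "power_allometric":
            values0.setdefault(f"beta_{rel.parameter}_{rel.covariate}", 0.0)
    if init:
        values0.update({k: v for k, v in init.items() if k in set(layout.names)})
    x0 = layout.encode(values0)

    engine = _FoceEngine(spec, ds)
    n_evals = [0]

    def objective(x: np.ndarray) -> float:
        n_evals[0] += 1
        values = layout.decode(x)
        omega2 = _omega2_from_values(spec, values)
        sigma = _sigma_from_values(spec, values)
        try:
            total = engine.ofv(values, omega2, sigma)
        except (EstimationError, FloatingPointError, np.linalg.LinAlgError):
            return _PENALTY
        if not np.isfinite(total):
            return _PENALTY
        return total

    res = scipy.optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=layout.bounds(),
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7, "eps": 1e-6, "maxcor": 20},
    )
    values = layout.decode(res.x)
    omega2 = _omega2_from_values(spec, values)
    sigma = _sigma_from_values(spec, values)
    ofv = engine.ofv(values, omega2, sigma)
    converged = bool(res.success) and ofv < _PENALTY / 2
    if not converged and ofv < _PENALTY / 2:
        # line-search failures at an already-stationary point (e.g. a warm
        # start at the optimum) are convergence; verify by FD gradient,
        # ignoring components pinned at their bounds
        bounds = layout.bounds()
        gmax = 0.0
        for i in range(len(res.x)):
            lo, hi = bounds[i]
            if res.x[i] - lo < 1e-6 or hi - res.x[i] < 1e-6:
                continue
            step = np.zeros(len(res.x))
            step[i] = 1e-5
            gmax = max(gmax, abs(objective(res.x + step) - objective(res.x - step)) / 2e-5)
        converged = gmax < 0.1
    boundary = bool(
        (spec.eta_on_cl and values.get("omega2_cl", 1.0) < 1e-7)
        or (spec.eta_on_v and values.get("omega2_v", 1.0) < 1e-7)
    )

    if diagnostics:
        eta, pred, ipred, cwres = engine.diagnostics(values, omega2, sigma)
        ebes = pd.DataFrame(
            {"ID": engine.subject_ids, "ETA1": eta[:, 0], "ETA2": eta[:, 1]}
        )
    else:
        eta = np.zeros((engine.S, 2))
        ebes = pd.DataFrame({"ID": engine.subject_ids})
        pred = ipred = cwres = np.array([])

    rse = None
    if estimate_rse and converged:
        rse = _rse_from_hessian(engine, spec, layout, values)

    model = _values_to_model(spec, values)
    return FitResult(
        model=model,
        ofv=float(ofv),
        converged=converged,
        estimates={n: values[n] for n in layout.names},
        rse=rse,
        ebes=ebes,
        pred=pred,
        ipred=ipred,
        cwres=cwres,
        n_subjects=engine.S,
        n_obs=engine.n_obs_total,
        boundary=boundary,
        message=str(res.message),
        n_function_evals=n_evals[0],
    )


def _rse_from_hessian(engine, spec, layout, values):
    """RSE% = 100*SE/estimate from a central-difference Hessian of the OFV on
    the natural scale; the covariance is 2 * H^-1 (OFV is -2 log L)."""
    names = layout.names
    p = np.array([values[n] for n in names])
    steps = np.maximum(1e-3 * np.abs(p), 1e-5)

    def f_at(q: np.ndarray) -> float:
        vals = dict(zip(names, q))
        omega2 = _omega2_from_values(spec, vals)
        try:
            sigma = _sigma_from_values(spec, vals)
            return engine.ofv(vals, omega2, sigma)
        except (ValueError, EstimationError, np.linalg.LinAlgError):
            return np.nan

    n = len(p)
    H = np.empty((n, n))
    f0 = f_at(p)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        H[i, i] = (f_at(p + ei) - 2.0 * f0 + f_at(p - ei)) / steps[i] ** 2
        for j in range(i):
            ej = np.zeros(n)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f_at(p + ei + ej) - f_at(p + ei - ej) - f_at(p - ei + ej) + f_at(p - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    rse = {}
    for i, name in enumerate(names):
        rse[name] = (
            float(100.0 * np.sqrt(var[i]) / abs(p[i])) if var[i] > 0 and p[i] != 0 else np.nan
        )
    return rse


def population_diagnostics(model: PopulationModel, ds: StudyDataset):
    """(PRED, IPRED, CWRES) table for a population model at fixed parameters.

    CWRES standardizes residuals by the FOCE-I observation covariance and is
    approximately standard normal under a correct model.
    Returns a DataFrame with one row per observation, in dataset order.
    """
    spec = model.spec
    engine = _FoceEngine(spec, ds)
    values = {"tvcl": model.theta.tvcl, "tvv": model.theta.tvv}
    for (p, c), b in model.theta.beta.items():
        values[f"beta_{p}_{c}"] = b
    values["omega2_cl"] = model.omega.omega2_cl
    values["omega2_v"] = model.omega.omega2_v
    if model.sigma.sigma_add is not None:
        values["sigma_add"] = model.sigma.sigma_add
    if model.sigma.sigma_prop is not None:
        values["sigma_prop"] = model.sigma.sigma_prop
    omega2 = _omega2_from_values(spec, values)
    sigma = model.sigma
    eta, pred, ipred, cwres = engine.diagnostics(values, omega2, sigma)
    obs = ds.frame[ds.frame["EVID"] == 0]
    return pd.DataFrame(
        {
            "ID": obs["ID"].to_numpy(),
            "TIME": obs["TIME"].to_numpy(dtype=float),
            "DV": obs["DV"].to_numpy(dtype=float),
            "PRED": pred,
            "IPRED": ipred,
            "CWRES": cwres,
        }
    )


def compute_cwres(fit: FitResult, ds: StudyDataset):
    """Recompute (PRED, IPRED, CWRES) for a fitted model on a dataset."""
    return population_diagnostics(fit.model, ds)
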