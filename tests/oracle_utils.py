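"""Independent oracles used by the tests.

These deliberately avoid the package's FOCE-I code paths: adaptive-free
Gauss-Hermite quadrature for the marginal likelihood, and an ODE integration
of the compartmental mass balance.  They exist only to cross-check the
analytic production code.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import solve_ivp


def quadrature_ofv_subject(predict_fn, y, omega2, sigma, nodes=61):
    """-2 log marginal likelihood (omitting n*log 2pi) by tensor-product
    Gauss-Hermite quadrature over the active random effects."""
    y = np.asarray(y, dtype=float)
    omega2 = np.asarray(omega2, dtype=float)
    x, w = hermgauss(nodes)
    active = [a for a in range(2) if omega2[a] > 0]
    if len(active) == 2:
        X1, X2 = np.meshgrid(x, x)
        W = np.outer(w, w).ravel()
        etas = np.column_stack(
            [np.sqrt(2 * omega2[0]) * X1.ravel(), np.sqrt(2 * omega2[1]) * X2.ravel()]
        )
        norm = np.pi
    elif len(active) == 1:
        a = active[0]
        etas = np.zeros((nodes, 2))
        etas[:, a] = np.sqrt(2 * omega2[a]) * x
        W = w
        norm = np.sqrt(np.pi)
    else:
        etas = np.zeros((1, 2))
        W = np.array([1.0])
        norm = 1.0
    ll = np.empty(len(etas))
    for i, eta in enumerate(etas):
        f, _ = predict_fn(eta)
        g = sigma.variance(f)
        ll[i] = -0.5 * np.sum(np.log(2 * np.pi * g) + (y - f) ** 2 / g)
    m = ll.max()
    logL = np.log(np.sum(W * np.exp(ll - m)) / norm) + m
    return -2.0 * logL - len(y) * np.log(2 * np.pi)


def ode_conc_two_cmt(cl, v, q, v2, doses, t_eval):
    """Two-compartment infusion concentrations by stiff ODE integration."""
    k10, k12, k21 = cl / v, q / v, q / v2

    def rate_in(t):
        r = 0.0
        for d in doses:
            if d.start_time <= t < d.start_time + d.duration:
                r += d.rate
        return r

    def rhs(t, a):
        return [
            rate_in(t) - (k10 + k12) * a[0] + k21 * a[1],
            k12 * a[0] - k21 * a[1],
        ]

    edges = sorted(
        {0.0, *[d.start_time for d in doses], *[d.start_time + d.duration for d in doses]}
    )
    sol = solve_ivp(
        rhs,
        (0.0, max(t_eval) + 1e-9),
        [0.0, 0.0],
        t_eval=np.asarray(t_eval, dtype=float),
        max_step=0.01,
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.y[0] / v
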