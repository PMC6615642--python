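"""Linear noise approximation for the controlled birth-death process.

The first-order system-size expansion of the master equation gives ODEs for
the mean vector and covariance matrix of (w, m):

    d<x>/dt   = f(<x>)                       f = ((lam-mu) w, (lam-mu) m)
    dSigma/dt = A Sigma + Sigma A^T + B      A = Jacobian of f at the mean
    B         = diag(w (lam+mu), m (lam+mu))

evaluated along the mean trajectory.  Heteroplasmy variance follows by the
delta method around the mean: Var(h) = g^T Sigma g with
g = (-m, w)/(w+m)^2.

Key qualitative consequences, recovered numerically here: the variance of a
controlled species saturates while an unsensed species' variance keeps
growing; equal sensing gives equal asymptotic variance growth; and the
initial heteroplasmy-variance growth rate is 2*mu*h0*(1-h0)/(w0+m0) —
it depends only on copy number and turnover, not on the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import ControlLaw, LinearLaw, PopulationState

__all__ = ["MomentTrajectory", "lna_moments", "initial_h_variance_rate",
           "drift_jacobian"]


@dataclass
class MomentTrajectory:
    times: np.ndarray
    mean: np.ndarray   # (n, 2): <w>, <m>
    cov: np.ndarray    # (n, 2, 2)

    @property
    def var_w(self) -> np.ndarray:
        return self.cov[:, 0, 0]

    @property
    def var_m(self) -> np.ndarray:
        return self.cov[:, 1, 1]

    @property
    def cov_wm(self) -> np.ndarray:
        return self.cov[:, 0, 1]

    @property
    def var_h(self) -> np.ndarray:
        """Delta-method heteroplasmy variance around the mean trajectory."""
        w, m = self.mean[:, 0], self.mean[:, 1]
        n2 = (w + m) ** 2
        gw, gm = -m / n2, w / n2
        return (gw * gw * self.var_w + gm * gm * self.var_m
                + 2.0 * gw * gm * self.cov_wm)

    def min_eigenvalue(self) -> float:
        return float(min(np.linalg.eigvalsh(c).min() for c in self.cov))


def drift_jacobian(law: ControlLaw, w: float, m: float, rel_step: float = 1e-6):
    """Jacobian of the drift at (w, m).

    Analytic for the linear law (in its unclamped region); central finite
    differences with step ``rel_step * scale`` otherwise.
    """
    if isinstance(law, LinearLaw):
        lam = law.mu + law.c1 * (law.w_opt - (w + law.delta * m))
        if lam > 0:  # inside the feasible region the clamp is inactive
            net = lam - law.mu
            return np.array([
                [net - law.c1 * w, -law.c1 * law.delta * w],
                [-law.c1 * m, net - law.c1 * law.delta * m],
            ])
    def f(wv, mv):
        return np.array(law.drift(wv, mv))

    hw = rel_step * max(abs(w), 1.0)
    hm = rel_step * max(abs(m), 1.0)
    J = np.empty((2, 2))
    J[:, 0] = (f(w + hw, m) - f(w - hw, m)) / (2 * hw)
    J[:, 1] = (f(w, m + hm) - f(w, m - hm)) / (2 * hm)
    return J


def lna_moments(
    law: ControlLaw,
    init: PopulationState,
    horizon: float,
    n_eval: int = 200,
    init_cov: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> MomentTrajectory:
    """Integrate the LNA mean and covariance ODEs from a (deterministic) start.

    ``init_cov`` defaults to zero (all cells start at the same state).
    Raises if the mean trajectory leaves the positive orthant, where the
    approximation breaks down.
    """
    if init.w <= 0 and init.m <= 0:
        raise ValueError("initial state must be strictly positive")

    def rhs(t, y):
        w, m = y[0], y[1]
        if w < -1e-6 or m < -1e-6:
            raise RuntimeError("LNA mean trajectory left the positive orthant")
        S = np.array([[y[2], y[3]], [y[3], y[4]]])
        fw, fm = law.drift(w, m)
        A = drift_jacobian(law, w, m)
        lam = float(law.birth_rate(w, m))
        B = np.diag([w * (lam + law.mu), m * (lam + law.mu)])
        dS = A @ S + S @ A.T + B
        return [fw, fm, dS[0, 0], dS[0, 1], dS[1, 1]]

    y0 = [init.w, init.m, 0.0, 0.0, 0.0]
    if init_cov is not None:
        y0[2], y0[3], y0[4] = init_cov[0][0], init_cov[0][1], init_cov[1][1]
    t_eval = np.linspace(0.0, horizon, n_eval)
    sol = solve_ivp(rhs, (0.0, horizon), y0, t_eval=t_eval,
                    rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"LNA integration failed: {sol.message}")
    mean = sol.y[:2].T
    cov = np.empty((len(sol.t), 2, 2))
    cov[:, 0, 0] = sol.y[2]
    cov[:, 0, 1] = cov[:, 1, 0] = sol.y[3]
    cov[:, 1, 1] = sol.y[4]
    return MomentTrajectory(times=sol.t, mean=mean, cov=cov)


def initial_h_variance_rate(init: PopulationState, mu: float) -> float:
    """Initial growth rate of heteroplasmy variance: 2*mu*h0*(1-h0)/(w0+m0).

    To first order this depends only on copy number and turnover — not on
    the form or tightness of the feedback control.
    """
    n = init.w + init.m
    if n <= 0:
        raise ValueError("w0 + m0 must be positive")
    h0 = init.m / n
    return 2.0 * mu * h0 * (1.0 - h0) / n
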