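"""Cellular mtDNA control laws and deterministic population dynamics.

A post-mitotic cell carries ``w`` wildtype and ``m`` mutant mtDNA molecules.
Every molecule replicates at a per-capita birth rate ``lambda(w, m)`` and is
degraded at a constant per-capita rate ``mu``.  Feedback control acts through
the replication rate only; the cell senses an *effective population*
``x = w + delta*m`` (``delta`` weighs how strongly mutants contribute to the
feedback signal) and steers it towards a target ``w_opt``.

Heteroplasmy ``h = m/(w+m)`` is deterministically conserved by every law in
this module: birth and death rates are per-capita and identical for both
species, so selection only arises through stochastic drift (see
:mod:`mitoctrl.stochastic`).
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PopulationState",
    "ControlLaw",
    "LinearLaw",
    "RelaxedLaw",
    "SensedLaw",
    "CalibrationError",
    "deterministic_trajectory",
    "heteroplasmy_summaries",
    "calibrate_alternative_control",
    "steady_state_for_h",
]

# numba kind codes shared with the SSA kernels
KIND_LINEAR = 0
KIND_RELAXED = 1
KIND_HYPERBOLIC = 2
KIND_EXPONENTIAL = 3


@dataclass(frozen=True)
class PopulationState:
    """State of a single cell: wildtype count, mutant count, time (days)."""

    w: float
    m: float
    t: float = 0.0

    def __post_init__(self):
        if self.w < 0 or self.m < 0:
            raise ValueError(f"copy numbers must be non-negative, got ({self.w}, {self.m})")

    @property
    def total(self) -> float:
        return self.w + self.m

    @property
    def h(self) -> float:
        """Heteroplasmy m/(w+m); undefined for an empty cell."""
        n = self.w + self.m
        if n <= 0:
            raise ValueError("heteroplasmy undefined for an empty cell (w + m = 0)")
        return self.m / n


class ControlLaw(ABC):
    """A replication-rate feedback rule with constant degradation rate ``mu``."""

    mu: float

    @abstractmethod
    def birth_rate(self, w, m):
        """Per-capita replication rate, clamped at zero (rates are non-negative)."""

    @abstractmethod
    def kind_code(self) -> int:
        ...

    @abstractmethod
    def param_array(self) -> np.ndarray:
        """Parameters packed for the jitted SSA kernels."""

    def drift(self, w, m):
        """Deterministic drift (dw/dt, dm/dt) = ((lam-mu) w, (lam-mu) m)."""
        net = self.birth_rate(w, m) - self.mu
        return net * w, net * m


@dataclass(frozen=True)
class LinearLaw(ControlLaw):
    """Linear feedback  lambda(w,m) = mu + c1*(w_opt - (w + delta*m)).

    ``c1`` sets how tightly the effective population is controlled; the
    deterministic fixed points form the line ``w + delta*m = w_opt``.
    ``delta`` may be negative (deficient mutants trigger wildtype
    proliferation) or exceed one.
    """

    mu: float
    c1: float
    w_opt: float
    delta: float = 1.0

    def __post_init__(self):
        if self.mu <= 0 or self.c1 <= 0 or self.w_opt <= 0:
            raise ValueError("require mu > 0, c1 > 0, w_opt > 0")

    def birth_rate(self, w, m):
        lam = self.mu + self.c1 * (self.w_opt - (w + self.delta * m))
        return np.maximum(lam, 0.0)

    def kind_code(self) -> int:
        return KIND_LINEAR

    def param_array(self) -> np.ndarray:
        return np.array([self.c1, self.w_opt, self.delta, 0.0], dtype=np.float64)


@dataclass(frozen=True)
class RelaxedLaw(ControlLaw):
    """The relaxed-replication control.

    lambda(w,m) = mu/(w+m) * ( alpha_R*[w_opt - (w + eta*m)] + (w + eta*m) )

    The replication rate relaxes towards the target effective population;
    both ``alpha_R`` (> 1) and ``eta`` shape the mutant contribution.
    Undefined for an empty cell.
    """

    mu: float
    alpha_R: float
    w_opt: float
    eta: float = 1.0

    def __post_init__(self):
        if self.alpha_R <= 1:
            raise ValueError("alpha_R must exceed 1")
        if self.mu <= 0 or self.w_opt <= 0:
            raise ValueError("require mu > 0, w_opt > 0")

    def birth_rate(self, w, m):
        n = np.asarray(w, dtype=float) + np.asarray(m, dtype=float)
        if np.any(n <= 0):
            raise ValueError("relaxed control is undefined at w + m = 0")
        x = w + self.eta * m
        lam = self.mu / n * (self.alpha_R * (self.w_opt - x) + x)
        out = np.maximum(lam, 0.0)
        return float(out) if np.isscalar(w) else out

    def kind_code(self) -> int:
        return KIND_RELAXED

    def param_array(self) -> np.ndarray:
        return np.array([self.alpha_R, self.w_opt, self.eta, 0.0], dtype=np.float64)


@dataclass(frozen=True)
class SensedLaw(ControlLaw):
    """Nonlinear monotone-decreasing controls of the sensed quantity x = w + delta*m.

    Two families:

    * ``hyperbolic``:  lambda(x) = a / (1 + (x/K)**n)  (n a fixed shape
      exponent, default 1 — the plain hyperbola)
    * ``exponential``: lambda(x) = a * exp(-x / x0)

    Both are calibrated against a target mutant-free mean/variance with
    :func:`calibrate_alternative_control`.
    """

    mu: float
    family: str
    a: float
    scale: float  # K (hyperbolic) or x0 (exponential)
    delta: float = 1.0
    n: float = 1.0  # shape exponent, hyperbolic only

    def __post_init__(self):
        if self.family not in ("hyperbolic", "exponential"):
            raise ValueError(f"unknown sensed family {self.family!r}")
        if self.a <= 0 or self.scale <= 0 or self.mu <= 0:
            raise ValueError("require a > 0, scale > 0, mu > 0")

    def birth_rate(self, w, m):
        x = np.maximum(w + self.delta * m, 0.0)
        if self.family == "hyperbolic":
            lam = self.a / (1.0 + (x / self.scale) ** self.n)
        else:
            lam = self.a * np.exp(-x / self.scale)
        return np.maximum(lam, 0.0)

    def kind_code(self) -> int:
        return KIND_HYPERBOLIC if self.family == "hyperbolic" else KIND_EXPONENTIAL

    def param_array(self) -> np.ndarray:
        return np.array([self.a, self.scale, self.delta, self.n], dtype=np.float64)


def deterministic_trajectory(
    law: ControlLaw,
    init: PopulationState,
    horizon: float,
    n_eval: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-8,
):
    """Integrate dw/dt = w(lambda - mu), dm/dt = m(lambda - mu).

    Returns ``(t, w, m)`` arrays sampled at ``n_eval`` equispaced times.
    Because both species share per-capita rates, heteroplasmy is conserved
    along the solution and trajectories converge to the law's steady-state
    manifold.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    def rhs(t, y):
        return law.drift(y[0], y[1])

    t_eval = np.linspace(0.0, horizon, n_eval)
    sol = solve_ivp(rhs, (0.0, horizon), [init.w, init.m], t_eval=t_eval,
                    rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"ODE integration failed at t={sol.t[-1]:.3f}: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


def heteroplasmy_summaries(w, m, delta: float | None = None) -> dict:
    """Cellular-mean vs homogenate heteroplasmy for a cell population.

    * cellular mean:  average over cells of per-cell m/(w+m)
    * homogenate:     pooled ratio  sum(m) / sum(w+m)  — what a tissue
      homogenate measurement reports
    * long-time homogenate prediction (if ``delta`` given): without explicit
      selection the homogenate drifts towards  m0/(m0 + delta*w0), pooled
      over cells.  Low mutant sensing (small delta) therefore lets the
      homogenate climb towards 1 even though the cellular mean is conserved.
    """
    w = np.asarray(w, dtype=float)
    m = np.asarray(m, dtype=float)
    if w.size == 0:
        raise ValueError("empty cell population")
    n = w + m
    if np.any(n <= 0):
        raise ValueError("every cell must have w + m > 0")
    out = {
        "cellular_mean_h": float(np.mean(m / n)),
        "homogenate_h": float(m.sum() / n.sum()),
    }
    if delta is not None:
        # Each cell's long-time mutant fraction is p = m0/(m0 + delta*w0); its
        # long-time total settles on the manifold w + delta*m = w_opt, i.e. is
        # proportional to 1/(1 - p + delta*p).  Pool with those weights.
        denom = m + delta * w
        if np.all(denom > 0):
            p = m / denom
            weight = 1.0 / (1.0 - p + delta * p)
            out["longtime_homogenate_h"] = float(np.sum(p * weight) / np.sum(weight))
        else:
            out["longtime_homogenate_h"] = float("nan")
    return out


class CalibrationError(ValueError):
    """Requested mutant-free mean/variance is unreachable for the family."""


def stationary_wildtype_variance(law: ControlLaw, w_star: float | None = None) -> float:
    """Mutant-free stationary variance of w from the linear noise approximation.

    For a per-capita control lambda(w) with fixed point lambda(w*) = mu, the
    fluctuation-dissipation relation gives  Var(w) = mu / |lambda'(w*)|.
    Computed here by a numeric derivative so it serves any differentiable law.
    """
    from scipy.optimize import brentq

    if w_star is None:
        f = lambda w: law.birth_rate(w, 0.0) - law.mu
        lo, hi = 1.0, 1.0
        while f(hi) > 0:
            hi *= 2
            if hi > 1e12:
                raise CalibrationError("no mutant-free fixed point found")
        while f(lo) < 0:
            lo /= 2
            if lo < 1e-9:
                raise CalibrationError("no mutant-free fixed point found")
        w_star = brentq(f, lo, hi, xtol=1e-10)
    eps = 1e-6 * max(w_star, 1.0)
    dlam = (law.birth_rate(w_star + eps, 0.0) - law.birth_rate(w_star - eps, 0.0)) / (2 * eps)
    if dlam >= 0:
        raise CalibrationError("control is not stabilising at the fixed point")
    return law.mu / abs(dlam)


def calibrate_alternative_control(
    family: str,
    target_mean: float,
    target_variance: float,
    mu: float,
    delta: float = 1.0,
    n: float = 1.0,
) -> ControlLaw:
    """Build a control whose mutant-free stationary mean and LNA variance match a target.

    Matching conditions (x = sensed quantity, evaluated mutant-free at w*):
    lambda(w*) = mu  and  |lambda'(w*)| = mu / Var_target.  Closed forms:

    * exponential a*exp(-x/x0):        x0 = Var,  a = mu*exp(w*/x0)
    * hyperbolic  a/(1+(x/K)**n):      Var = w*(1+u)/(n*u) with u=(w*/K)**n,
      feasible only when  n*Var > w*  (the family's variance floor is w*/n).

    ``family`` may also be ``"linear"`` (self-calibration: c1 = mu/Var).
    """
    if target_variance <= 0 or target_mean <= 0:
        raise CalibrationError("target mean and variance must be positive")
    w_star, V = float(target_mean), float(target_variance)
    if family == "linear":
        return LinearLaw(mu=mu, c1=mu / V, w_opt=w_star, delta=delta)
    if family == "exponential":
        x0 = V
        a = mu * math.exp(w_star / x0)
        law = SensedLaw(mu=mu, family="exponential", a=a, scale=x0, delta=delta)
    elif family == "hyperbolic":
        if n * V <= w_star:
            raise CalibrationError(
                f"hyperbolic family (n={n}) cannot reach variance {V} at mean "
                f"{w_star}: floor is {w_star / n:.4g}"
            )
        u = w_star / (n * V - w_star)
        K = w_star / u ** (1.0 / n)
        a = mu * (1.0 + u)
        law = SensedLaw(mu=mu, family="hyperbolic", a=a, scale=K, delta=delta, n=n)
    else:
        raise ValueError(f"unknown family {family!r}")
    # verify against the LNA closed form (1% contract)
    got = stationary_wildtype_variance(law, w_star=w_star)
    if abs(got - V) > 0.01 * V:
        raise CalibrationError(f"calibration check failed: variance {got:.4g} vs target {V:.4g}")
    return law


def steady_state_for_h(law: ControlLaw, h: float) -> PopulationState:
    """Deterministic steady state with heteroplasmy h on the law's manifold."""
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    if isinstance(law, LinearLaw):
        denom = (1.0 - h) + law.delta * h
        if denom <= 0:
            raise ValueError("no positive steady state at this (h, delta)")
        n = law.w_opt / denom
    elif isinstance(law, RelaxedLaw):
        xfrac = (1.0 - h) + law.eta * h
        denom = 1.0 + (law.alpha_R - 1.0) * xfrac
        if denom <= 0:
            raise ValueError("no positive steady state at this (h, eta)")
        n = law.alpha_R * law.w_opt / denom
    else:
        # generic: per-capita rate along the ray (1-h, h)*n equals mu
        from scipy.optimize import brentq

        f = lambda n: law.birth_rate((1 - h) * n, h * n) - law.mu
        n = brentq(f, 1e-6, 1e9)
    return PopulationState(w=(1.0 - h) * n, m=h * n)
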