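"""An effective energy-based cost for mtDNA states (w, m).

The cost of a state balances unmet demand against resource use:

    C(w, m) = |D - S(w, m)| + alpha * (w*r_w + m*r_m),      r_m = eps1 * r_w

with net supply (all terms rates, ATP/s)

    S(w, m) = w*(s(r_w) - rho1) + m*(eps2*s(eps1*r_w) - rho1)
              - (w + m)*(rho2*lam + rho3*mu)

where s(r) is the power output of one (wildtype) mitochondrion at resource
consumption rate r, rho1/rho2/rho3 are maintenance, building and degradation
costs, and lam/mu are the birth/death rates *per second*.  Mutants draw
resource at a fraction eps1 of the wildtype rate and convert it with
relative efficiency eps2 (default 1: dysfunction enters through reduced
uptake, as for damaged respiratory complexes).

Two output models:

    linear:      s(r) = phi * (r - beta)
    saturating:  s(r) = 2*s_max / (1 + exp(-k*r)) - 1.1*s_max

Both cross zero supply at a small basal "leak" consumption and are matched
at low rates when phi = s_max*k/2 and beta = 0.2/k.  The saturating model
caps power at 0.9*s_max, creating spare capacity and — for moderately
dysfunctional mutants — a most-expensive *intermediate* heteroplasmy h_max.

Resource allocation: mitochondria consume just enough to meet demand when
possible (demand-matched); otherwise they work at r_max (capacity-capped) or
share the cell's total resource supply rate R equally (resource-shared).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = ["OutputModel", "CostParams", "ResourceSolution", "CostLandscape",
           "mito_output", "solve_resource_rate", "state_cost",
           "cost_landscape", "h_max_at_total", "expected_cost_taylor",
           "default_cost_params", "optimal_copy_number"]

SECONDS_PER_DAY = 86400.0
#: default mtDNA turnover, per *second* (0.07/day, ~10-day half-life)
MU_PER_S = 0.07 / SECONDS_PER_DAY


@dataclass(frozen=True)
class OutputModel:
    """Power production s(r) of a single mitochondrion (ATP/s)."""

    kind: str = "saturating"  # "linear" | "saturating"
    phi: float = 1.0          # efficiency (linear)
    beta: float = 0.1         # basal leak offset (linear)
    s_max: float = 1.0        # maximum power (saturating)
    k: float = 2.0            # saturation rate (saturating)

    def __post_init__(self):
        if self.kind not in ("linear", "saturating"):
            raise ValueError(f"unknown output model kind {self.kind!r}")
        if self.phi <= 0 or self.s_max <= 0 or self.k <= 0:
            raise ValueError("require phi > 0, s_max > 0, k > 0")

    def __call__(self, r):
        return mito_output(r, self)


def mito_output(r, model: OutputModel):
    """Evaluate the output model at resource consumption rate r >= 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("resource rate must be non-negative")
    if model.kind == "linear":
        out = model.phi * (r - model.beta)
    else:
        out = 2.0 * model.s_max / (1.0 + np.exp(-model.k * r)) - 1.1 * model.s_max
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CostParams:
    D: float                  # energy demand (ATP/s)
    R: float                  # total resource supply rate (resource/s)
    r_max: float              # per-mitochondrion max consumption rate
    alpha: float              # cost per unit of resource consumption rate
    rho1: float               # maintenance cost (ATP/s per mitochondrion)
    rho2: float               # building cost (ATP per replication)
    rho3: float               # degradation cost (ATP per degradation)
    eps1: float = 0.3         # mutant relative resource uptake, in [0, 1]
    eps2: float = 1.0         # mutant relative efficiency, in [0, 1]
    output: OutputModel = field(default_factory=OutputModel)

    def __post_init__(self):
        if min(self.D, self.R, self.r_max, self.alpha) < 0:
            raise ValueError("D, R, r_max, alpha must be non-negative")
        if not (0 <= self.eps1 <= 1 and 0 <= self.eps2 <= 1):
            raise ValueError("eps1 and eps2 must lie in [0, 1]")


def default_cost_params(output: str = "saturating", eps1: float = 0.3,
                        scale: float = 1.0, **overrides) -> CostParams:
    """Illustrative defaults reproducing the qualitative cost regimes.

    ``scale`` multiplies demand and resource supply, moving the landscape to
    proportionally larger copy numbers (the demand-matched copy-number scale
    is ~scale*1000 for the saturating model).
    """
    model = (OutputModel(kind="saturating", s_max=1.0, k=2.0)
             if output == "saturating"
             else OutputModel(kind="linear", phi=1.0, beta=0.1))
    base = dict(D=450.0 * scale, R=3000.0 * scale, r_max=1.2, alpha=0.01,
                rho1=0.05, rho2=6000.0, rho3=6000.0, eps1=eps1, eps2=1.0,
                output=model)
    base.update(overrides)
    return CostParams(**base)


@dataclass(frozen=True)
class ResourceSolution:
    r_w: float
    regime: str       # demand-matched | capacity-capped | resource-shared
    supply: float

    @property
    def r_m_factor(self):  # r_m = eps1 * r_w is applied by the caller
        return self.r_w


def _supply(r_w: float, w: float, m: float, p: CostParams,
            lam_s: float, mu_s: float) -> float:
    s = p.output
    return (w * (mito_output(r_w, s) - p.rho1)
            + m * (p.eps2 * mito_output(p.eps1 * r_w, s) - p.rho1)
            - (w + m) * (p.rho2 * lam_s + p.rho3 * mu_s))


def solve_resource_rate(
    w: float, m: float, p: CostParams,
    lam_s: float = MU_PER_S, mu_s: float = MU_PER_S,
    tol_rel: float = 1e-9,
) -> ResourceSolution:
    """Resource consumption rate per wildtype mitochondrion for state (w, m).

    Mitochondria meet demand exactly when they can (smallest such r_w; supply
    is monotone increasing in r_w, so the root is unique); otherwise they run
    at the binding cap: r_max (capacity-capped) or R/(w + eps1*m)
    (resource-shared).
    """
    if w + m <= 0:
        return ResourceSolution(r_w=0.0, regime="empty", supply=0.0)
    weighted = w + p.eps1 * m
    r_share = p.R / weighted if weighted > 0 else np.inf
    if r_share < p.r_max:
        r_cap, cap_regime = r_share, "resource-shared"
    else:
        r_cap, cap_regime = p.r_max, "capacity-capped"
    S_cap = _supply(r_cap, w, m, p, lam_s, mu_s)
    if S_cap < p.D:
        return ResourceSolution(r_w=r_cap, regime=cap_regime, supply=S_cap)
    S0 = _supply(0.0, w, m, p, lam_s, mu_s)
    if S0 >= p.D:  # degenerate: supply exceeds demand even at zero consumption
        return ResourceSolution(r_w=0.0, regime="demand-matched", supply=S0)
    r = brentq(lambda rr: _supply(rr, w, m, p, lam_s, mu_s) - p.D,
               0.0, r_cap, xtol=1e-15, rtol=1e-14)
    return ResourceSolution(r_w=float(r), regime="demand-matched",
                            supply=_supply(r, w, m, p, lam_s, mu_s))


def state_cost(w: float, m: float, p: CostParams,
               lam_s: float = MU_PER_S, mu_s: float = MU_PER_S) -> float:
    """C(w, m) = |D - S| + alpha*(w + eps1*m)*r_w."""
    if w + m <= 0:
        return abs(p.D)
    sol = solve_resource_rate(w, m, p, lam_s, mu_s)
    return abs(p.D - sol.supply) + p.alpha * (w + p.eps1 * m) * sol.r_w


@dataclass
class CostLandscape:
    w_grid: np.ndarray
    m_grid: np.ndarray
    cost: np.ndarray       # (len(m_grid), len(w_grid))
    demand_ok: np.ndarray  # same shape, True where demand-matched

    def to_frame(self):
        import pandas as pd

        W, M = np.meshgrid(self.w_grid, self.m_grid)
        return pd.DataFrame({"w": W.ravel(), "m": M.ravel(),
                             "cost": self.cost.ravel(),
                             "demand_ok": self.demand_ok.ravel()})


def cost_landscape(p: CostParams, w_grid, m_grid,
                   lam_s: float = MU_PER_S, mu_s: float = MU_PER_S) -> CostLandscape:
    """Evaluate the cost and demand-satisfiability over a (w, m) grid."""
    w_grid = np.asarray(w_grid, dtype=float)
    m_grid = np.asarray(m_grid, dtype=float)
    if w_grid.size == 0 or m_grid.size == 0:
        raise ValueError("grid ranges must be non-empty")
    cost = np.empty((m_grid.size, w_grid.size))
    ok = np.zeros_like(cost, dtype=bool)
    for i, m in enumerate(m_grid):
        for j, w in enumerate(w_grid):
            if w + m <= 0:
                cost[i, j] = abs(p.D)
                continue
            sol = solve_resource_rate(w, m, p, lam_s, mu_s)
            ok[i, j] = sol.regime == "demand-matched"
            cost[i, j] = abs(p.D - sol.supply) + p.alpha * (w + p.eps1 * m) * sol.r_w
    return CostLandscape(w_grid, m_grid, cost, ok)


def h_max_at_total(p: CostParams, total: float, n_h: int = 201,
                   lam_s: float = MU_PER_S, mu_s: float = MU_PER_S) -> float:
    """Most expensive heteroplasmy at fixed total copy number.

    Scans h in [0, 1] along (w, m) = ((1-h)N, hN) and returns the argmax of
    the cost.  For the saturating model with moderately dysfunctional mutants
    (eps1 in roughly (0.5, 1)) this lands at an intermediate h; for severely
    dysfunctional mutants (eps1 <~ 0.3) the homoplasmic mutant state h = 1 is
    the most expensive.
    """
    hs = np.linspace(0.0, 1.0, n_h)
    costs = [state_cost((1 - h) * total, h * total, p, lam_s, mu_s) for h in hs]
    return float(hs[int(np.argmax(costs))])


def optimal_copy_number(p: CostParams, bracket=(1.0, 1e5),
                        lam_s: float = MU_PER_S, mu_s: float = MU_PER_S) -> float:
    """Mutant-free copy number minimising the cost (the natural w_opt)."""
    res = minimize_scalar(lambda w: state_cost(w, 0.0, p, lam_s, mu_s),
                          bounds=bracket, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)


def expected_cost_taylor(cost_fn, mean, cov, step: float = 1.0) -> float:
    """Second-order Taylor estimate of E[C] under fluctuations around the mean.

        E[C] ~ C(mean) + 1/2*(Var(w) Cww + Var(m) Cmm + 2 Cov(w,m) Cwm)

    with second derivatives by central differences (exact for quadratics).
    Fluctuations between cells therefore raise the mean cost of maintaining
    a tissue whenever the cost surface is locally convex, even at constant
    mean copy numbers and demand.
    """
    wbar, mbar = float(mean[0]), float(mean[1])
    cov = np.asarray(cov, dtype=float)
    c0 = cost_fn(wbar, mbar)
    h = step
    cww = (cost_fn(wbar + h, mbar) - 2 * c0 + cost_fn(wbar - h, mbar)) / h**2
    cmm = (cost_fn(wbar, mbar + h) - 2 * c0 + cost_fn(wbar, mbar - h)) / h**2
    cwm = (cost_fn(wbar + h, mbar + h) - cost_fn(wbar + h, mbar - h)
           - cost_fn(wbar - h, mbar + h) + cost_fn(wbar - h, mbar - h)) / (4 * h**2)
    out = c0 + 0.5 * (cov[0, 0] * cww + cov[1, 1] * cmm + 2 * cov[0, 1] * cwm)
    if not np.isfinite(out):
        raise FloatingPointError("non-finite curvature estimate in expected cost")
    return float(out)
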