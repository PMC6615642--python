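"""Mitochondrially targeted nuclease (mtZFN) gene therapy on top of
cellular feedback control.

Transfection floods the cell with an effective nuclease pool whose
concentration follows an immigration-death model with exponentially decaying
immigration I(t) = I0*exp(-b*t):

    [ZFN](t) = I0/(mu_z - b) * (exp(-b*t) - exp(-mu_z*t))

(limit I0*t*exp(-mu_z*t) at b = mu_z).  The nuclease raises mtDNA death
rates selectively: the mutant excess rate equals the summed concentration
Z(t) over all past transfection rounds, the wildtype excess is xi*Z(t)
(xi = wildtype cleavages per mutant cleavage; xi = 0 perfectly selective,
xi = 1 indiscriminate).  Untreated dynamics are recovered exactly at Z = 0.

Deterministic dynamics (linear feedback control):

    dw/dt = w [ c1 (w_opt - (w + delta*m)) - xi * Z(t) ]
    dm/dt = m [ c1 (w_opt - (w + delta*m)) - Z(t) ]

Stochastic mode runs a time-inhomogeneous SSA with the same rates (exact
thinning).  Copy number collapses during nuclease expression and recovers
under feedback control; heteroplasmy shifts downward for xi < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .dynamics import ControlLaw, LinearLaw, PopulationState
from .stochastic import spawn_seeds, summarize_ensemble

__all__ = ["TreatmentParams", "TreatmentOutcome", "zfn_concentration",
           "zfn_peak", "excess_death_rates", "simulate_treatment",
           "treat_cell_population", "heteroplasmy_transfer_map",
           "optimize_treatment_strength"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class TreatmentParams:
    """One protocol: strength I0, duration constant b, selectivity xi,
    nuclease decay mu_z (default ln 2: one-day half-life), and the round
    schedule (transfections at 0, period, ..., (n_rounds-1)*period days)."""

    I0: float
    b: float
    xi: float
    mu_z: float = LN2
    period: float = 28.0
    n_rounds: int = 1

    def __post_init__(self):
        if self.I0 < 0 or self.b <= 0 or self.xi < 0 or self.mu_z <= 0:
            raise ValueError("require I0 >= 0, b > 0, xi >= 0, mu_z > 0")
        if self.period <= 0 or self.n_rounds < 1:
            raise ValueError("require period > 0 and n_rounds >= 1")


def zfn_concentration(t, params: TreatmentParams):
    """[ZFN](t) for a single transfection at t = 0 (vectorised)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    d = params.mu_z - params.b
    if abs(d) < 1e-10 * params.mu_z:
        out = params.I0 * t * np.exp(-params.mu_z * t)
    else:
        out = params.I0 / d * (np.exp(-params.b * t) - np.exp(-params.mu_z * t))
    return float(out) if out.ndim == 0 else out


def zfn_peak(params: TreatmentParams) -> tuple[float, float]:
    """(time, value) of the concentration peak: t* = ln(b/mu_z)/(b - mu_z)."""
    if abs(params.b - params.mu_z) < 1e-10 * params.mu_z:
        t_star = 1.0 / params.mu_z
    else:
        t_star = math.log(params.b / params.mu_z) / (params.b - params.mu_z)
    return t_star, float(zfn_concentration(t_star, params))


def summed_concentration(t, params: TreatmentParams):
    """Z(t): nuclease from all transfection rounds no later than t (vectorised)."""
    scalar = np.isscalar(t) or np.asarray(t).ndim == 0
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    z = np.zeros_like(tt)
    for j in range(params.n_rounds):
        tau = tt - j * params.period
        live = tau >= 0
        if not live.any():
            break
        z[live] += zfn_concentration(tau[live], params)
    return float(z[0]) if scalar else z


def excess_death_rates(t, params: TreatmentParams):
    """(wildtype excess, mutant excess) death rates at time t.

    Mutant excess = Z(t); wildtype excess = xi*Z(t).  Total death rates are
    the cellular baseline mu plus these, so untreated dynamics are recovered
    exactly once the nuclease has decayed.
    """
    z = summed_concentration(t, params)
    return params.xi * z, z


@dataclass
class TreatmentOutcome:
    times: np.ndarray
    w: np.ndarray               # (n_times,) deterministic or ensemble mean
    m: np.ndarray
    h: np.ndarray
    rel_total: np.ndarray       # (w+m) / initial total
    mode: str
    per_round_h: np.ndarray | None = None          # h at the end of each round
    per_round_rel_total: np.ndarray | None = None
    # population-level extras
    final_h_values: np.ndarray | None = None       # per-cell h (survivors)
    per_round_mean_h: np.ndarray | None = None
    per_round_p_above: np.ndarray | None = None
    frac_extinct: float = 0.0


def _law_arrays(law: ControlLaw):
    return law.kind_code(), law.param_array(), law.mu


def simulate_treatment(
    law: ControlLaw,
    params: TreatmentParams,
    init: PopulationState,
    horizon: float | None = None,
    mode: str = "deterministic",
    seed: int = 0,
    n_times: int = 400,
    sample_times: np.ndarray | None = None,
) -> TreatmentOutcome:
    """Simulate one cell through the full treatment schedule."""
    if horizon is None:
        horizon = params.period * params.n_rounds
    if horizon < params.period:
        raise ValueError("horizon must cover at least one treatment round")
    if sample_times is None:
        sample_times = np.linspace(0.0, horizon, n_times)
    st = np.asarray(sample_times, dtype=np.float64)
    kind, p, mu = _law_arrays(law)
    if mode == "deterministic":
        W, M = _kernels.treat_rk4(kind, p, mu, params.xi, params.I0, params.b,
                                  params.mu_z, params.period, params.n_rounds,
                                  float(init.w), float(init.m), st,
                                  1e-3, 2.0, 2e-2)
    elif mode == "stochastic":
        W, M = _kernels.treat_ssa(kind, p, mu, params.xi, params.I0, params.b,
                                  params.mu_z, params.period, params.n_rounds,
                                  int(round(init.w)), int(round(init.m)), st,
                                  seed)
        W, M = W.astype(float), M.astype(float)
    else:
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    tot = W + M
    n0 = init.w + init.m
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(tot > 0, M / np.maximum(tot, 1e-300), np.nan)
    round_ends = np.array([min(params.period * (j + 1), horizon)
                           for j in range(params.n_rounds)])
    # last recorded sample at or before each round end (end-of-recovery state)
    idx = np.clip(np.searchsorted(st, round_ends + 1e-9) - 1, 0, st.size - 1)
    return TreatmentOutcome(
        times=st, w=W, m=M, h=h, rel_total=tot / n0, mode=mode,
        per_round_h=h[idx], per_round_rel_total=(tot / n0)[idx],
    )


def _steady_totals_for_h(law: ControlLaw, h_values: np.ndarray) -> np.ndarray:
    """Per-cell steady-state totals on the control manifold for given h."""
    from .dynamics import steady_state_for_h

    return np.array([steady_state_for_h(law, float(h)).total for h in h_values])


def treat_cell_population(
    h_values: np.ndarray,
    params: TreatmentParams,
    law: ControlLaw,
    seed: int = 0,
    threshold: float = 0.6,
    sample_per_round: int = 8,
) -> TreatmentOutcome:
    """Stochastic treatment of a cell population (every cell transfected).

    Cells start at their steady-state copy numbers for their heteroplasmy.
    Reports the post-round h distribution, its mean over surviving cells,
    and the threshold-crossing probability P(h > threshold).
    """
    h_values = np.asarray(h_values, dtype=float)
    if np.any((h_values < 0) | (h_values > 1)):
        raise ValueError("h values must lie in [0, 1]")
    totals = _steady_totals_for_h(law, h_values)
    m0s = np.round(h_values * totals).astype(np.int64)
    w0s = np.round(totals).astype(np.int64) - m0s
    horizon = params.period * params.n_rounds
    st = np.linspace(0.0, horizon, params.n_rounds * sample_per_round + 1)
    kind, p, mu = _law_arrays(law)
    seeds = spawn_seeds(seed, h_values.size)
    W, M = _kernels.treat_ssa_ensemble(kind, p, mu, params.xi, params.I0,
                                       params.b, params.mu_z, params.period,
                                       params.n_rounds, w0s, m0s, st, seeds)
    summ = summarize_ensemble(st, W, M)
    round_ends = np.array([params.period * (j + 1) for j in range(params.n_rounds)])
    idx = np.clip(np.searchsorted(st, round_ends + 1e-9) - 1, 0, st.size - 1)
    tot = W + M
    alive = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(alive, M / np.maximum(tot, 1), np.nan)
    p_above = np.array([np.nanmean(h[:, i] > threshold) for i in idx])
    mean_h = np.array([np.nanmean(h[:, i]) for i in idx])
    return TreatmentOutcome(
        times=st, w=summ.mean_w, m=summ.mean_m, h=summ.mean_h,
        rel_total=(summ.mean_w + summ.mean_m) / np.mean(totals),
        mode="population",
        final_h_values=h[alive[:, -1], -1],
        per_round_mean_h=mean_h, per_round_p_above=p_above,
        frac_extinct=float(summ.frac_extinct[-1]),
    )


def heteroplasmy_transfer_map(
    h_grid: np.ndarray,
    params: TreatmentParams,
    law: ControlLaw,
    mode: str = "deterministic",
    n_reps: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Mean final heteroplasmy h_f after one treatment + recovery, per h_i.

    Shifts are largest at intermediate h_i; at high h_i with xi near 1 the
    stochastic map can even end above its start.
    """
    one_round = replace(params, n_rounds=1)
    h_grid = np.asarray(h_grid, dtype=float)
    totals = _steady_totals_for_h(law, h_grid)
    out = np.empty_like(h_grid)
    for i, (h0, n0) in enumerate(zip(h_grid, totals)):
        init = PopulationState(w=(1 - h0) * n0, m=h0 * n0)
        if h0 == 0.0 or h0 == 1.0:
            out[i] = h0  # no molecules of the other species to create
            continue
        if mode == "deterministic":
            res = simulate_treatment(law, one_round, init, one_round.period,
                                     mode="deterministic", n_times=50)
            out[i] = res.h[-1]
        else:
            kind, p, mu = _law_arrays(law)
            st = np.array([one_round.period])
            seeds = spawn_seeds(seed + i, n_reps)
            w0 = int(round(init.w))
            m0 = int(round(init.m))
            W, M = _kernels.treat_ssa_ensemble(
                kind, p, mu, params.xi, params.I0, params.b, params.mu_z,
                one_round.period, 1, np.full(n_reps, w0, np.int64),
                np.full(n_reps, m0, np.int64), st, seeds)
            tot = (W + M)[:, 0]
            alive = tot > 0
            out[i] = np.mean(M[alive, 0] / tot[alive]) if alive.any() else np.nan
    return out


def optimize_treatment_strength(
    law: ControlLaw,
    init: PopulationState,
    b: float,
    eps1: float | None = None,
    cost_params=None,
    horizon: float | None = None,
    xi: float = 0.72,
    bounds: tuple[float, float] = (0.0, 400.0),
    objective: str = "cost",
    n_coarse: int = 17,
    n_refine: int = 2,
    seed: int = 0,
) -> dict:
    """Treatment strength I0 minimising mean cost (or final heteroplasmy).

    Deterministic single-round objective over ``horizon`` days.  With the
    "cost" objective the mean bioenergetic state cost over the horizon is
    minimised (requires ``cost_params``; ``eps1`` overrides its pathology);
    with "final_h" the final heteroplasmy is minimised.  For nearly
    functional mutants (eps1 -> 1) treating is counterproductive and the
    optimum collapses to I0 = 0; for severely dysfunctional mutants the
    strongest allowed treatment wins.
    """
    from dataclasses import replace as _replace

    from .bioenergetics import SECONDS_PER_DAY, state_cost

    if horizon is None:
        horizon = 28.0
    if objective == "cost":
        if cost_params is None:
            raise ValueError("cost objective requires cost_params")
        if eps1 is not None:
            cost_params = _replace(cost_params, eps1=eps1)

    def run(I0):
        params = TreatmentParams(I0=float(I0), b=b, xi=xi, n_rounds=1,
                                 period=horizon)
        res = simulate_treatment(law, params, init, horizon,
                                 mode="deterministic", n_times=120)
        if objective == "final_h":
            hf = float(res.h[-1])
            # a protocol that wipes out the whole population is no cure
            return hf if math.isfinite(hf) else float("inf")
        costs = []
        for w, m in zip(res.w, res.m):
            lam_s = float(law.birth_rate(w, m)) / SECONDS_PER_DAY
            costs.append(state_cost(w, m, cost_params, lam_s,
                                    law.mu / SECONDS_PER_DAY))
        out = float(np.mean(costs))
        return out if math.isfinite(out) else float("inf")

    lo, hi = bounds
    best = None
    for _ in range(n_refine + 1):
        grid = np.linspace(lo, hi, n_coarse)
        vals = [run(g) for g in grid]
        k = int(np.argmin(vals))
        best = (float(grid[k]), float(vals[k]))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, n_coarse - 1)]
    return {"I0_opt": best[0], "objective": best[1],
            "bracket": (float(lo), float(hi))}
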