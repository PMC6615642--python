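"""Exact stochastic simulation of the controlled mtDNA birth-death process.

Each molecule replicates at the state-dependent per-capita rate lambda(w, m)
and degrades at constant rate mu, giving a Markov jump process with
propensities (w*lam, m*lam, w*mu, m*mu).  Trajectories are sampled with the
direct Gillespie method; ensembles are driven by a jitted kernel with
per-cell seeds spawned deterministically from a master seed via
``numpy.random.SeedSequence``.

Heteroplasmy summaries exclude extinct cells (w = m = 0); the excluded count
is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import ControlLaw, PopulationState

__all__ = ["StochasticTrajectory", "EnsembleSummary", "gillespie_trajectory",
           "ensemble_summary", "spawn_seeds"]


@dataclass
class StochasticTrajectory:
    times: np.ndarray
    w: np.ndarray
    m: np.ndarray
    seed: int
    absorbed: str = "none"  # none | wildtype-fixed | mutant-fixed | extinct

    @property
    def h(self) -> np.ndarray:
        n = self.w + self.m
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.m / np.maximum(n, 1), np.nan)


@dataclass
class EnsembleSummary:
    times: np.ndarray
    mean_w: np.ndarray
    var_w: np.ndarray
    mean_m: np.ndarray
    var_m: np.ndarray
    mean_h: np.ndarray          # over surviving (non-extinct) cells
    var_h: np.ndarray
    homogenate_h: np.ndarray
    frac_fixed_w: np.ndarray    # m = 0, w > 0
    frac_fixed_m: np.ndarray    # w = 0, m > 0
    frac_extinct: np.ndarray    # w = m = 0
    n_cells: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.times, "mean_w": self.mean_w, "var_w": self.var_w,
            "mean_m": self.mean_m, "var_m": self.var_m, "mean_h": self.mean_h,
            "var_h": self.var_h, "homog_h": self.homogenate_h,
            "fix_w": self.frac_fixed_w, "fix_m": self.frac_fixed_m,
            "extinct": self.frac_extinct,
        })


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-cell seeds: SeedSequence(master).generate_state(n)."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64)


def _absorbed_flag(w: int, m: int) -> str:
    if w == 0 and m == 0:
        return "extinct"
    if m == 0:
        return "wildtype-fixed"
    if w == 0:
        return "mutant-fixed"
    return "none"


def gillespie_trajectory(
    law: ControlLaw,
    init: PopulationState,
    horizon: float,
    seed: int,
    sample_times: np.ndarray | None = None,
    max_events: int = 10_000_000,
) -> StochasticTrajectory:
    """One statistically exact trajectory.

    With ``sample_times`` given, states are recorded at those times by the
    jitted kernel; otherwise the full event history is recorded by a NumPy
    reference implementation (kept independent of the kernel so the two can
    be cross-checked).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    w0, m0 = int(round(init.w)), int(round(init.m))

    if sample_times is not None:
        st = np.asarray(sample_times, dtype=np.float64)
        W, M = _kernels.ssa_sampled(law.kind_code(), law.param_array(),
                                    law.mu, w0, m0, st, seed)
        return StochasticTrajectory(st, W, M, seed, _absorbed_flag(W[-1], M[-1]))

    rng = np.random.default_rng(seed)
    w, m, t = w0, m0, 0.0
    ts, ws, ms = [0.0], [w], [m]
    for _ in range(max_events):
        n = w + m
        if n == 0:
            break
        lam = float(law.birth_rate(float(w), float(m)))
        a = n * (lam + law.mu)
        if a <= 0:
            break
        t += rng.exponential(1.0 / a)
        if t > horizon:
            break
        r = rng.random() * a
        if r < w * lam:
            w += 1
        elif r < n * lam:
            m += 1
        elif r < n * lam + w * law.mu:
            w -= 1
        else:
            m -= 1
        ts.append(t)
        ws.append(w)
        ms.append(m)
    return StochasticTrajectory(np.array(ts), np.array(ws), np.array(ms),
                                seed, _absorbed_flag(w, m))


def summarize_ensemble(times: np.ndarray, W: np.ndarray, M: np.ndarray) -> EnsembleSummary:
    """Per-time summary statistics of an ensemble of (cells x times) states."""
    N = W + M
    alive = N > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(alive, M / np.maximum(N, 1), np.nan)
    n_alive = alive.sum(axis=0)
    mean_h = np.nanmean(np.where(alive, h, np.nan), axis=0)
    var_h = np.nanvar(np.where(alive, h, np.nan), axis=0)
    return EnsembleSummary(
        times=times,
        mean_w=W.mean(axis=0), var_w=W.var(axis=0),
        mean_m=M.mean(axis=0), var_m=M.var(axis=0),
        mean_h=mean_h, var_h=var_h,
        homogenate_h=M.sum(axis=0) / np.maximum(N.sum(axis=0), 1),
        frac_fixed_w=((M == 0) & (W > 0)).mean(axis=0),
        frac_fixed_m=((W == 0) & (M > 0)).mean(axis=0),
        frac_extinct=(~alive).mean(axis=0),
        n_cells=W.shape[0],
    )


def ensemble_summary(
    law: ControlLaw,
    init: PopulationState,
    horizon: float,
    n_cells: int,
    seed: int,
    n_times: int = 50,
    sample_times: np.ndarray | None = None,
    return_states: bool = False,
):
    """Summary statistics over ``n_cells`` independent trajectories."""
    if n_cells < 2:
        raise ValueError("n_cells must be at least 2")
    if sample_times is None:
        sample_times = np.linspace(0.0, horizon, n_times)
    st = np.asarray(sample_times, dtype=np.float64)
    seeds = spawn_seeds(seed, n_cells)
    W, M = _kernels.ssa_ensemble(law.kind_code(), law.param_array(), law.mu,
                                 int(round(init.w)), int(round(init.m)), st, seeds)
    summary = summarize_ensemble(st, W, M)
    if return_states:
        return summary, W, M
    return summary
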