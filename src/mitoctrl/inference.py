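"""Bayesian fitting of the nuclease-treatment model.

Observables are heteroplasmy and *relative* total copy number (normalised to
the pre-treatment total) over a multi-round transfection schedule; the
observation model is additive Gaussian with separate variances:

    y_i(h) = h_model(t_i) + N(0, sigma_h^2)
    y_i(T) = T_model(t_i) + N(0, sigma_T^2)

with model predictions from the deterministic treatment ODEs.  Sampling is
plain Metropolis: componentwise-scaled Gaussian random walk in transformed
coordinates (log for positive parameters), scales tuned to a 20-40%
acceptance rate during a discarded adaptation phase and then frozen.

Parameters are (I0, b, c1, xi, delta, sigma_h2, sigma_T2).  The cellular
target population is tied to the initial state, w_opt = w0 + delta*m0, so
the pre-treatment data are stationary under the fitted control.  For fast
nuclease immigration decay (b >> mu_z) the pulse collapses to
(I0/(b - mu_z))*exp(-mu_z*t): only the ratio I0/(b - mu_z) is identified,
which is why posterior (I0, b) ridges appear and why recovery checks score
the ratio, not the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .dynamics import PopulationState
from .treatment import LN2, TreatmentParams

__all__ = ["MeasurementSeries", "NoiseModel", "PriorBox", "PosteriorResult",
           "predict_observables", "log_likelihood", "log_posterior",
           "metropolis_sample", "fit_map", "ml_selectivity", "credible_bands",
           "PARAM_NAMES"]

PARAM_NAMES = ("I0", "b", "c1", "xi", "delta", "sigma_h2", "sigma_T2")
#: indices of log-transformed components in the sampling space
_LOG_IDX = (0, 1, 2, 5, 6)


@dataclass(frozen=True)
class NoiseModel:
    sigma_h2: float = 0.061
    sigma_T2: float = 0.10

    def __post_init__(self):
        if self.sigma_h2 <= 0 or self.sigma_T2 <= 0:
            raise ValueError("noise variances must be positive")


@dataclass
class MeasurementSeries:
    """Timestamped noisy observations; ``kind`` is 'h' or 'T' per row."""

    times: np.ndarray
    values: np.ndarray
    kinds: np.ndarray  # array of 'h' / 'T' strings

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.kinds = np.asarray(self.kinds)
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if not set(np.unique(self.kinds)) <= {"h", "T"}:
            raise ValueError("kinds must be 'h' or 'T'")
        if np.any(self.values[self.kinds == "T"] <= 0):
            raise ValueError("relative copy numbers must be positive")

    def split(self):
        hm = self.kinds == "h"
        return (self.times[hm], self.values[hm],
                self.times[~hm], self.values[~hm])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "observable": self.kinds,
                             "value": self.values})

    @classmethod
    def from_frame(cls, df):
        return cls(df["t"].to_numpy(), df["value"].to_numpy(),
                   df["observable"].to_numpy())


def predict_observables(theta, times, design: TreatmentParams,
                        init: PopulationState, mu: float = 0.07):
    """Deterministic (h, rel_total) at the given times for (I0,b,c1,xi,delta).

    Returns None when the parameter point is dynamically invalid (e.g. the
    implied w_opt = w0 + delta*m0 is non-positive).
    """
    I0, b, c1, xi, delta = [float(v) for v in theta[:5]]
    w_opt = init.w + delta * init.m
    if w_opt <= 0 or c1 <= 0 or I0 < 0 or b <= 0 or xi < 0:
        return None
    p = np.array([c1, w_opt, delta, 0.0])
    ts = np.asarray(times, dtype=np.float64)
    order = np.argsort(ts)
    W, M = _kernels.treat_rk4(0, p, mu, xi, I0, b, design.mu_z,
                              design.period, design.n_rounds,
                              float(init.w), float(init.m),
                              ts[order], 2e-3, 1.5, 4e-2)
    Wo = np.empty_like(W)
    Mo = np.empty_like(M)
    Wo[order] = W
    Mo[order] = M
    tot = Wo + Mo
    if not np.all(np.isfinite(tot)) or np.any(tot <= 0):
        return None
    return Mo / tot, tot / (init.w + init.m)


def log_likelihood(theta, data: MeasurementSeries, design: TreatmentParams,
                   init: PopulationState, mu: float = 0.07) -> float:
    """Gaussian log likelihood of the data under parameter vector theta.

    ``theta`` = (I0, b, c1, xi, delta, sigma_h2, sigma_T2) on natural scale.
    Returns -inf for invalid parameter points or failed integrations.
    """
    sh2, sT2 = float(theta[5]), float(theta[6])
    if sh2 <= 0 or sT2 <= 0:
        return -np.inf
    pred = predict_observables(theta, data.times, design, init, mu)
    if pred is None:
        return -np.inf
    h_pred, T_pred = pred
    hm = data.kinds == "h"
    r_h = data.values[hm] - h_pred[hm]
    r_T = data.values[~hm] - T_pred[~hm]
    ll = (-0.5 * r_h.size * math.log(2 * math.pi * sh2)
          - 0.5 * np.sum(r_h ** 2) / sh2
          - 0.5 * r_T.size * math.log(2 * math.pi * sT2)
          - 0.5 * np.sum(r_T ** 2) / sT2)
    return float(ll)


@dataclass(frozen=True)
class PriorBox:
    """Independent priors: log-uniform for positive parameters (I0, b, c1,
    both noise variances) and uniform for xi and delta.  ``hi`` for b also
    regularises the fast-immigration degeneracy."""

    lo: np.ndarray = field(default_factory=lambda: np.array(
        [1e-2, 0.1, 1e-6, 0.0, -1.0, 1e-4, 1e-4]))
    hi: np.ndarray = field(default_factory=lambda: np.array(
        [1e4, 200.0, 1e-2, 2.0, 3.0, 1.0, 1.0]))

    def to_z(self, theta):
        z = np.array(theta, dtype=float)
        for i in _LOG_IDX:
            z[i] = math.log(z[i])
        return z

    def from_z(self, z):
        th = np.array(z, dtype=float)
        for i in _LOG_IDX:
            th[i] = math.exp(th[i])
        return th

    def log_prior_z(self, z) -> float:
        """Flat in z-space inside the box (log-uniform on natural scale for
        the log-transformed components)."""
        th = self.from_z(z)
        if np.all(th >= self.lo) and np.all(th <= self.hi):
            return 0.0
        return -np.inf


def log_posterior(z, data, design, init, prior: PriorBox, mu: float = 0.07):
    lp = prior.log_prior_z(z)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(prior.from_z(z), data, design, init, mu)


@dataclass
class PosteriorResult:
    chain: np.ndarray        # (n_steps, dim), natural scale
    log_post: np.ndarray
    acceptance_rate: float
    map_estimate: np.ndarray
    seed: int
    param_names: tuple = PARAM_NAMES

    def marginal(self, name: str) -> np.ndarray:
        return self.chain[:, self.param_names.index(name)]

    def identifiable_ratio(self, mu_z: float = LN2) -> np.ndarray:
        """Samples of I0/(b - mu_z), the identified pulse amplitude."""
        return self.marginal("I0") / (self.marginal("b") - mu_z)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.chain, columns=list(self.param_names))
        df["log_posterior"] = self.log_post
        return df


def metropolis_sample(log_post, start, n_steps: int, proposal_scales,
                      seed: int = 0, adapt_steps: int = 0,
                      target_acceptance: tuple = (0.2, 0.4),
                      adapt_covariance: bool = True,
                      transform=None) -> PosteriorResult:
    """Plain Metropolis with a symmetric Gaussian random-walk proposal.

    ``proposal_scales`` are per-component standard deviations (0 pins a
    component).  During the first ``adapt_steps`` (discarded) the proposal
    is tuned — the scale vector is multiplied up/down to land inside
    ``target_acceptance`` and, with ``adapt_covariance``, the second half of
    the phase re-shapes the proposal to the empirical covariance of the
    first half (scaled by 2.38^2/d) — then frozen, so the returned chain is
    a valid Metropolis chain.  ``transform`` maps a sampled point to natural
    scale for the stored chain (identity by default).  Deterministic under
    ``seed``; uphill moves always accepted.
    """
    rng = np.random.default_rng(seed)
    x = np.array(start, dtype=float)
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise ValueError("start point has non-finite log posterior")
    scales = np.array(proposal_scales, dtype=float)
    dim = x.size
    L = None  # frozen proposal shape (Cholesky factor); None = diagonal

    def sweep(n, scales, L, record=None, collect=None):
        nonlocal x, lp
        accepted = 0
        for i in range(n):
            step = rng.standard_normal(dim)
            prop = x + (scales * step if L is None else scales[0] * (L @ step))
            lp_prop = float(log_post(prop))
            if lp_prop >= lp or math.log(rng.random() + 1e-300) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
            if record is not None:
                record[0][i] = x
                record[1][i] = lp
            if collect is not None:
                collect.append(x.copy())
        return accepted / max(n, 1)

    def tune(n_total, scales, L, collect=None):
        block = max(n_total // 10, 20)
        done = 0
        while done < n_total:
            n = min(block, n_total - done)
            acc = sweep(n, scales, L, collect=collect)
            if acc < target_acceptance[0]:
                scales = scales * 0.7
            elif acc > target_acceptance[1]:
                scales = scales * 1.4
            done += n
        return scales

    if adapt_steps > 0:
        if adapt_covariance and np.all(np.asarray(proposal_scales) > 0):
            half = adapt_steps // 2
            samples: list = []
            scales = tune(half, scales, None, collect=samples)
            S = np.cov(np.array(samples).T) + 1e-12 * np.eye(dim)
            try:
                L = np.linalg.cholesky(2.38 ** 2 / dim * S)
                scales = np.ones(dim)
            except np.linalg.LinAlgError:
                L = None
            scales = tune(adapt_steps - half, scales, L)
        else:
            scales = tune(adapt_steps, scales, None)

    chain_z = np.empty((n_steps, dim))
    lps = np.empty(n_steps)
    acc_rate = sweep(n_steps, scales, L, record=(chain_z, lps))
    if acc_rate == 0.0 and np.any(scales > 0):
        import warnings

        warnings.warn("Metropolis chain accepted no proposals; "
                      "proposal scales are likely far too large")
    tf = transform if transform is not None else (lambda z: z)
    chain = np.array([tf(z) for z in chain_z])
    k = int(np.argmax(lps))
    return PosteriorResult(chain=chain, log_post=lps,
                           acceptance_rate=float(acc_rate),
                           map_estimate=chain[k], seed=seed)


def _default_scales():
    # z-space: ln I0, ln b, ln c1, xi, delta, ln sh2, ln sT2
    return np.array([0.15, 0.15, 0.08, 0.05, 0.05, 0.2, 0.2])


def sample_posterior(data: MeasurementSeries, design: TreatmentParams,
                     init: PopulationState, start=None,
                     prior: PriorBox | None = None, n_steps: int = 4000,
                     adapt_steps: int = 600, seed: int = 0,
                     mu: float = 0.07) -> PosteriorResult:
    """Convenience wrapper: Metropolis over the treatment model's parameters."""
    prior = prior or PriorBox()
    if start is None:
        start = np.array([100.0, 40.0, 2e-4, 0.7, 1.2,
                          max(np.var(data.values[data.kinds == "h"]), 1e-3),
                          max(np.var(data.values[data.kinds == "T"]), 1e-3)])
    z0 = prior.to_z(start)
    lp = lambda z: log_posterior(z, data, design, init, prior, mu)
    return metropolis_sample(lp, z0, n_steps, _default_scales(), seed=seed,
                             adapt_steps=adapt_steps, transform=prior.from_z)


def fit_map(data: MeasurementSeries, design: TreatmentParams,
            init: PopulationState, prior: PriorBox | None = None,
            n_steps: int = 800, seed: int = 0, mu: float = 0.07,
            mu_z: float = LN2) -> dict:
    """Maximum a posteriori fit: best sample of a short chain, refined by
    Nelder-Mead in the transformed space.

    Returns the MAP parameter dict plus the identifiable pulse amplitude
    I0/(b - mu_z); a flag marks optima pinned to the prior boundary (where
    only the amplitude, not (I0, b) separately, should be trusted).
    """
    from scipy.optimize import minimize

    prior = prior or PriorBox()
    post = sample_posterior(data, design, init, prior=prior, n_steps=n_steps,
                            adapt_steps=max(n_steps // 2, 200), seed=seed, mu=mu)
    z0 = prior.to_z(post.map_estimate)
    neg = lambda z: -log_posterior(z, data, design, init, prior, mu)
    res = minimize(neg, z0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    z_best = res.x if res.fun < neg(z0) else z0
    theta = prior.from_z(z_best)
    zlo, zhi = prior.to_z(prior.lo), prior.to_z(prior.hi)
    pinned = bool(np.any(np.abs(z_best - zlo) < 1e-3)
                  or np.any(np.abs(z_best - zhi) < 1e-3))
    out = dict(zip(PARAM_NAMES, (float(v) for v in theta)))
    out["amplitude"] = out["I0"] / (out["b"] - mu_z)
    out["log_posterior"] = float(-res.fun)
    out["boundary_pinned"] = pinned
    return out


def ml_selectivity(data: MeasurementSeries, fixed_params: dict,
                   design: TreatmentParams, init: PopulationState,
                   bounds=(0.0, 2.0), mu: float = 0.07) -> dict:
    """Maximum-likelihood selectivity xi with every other parameter fixed.

    Used for data taken under a different protocol (e.g. reduced nuclease
    concentration): the previously fitted parameters are held and only xi is
    re-estimated.  Returns the estimate and a near-flat-likelihood interval
    (points within 0.5 log units of the maximum on a dense grid).
    """
    from scipy.optimize import minimize_scalar

    def ll(xi):
        theta = np.array([fixed_params["I0"], fixed_params["b"],
                          fixed_params["c1"], xi, fixed_params["delta"],
                          fixed_params["sigma_h2"], fixed_params["sigma_T2"]])
        return log_likelihood(theta, data, design, init, mu)

    grid = np.linspace(bounds[0], bounds[1], 81)
    vals = np.array([ll(x) for x in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(lambda x: -ll(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5})
    xi_hat = float(res.x) if -res.fun >= vals[k] else float(grid[k])
    best = max(-res.fun, vals[k])
    flat = grid[vals > best - 0.5]
    return {"xi": xi_hat, "log_likelihood": float(best),
            "flat_interval": (float(flat.min()), float(flat.max()))}


def credible_bands(posterior: PosteriorResult, design: TreatmentParams,
                   init: PopulationState, times, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975),
                   max_draws: int = 300, mu: float = 0.07) -> dict:
    """Pointwise posterior-predictive quantiles of the deterministic model.

    Bands reflect parameter uncertainty only (model trajectories under
    posterior draws), matching a deterministic-prediction credible interval.
    """
    ts = np.asarray(times, dtype=float)
    n = posterior.chain.shape[0]
    if n == 0:
        raise ValueError("empty posterior chain")
    idx = np.unique(np.linspace(0, n - 1, min(max_draws, n)).astype(int))
    H = np.empty((idx.size, ts.size))
    T = np.empty((idx.size, ts.size))
    for row, i in enumerate(idx):
        pred = predict_observables(posterior.chain[i], ts, design, init, mu)
        if pred is None:
            H[row] = np.nan
            T[row] = np.nan
        else:
            H[row], T[row] = pred
    qs = np.asarray(quantiles)
    return {
        "times": ts,
        "quantiles": qs,
        "h": np.nanquantile(H, qs, axis=0),
        "rel_total": np.nanquantile(T, qs, axis=0),
        "h_mean": np.nanmean(H, axis=0),
        "rel_total_mean": np.nanmean(T, axis=0),
    }
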