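"""Synthetic stand-ins for the study's experimental inputs.

The laboratory measurements behind the treatment fits (heteroplasmy and
relative copy-number time courses over four 28-day mtZFN transfection /
recovery cycles in ~80%-heteroplasmy cybrid cells) are not machine-readable,
so every pipeline stage is exercised against generated data instead:

* noisy treatment time series from the deterministic treatment model plus
  Gaussian observation noise (the inference model's own error structure);
* initial heteroplasmy populations with controlled mean and variance (beta,
  or a two-spike mixture for extreme variances);
* nuclease expression profiles mimicking western-blot quantification
  (peak-normalised concentrations with multiplicative noise).

Defaults are the fitted operating point: treatment parameters at the MAP
vector (I0, b, c1, xi, delta) = (122.82, 46.68, 1.90e-4, 0.72, 1.26), noise
variances (0.061, 0.10), initial state (w, m) = (180, 720), four rounds 28
days apart.  All generators are pure functions of (design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import PopulationState
from .inference import MeasurementSeries, NoiseModel, predict_observables
from .treatment import LN2, TreatmentParams, zfn_concentration, zfn_peak

__all__ = ["MAP_PARAMS", "SyntheticDesign", "synth_treatment_measurements",
           "synth_heteroplasmy_population", "synth_expression_profile"]

#: fitted treatment operating point (I0, b, c1, xi, delta)
MAP_PARAMS = {"I0": 122.82, "b": 46.68, "c1": 1.90e-4, "xi": 0.72,
              "delta": 1.26, "sigma_h2": 0.061, "sigma_T2": 0.10}


@dataclass(frozen=True)
class SyntheticDesign:
    """True parameters + measurement schedule for a synthetic experiment."""

    I0: float = MAP_PARAMS["I0"]
    b: float = MAP_PARAMS["b"]
    c1: float = MAP_PARAMS["c1"]
    xi: float = MAP_PARAMS["xi"]
    delta: float = MAP_PARAMS["delta"]
    mu: float = 0.07
    mu_z: float = LN2
    init: PopulationState = field(default_factory=lambda: PopulationState(180.0, 720.0))
    n_rounds: int = 4
    period: float = 28.0
    #: measurement offsets within each round (days after transfection)
    times_per_round: tuple = (1.0, 3.0, 7.0, 14.0, 21.0, 28.0)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self):
        horizon = self.n_rounds * self.period
        for t in self.times_per_round:
            if not 0 <= t <= self.period:
                raise ValueError("per-round times must lie within one period")
        if max(self.measurement_times()) > horizon + 1e-9:
            raise ValueError("measurement times exceed the protocol horizon")

    def measurement_times(self) -> np.ndarray:
        return np.concatenate([
            j * self.period + np.asarray(self.times_per_round, dtype=float)
            for j in range(self.n_rounds)])

    def treatment_params(self) -> TreatmentParams:
        return TreatmentParams(I0=self.I0, b=self.b, xi=self.xi,
                               mu_z=self.mu_z, period=self.period,
                               n_rounds=self.n_rounds)

    def theta(self) -> np.ndarray:
        return np.array([self.I0, self.b, self.c1, self.xi, self.delta,
                         self.noise.sigma_h2, self.noise.sigma_T2])


def synth_treatment_measurements(design: SyntheticDesign,
                                 noise_free: bool = False) -> MeasurementSeries:
    """Noisy (h, relative total) series from the deterministic treatment model.

    Gaussian noise per observable; values are *not* clipped to [0, 1] — the
    Gaussian observation model permits out-of-range values and the
    likelihood handles them naturally.  Relative totals are resampled while
    non-positive (they enter the series contract as positive).
    """
    ts = design.measurement_times()
    pred = predict_observables(design.theta(), ts, design.treatment_params(),
                               design.init, design.mu)
    if pred is None:
        raise RuntimeError("synthetic design is dynamically invalid")
    h, T = pred
    if noise_free:
        times = np.concatenate([ts, ts])
        values = np.concatenate([h, T])
    else:
        rng = np.random.default_rng(design.seed)
        h_obs = h + math.sqrt(design.noise.sigma_h2) * rng.standard_normal(ts.size)
        T_obs = T + math.sqrt(design.noise.sigma_T2) * rng.standard_normal(ts.size)
        bad = T_obs <= 0
        while bad.any():
            T_obs[bad] = T[bad] + math.sqrt(design.noise.sigma_T2) * \
                rng.standard_normal(int(bad.sum()))
            bad = T_obs <= 0
        times = np.concatenate([ts, ts])
        values = np.concatenate([h_obs, T_obs])
    kinds = np.array(["h"] * ts.size + ["T"] * ts.size)
    return MeasurementSeries(times=times, values=values, kinds=kinds)


def synth_heteroplasmy_population(mean: float, variance: float, n_cells: int,
                                  family: str = "beta", seed: int = 0) -> np.ndarray:
    """Per-cell heteroplasmy sample with prescribed mean and variance.

    ``beta``: Beta(a, b) with moment-matched shape parameters.  ``two-spike``:
    a two-atom mixture — the most extreme h distribution at fixed (mean,
    variance), representing a tissue whose high mean is carried by a small
    fraction of near-homoplasmic cells.  Requires variance < mean*(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly inside (0, 1)")
    if variance < 0 or variance >= mean * (1.0 - mean):
        raise ValueError("variance must lie in [0, mean*(1-mean))")
    rng = np.random.default_rng(seed)
    if variance == 0:
        return np.full(n_cells, mean)
    if family == "beta":
        nu = mean * (1.0 - mean) / variance - 1.0
        a, b = mean * nu, (1.0 - mean) * nu
        return rng.beta(a, b, size=n_cells)
    if family == "two-spike":
        # atoms at x1 < mean < x2 with weight q at the upper atom; q chosen
        # so both atoms stay inside [0, 1]
        q = max(min(mean, 0.9), 0.1)
        for _ in range(60):
            x1 = mean - math.sqrt(variance * q / (1.0 - q))
            x2 = mean + math.sqrt(variance * (1.0 - q) / q)
            if 0.0 <= x1 and x2 <= 1.0:
                break
            q = q + 0.05 * (1 if x2 > 1.0 else -1)
        else:
            raise ValueError("no feasible two-spike mixture for this (mean, variance)")
        return np.where(rng.random(n_cells) < q, x2, x1)
    raise ValueError(f"unknown family {family!r}")


def synth_expression_profile(params: TreatmentParams, times,
                             noise_scale: float = 0.1, seed: int = 0) -> np.ndarray:
    """Peak-normalised nuclease concentrations with multiplicative noise.

    Mimics western-blot band quantification: intensities are proportional to
    concentration with an arbitrary constant, so the profile is scaled to a
    maximum of 1; log-normal multiplicative noise of scale ``noise_scale``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    _, peak = zfn_peak(params)
    rel = zfn_concentration(times, params) / peak
    if noise_scale == 0:
        return rel
    rng = np.random.default_rng(seed)
    return rel * rng.lognormal(mean=0.0, sigma=noise_scale, size=times.size)
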