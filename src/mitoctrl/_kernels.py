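"""Jitted hot loops: exact SSA for the controlled birth-death process,
time-inhomogeneous SSA for nuclease treatment (thinning), and a fixed-step
RK4 integrator for the deterministic treatment equations.

Control laws are passed as (kind, params) pairs — see the ``kind_code`` /
``param_array`` methods on :class:`mitoctrl.dynamics.ControlLaw`.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- birth rates


@njit(cache=True)
def birth_percap(kind, p, mu, w, m):
    """Per-capita replication rate lambda(w, m), clamped at zero."""
    if kind == 0:  # linear: p = (c1, w_opt, delta, -)
        lam = mu + p[0] * (p[1] - (w + p[2] * m))
    elif kind == 1:  # relaxed: p = (alpha_R, w_opt, eta, -)
        n = w + m
        if n <= 0.0:
            return 0.0
        x = w + p[2] * m
        lam = mu / n * (p[0] * (p[1] - x) + x)
    elif kind == 2:  # hyperbolic: p = (a, K, delta, n)
        x = w + p[2] * m
        if x < 0.0:
            x = 0.0
        lam = p[0] / (1.0 + (x / p[1]) ** p[3])
    else:  # exponential: p = (a, x0, delta, -)
        x = w + p[2] * m
        if x < 0.0:
            x = 0.0
        lam = p[0] * math.exp(-x / p[1])
    return lam if lam > 0.0 else 0.0


# ------------------------------------------------------------------ plain SSA


@njit(cache=True)
def ssa_sampled(kind, p, mu, w0, m0, sample_times, seed):
    """One exact trajectory, recorded at ``sample_times`` (sorted, >= 0)."""
    np.random.seed(seed)
    w = w0
    m = m0
    t = 0.0
    n_s = sample_times.shape[0]
    W = np.empty(n_s, np.int64)
    M = np.empty(n_s, np.int64)
    idx = 0
    while idx < n_s:
        n = w + m
        if n == 0:
            while idx < n_s:
                W[idx] = 0
                M[idx] = 0
                idx += 1
            break
        lam = birth_percap(kind, p, mu, float(w), float(m))
        a_tot = n * (lam + mu)
        if a_tot <= 0.0:
            while idx < n_s:
                W[idx] = w
                M[idx] = m
                idx += 1
            break
        t_next = t - math.log(np.random.random()) / a_tot
        while idx < n_s and sample_times[idx] < t_next:
            W[idx] = w
            M[idx] = m
            idx += 1
        t = t_next
        r = np.random.random() * a_tot
        if r < w * lam:
            w += 1
        elif r < n * lam:
            m += 1
        elif r < n * lam + w * mu:
            w -= 1
        else:
            m -= 1
    return W, M


@njit(cache=True)
def ssa_ensemble(kind, p, mu, w0, m0, sample_times, seeds):
    n_cells = seeds.shape[0]
    n_s = sample_times.shape[0]
    W = np.empty((n_cells, n_s), np.int64)
    M = np.empty((n_cells, n_s), np.int64)
    for i in range(n_cells):
        Wi, Mi = ssa_sampled(kind, p, mu, w0, m0, sample_times, seeds[i])
        W[i] = Wi
        M[i] = Mi
    return W, M


# --------------------------------------------------------- nuclease kinetics


@njit(cache=True)
def zfn_single(tau, I0, b, mu_z):
    """[ZFN](tau) for one transfection at tau = 0 (immigration-death model)."""
    if tau < 0.0:
        return 0.0
    d = mu_z - b
    if abs(d) < 1e-10 * mu_z:
        return I0 * tau * math.exp(-mu_z * tau)
    return I0 / d * (math.exp(-b * tau) - math.exp(-mu_z * tau))


@njit(cache=True)
def zfn_peak_time(b, mu_z):
    if abs(b - mu_z) < 1e-10 * mu_z:
        return 1.0 / mu_z
    return math.log(b / mu_z) / (b - mu_z)


@njit(cache=True)
def zfn_sum(t, I0, b, mu_z, period, n_rounds):
    """Summed concentration from all transfections at times 0, period, 2*period, ..."""
    s = 0.0
    for j in range(n_rounds):
        tau = t - j * period
        if tau >= 0.0:
            s += zfn_single(tau, I0, b, mu_z)
    return s


@njit(cache=True)
def _zfn_sum_max(t0, t1, I0, b, mu_z, period, n_rounds):
    """Upper bound on the summed concentration over [t0, t1].

    Each round's pulse is unimodal, so its max over the window is attained at
    an endpoint or at the pulse peak if that lies inside.  Assumes no new
    transfection occurs strictly inside (t0, t1].
    """
    tpk = zfn_peak_time(b, mu_z)
    s = 0.0
    for j in range(n_rounds):
        tj = j * period
        if tj > t1:
            break
        a = zfn_single(t0 - tj, I0, b, mu_z)
        c = zfn_single(t1 - tj, I0, b, mu_z)
        hi = a if a > c else c
        if t0 - tj <= tpk <= t1 - tj:
            pk = zfn_single(tpk, I0, b, mu_z)
            if pk > hi:
                hi = pk
        s += hi
    return s


# ------------------------------------------------------ treatment simulation


@njit(cache=True)
def treat_ssa(kind, p, mu, xi, I0, b, mu_z, period, n_rounds,
              w0, m0, sample_times, seed):
    """Exact time-inhomogeneous SSA for treatment via thinning.

    Death rates are mu + xi*Z(t) (wildtype) and mu + Z(t) (mutant), with Z
    the summed nuclease concentration.  The rejection envelope on each
    lookahead window uses the per-round unimodal pulse bound.
    """
    np.random.seed(seed)
    w = w0
    m = m0
    t = 0.0
    n_s = sample_times.shape[0]
    horizon = sample_times[n_s - 1]
    W = np.empty(n_s, np.int64)
    M = np.empty(n_s, np.int64)
    idx = 0
    window = 0.25  # days; envelope lookahead
    while idx < n_s:
        n = w + m
        if n == 0:
            while idx < n_s:
                W[idx] = 0
                M[idx] = 0
                idx += 1
            break
        # cap the window at the next transfection so Z stays unimodal per round
        t_end = t + window
        for j in range(1, n_rounds):
            tj = j * period
            if t < tj < t_end:
                t_end = tj
                break
        if t_end > horizon + 1e-9:
            t_end = horizon + 1e-9
        lam = birth_percap(kind, p, mu, float(w), float(m))
        z_hi = _zfn_sum_max(t, t_end, I0, b, mu_z, period, n_rounds)
        a_max = n * (lam + mu) + (xi * w + m) * z_hi
        if a_max <= 0.0:
            t_next = t_end
        else:
            t_next = t - math.log(np.random.random()) / a_max
        if t_next >= t_end:
            # no event in this window
            while idx < n_s and sample_times[idx] < t_end:
                W[idx] = w
                M[idx] = m
                idx += 1
            t = t_end
            continue
        z = zfn_sum(t_next, I0, b, mu_z, period, n_rounds)
        a_true = n * (lam + mu) + (xi * w + m) * z
        if np.random.random() * a_max > a_true:
            t = t_next  # thinned: no event
            continue
        while idx < n_s and sample_times[idx] < t_next:
            W[idx] = w
            M[idx] = m
            idx += 1
        t = t_next
        r = np.random.random() * a_true
        if r < w * lam:
            w += 1
        elif r < n * lam:
            m += 1
        elif r < n * lam + w * (mu + xi * z):
            w -= 1
        else:
            m -= 1
    return W, M


@njit(cache=True)
def treat_ssa_ensemble(kind, p, mu, xi, I0, b, mu_z, period, n_rounds,
                       w0s, m0s, sample_times, seeds):
    n_cells = seeds.shape[0]
    n_s = sample_times.shape[0]
    W = np.empty((n_cells, n_s), np.int64)
    M = np.empty((n_cells, n_s), np.int64)
    for i in range(n_cells):
        Wi, Mi = treat_ssa(kind, p, mu, xi, I0, b, mu_z, period, n_rounds,
                           w0s[i], m0s[i], sample_times, seeds[i])
        W[i] = Wi
        M[i] = Mi
    return W, M


# ------------------------------------------- deterministic treatment (RK4)


@njit(cache=True)
def _treat_rhs(kind, p, mu, xi, z, w, m):
    lam = birth_percap(kind, p, mu, w, m)
    dw = w * (lam - mu - xi * z)
    dm = m * (lam - mu - z)
    return dw, dm


@njit(cache=True)
def treat_rk4(kind, p, mu, xi, I0, b, mu_z, period, n_rounds,
              w0, m0, t_out, h_fine, t_fine, h_coarse):
    """Fixed-step RK4 for dw/dt = w[lam-mu-xi*Z(t)], dm/dt = m[lam-mu-Z(t)].

    Uses a fine step for ``t_fine`` days after each transfection (the nuclease
    pulse is fast, timescale 1/b) and a coarse step otherwise.  Output states
    are recorded by stepping exactly onto each requested time.
    """
    w = w0
    m = m0
    t = 0.0
    n_s = t_out.shape[0]
    W = np.empty(n_s, np.float64)
    M = np.empty(n_s, np.float64)
    idx = 0
    while idx < n_s:
        if t_out[idx] <= t + 1e-12:
            W[idx] = w
            M[idx] = m
            idx += 1
            continue
        # step size regime based on time since the most recent transfection
        phase = t - period * math.floor(t / period)
        j = int(math.floor(t / period))
        if j >= n_rounds:
            phase = t - (n_rounds - 1) * period
        h = h_fine if phase < t_fine else h_coarse
        # do not step across a transfection or a requested output time
        nxt = t_out[idx]
        for k in range(1, n_rounds):
            tk = k * period
            if t < tk < nxt:
                nxt = tk
                break
        if t + h > nxt:
            h = nxt - t
        z1 = zfn_sum(t, I0, b, mu_z, period, n_rounds)
        z2 = zfn_sum(t + 0.5 * h, I0, b, mu_z, period, n_rounds)
        z4 = zfn_sum(t + h, I0, b, mu_z, period, n_rounds)
        k1w, k1m = _treat_rhs(kind, p, mu, xi, z1, w, m)
        k2w, k2m = _treat_rhs(kind, p, mu, xi, z2, w + 0.5 * h * k1w, m + 0.5 * h * k1m)
        k3w, k3m = _treat_rhs(kind, p, mu, xi, z2, w + 0.5 * h * k2w, m + 0.5 * h * k2m)
        k4w, k4m = _treat_rhs(kind, p, mu, xi, z4, w + h * k3w, m + h * k3m)
        w += h / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        m += h / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        if w < 0.0:
            w = 0.0
        if m < 0.0:
            m = 0.0
        t += h
    return W, M
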