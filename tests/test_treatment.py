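"""Nuclease pharmacokinetics, selective-degradation dynamics, population
treatment, and protocol optimisation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mitoctrl.dynamics import LinearLaw, PopulationState, steady_state_for_h
from mitoctrl.treatment import (TreatmentParams, excess_death_rates,
                                heteroplasmy_transfer_map,
                                optimize_treatment_strength,
                                simulate_treatment, summed_concentration,
                                treat_cell_population, zfn_concentration,
                                zfn_peak)


class TestNucleaseKinetics:
    def test_zero_at_transfection(self, map_treatment):
        assert zfn_concentration(0.0, map_treatment) == 0.0

    def test_peak_location_matches_dense_evaluation(self, map_treatment):
        t_star, z_star = zfn_peak(map_treatment)
        ts = np.linspace(0, 2, 20001)
        zs = zfn_concentration(ts, map_treatment)
        assert ts[np.argmax(zs)] == pytest.approx(t_star, abs=1e-3)
        assert zs.max() == pytest.approx(z_star, rel=1e-6)

    def test_removable_singularity_at_equal_rates(self):
        mu_z = np.log(2)
        exact = TreatmentParams(I0=10.0, b=mu_z, xi=0.5)
        near = TreatmentParams(I0=10.0, b=mu_z * (1 + 1e-7), xi=0.5)
        ts = np.linspace(0.01, 5, 50)
        assert np.allclose(zfn_concentration(ts, exact),
                           zfn_concentration(ts, near), rtol=1e-4)
        # the limit form is I0 * t * exp(-mu_z t)
        assert zfn_concentration(1.0, exact) == pytest.approx(
            10.0 * np.exp(-mu_z), rel=1e-9)

    def test_five_percent_decay_time(self, map_treatment):
        """Fitted short treatment: concentration first drops below 5% of its
        peak about 4.4 days post-transfection."""
        from scipy.optimize import brentq

        t_star, z_star = zfn_peak(map_treatment)
        t5 = brentq(lambda t: zfn_concentration(t, map_treatment) - 0.05 * z_star,
                    t_star, 28.0)
        assert t5 == pytest.approx(4.43, abs=0.05)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TreatmentParams(I0=-1.0, b=1.0, xi=0.5)
        with pytest.raises(ValueError):
            TreatmentParams(I0=1.0, b=1.0, xi=0.5, n_rounds=0)


class TestExcessDeathRates:
    def test_zero_before_first_transfection_decays_after(self, map_treatment):
        ew, em = excess_death_rates(0.0, map_treatment)
        assert ew == 0.0 and em == 0.0

    def test_selectivity_relations(self):
        t = np.linspace(0.1, 50, 40)
        p0 = TreatmentParams(I0=50.0, b=10.0, xi=0.0, n_rounds=2)
        ew, em = excess_death_rates(t, p0)
        assert np.all(ew == 0.0) and np.all(em > 0)
        p1 = TreatmentParams(I0=50.0, b=10.0, xi=1.0, n_rounds=2)
        ew, em = excess_death_rates(t, p1)
        assert np.allclose(ew, em)

    def test_rounds_accumulate(self):
        p = TreatmentParams(I0=50.0, b=2.0, xi=0.5, period=28.0, n_rounds=4)
        z1 = summed_concentration(28.0 + 1.0, p)
        single = TreatmentParams(I0=50.0, b=2.0, xi=0.5, n_rounds=1)
        assert z1 == pytest.approx(zfn_concentration(1.0, single)
                                   + zfn_concentration(29.0, single), rel=1e-9)


class TestSimulateTreatment:
    def test_no_treatment_is_untreated_dynamics(self, map_law):
        from mitoctrl.dynamics import deterministic_trajectory

        params = TreatmentParams(I0=0.0, b=46.68, xi=0.72, n_rounds=1)
        init = PopulationState(400.0, 300.0)
        res = simulate_treatment(map_law, params, init, 28.0, n_times=50)
        t, w, m = deterministic_trajectory(map_law, init, 28.0, n_eval=50)
        assert np.allclose(res.w, w, rtol=1e-5, atol=1e-3)
        assert np.allclose(res.m, m, rtol=1e-5, atol=1e-3)

    def test_indiscriminate_cleavage_preserves_h(self, map_law, map_init):
        """xi = 1: both species share per-capita rates, so h never moves."""
        params = TreatmentParams(I0=122.82, b=46.68, xi=1.0, n_rounds=2)
        res = simulate_treatment(map_law, params, map_init, 56.0, n_times=200)
        assert np.nanmax(np.abs(res.h - map_init.h)) < 1e-7

    def test_map_trough_and_recovery(self, map_law, map_treatment, map_init):
        """Fitted parameters: copy number collapses to <10% within days and
        recovers under feedback; heteroplasmy steps down each round."""
        res = simulate_treatment(map_law, map_treatment, map_init,
                                 n_times=3000)
        first = res.times <= 28.0
        tot = res.rel_total
        t_min = res.times[first][np.argmin(tot[first])]
        assert 3.0 <= t_min <= 4.5
        assert tot[first].min() < 0.12
        assert np.all(np.diff(res.per_round_h) < 0)
        assert res.per_round_rel_total[-1] > 0.8

    def test_rk4_matches_reference_integrator(self, map_law, map_treatment,
                                              map_init):
        """Jitted fixed-step RK4 against an adaptive library integrator."""
        res = simulate_treatment(map_law, map_treatment, map_init, n_times=57)

        def rhs(t, y):
            z = summed_concentration(t, map_treatment)
            g = map_law.birth_rate(y[0], y[1]) - map_law.mu
            return [y[0] * (g - map_treatment.xi * z), y[1] * (g - z)]

        sol = solve_ivp(rhs, (0, 112), [map_init.w, map_init.m],
                        t_eval=res.times, rtol=1e-10, atol=1e-10,
                        method="LSODA")
        assert np.allclose(res.w, sol.y[0], rtol=1e-5, atol=1e-4)
        assert np.allclose(res.m, sol.y[1], rtol=1e-5, atol=1e-4)

    def test_stochastic_mean_matches_ode(self, map_law, map_init):
        """Time-inhomogeneous SSA agrees with the deterministic solution
        at moderate copy numbers (thinning is exact)."""
        params = TreatmentParams(I0=60.0, b=46.68, xi=0.72, n_rounds=1)
        det = simulate_treatment(map_law, params, map_init, 28.0, n_times=8)
        n = 400
        W = np.empty((n, 8))
        M = np.empty((n, 8))
        for i in range(n):
            r = simulate_treatment(map_law, params, map_init, 28.0,
                                   mode="stochastic", seed=1000 + i, n_times=8)
            W[i], M[i] = r.w, r.m
        for arr, ref in ((W, det.w), (M, det.m)):
            se = arr.std(axis=0) / np.sqrt(n)
            assert np.all(np.abs(arr.mean(axis=0) - ref) < 4 * se + 1.5)

    def test_stochastic_determinism(self, map_law, map_treatment, map_init):
        a = simulate_treatment(map_law, map_treatment, map_init,
                               mode="stochastic", seed=5, n_times=20)
        b = simulate_treatment(map_law, map_treatment, map_init,
                               mode="stochastic", seed=5, n_times=20)
        assert np.array_equal(a.w, b.w) and np.array_equal(a.m, b.m)


class TestTransferMap:
    def test_endpoints_fixed(self, map_law, map_treatment):
        hf = heteroplasmy_transfer_map(np.array([0.0, 1.0]), map_treatment,
                                       map_law)
        assert hf[0] == 0.0 and hf[1] == 1.0

    def test_shift_maximal_at_intermediate_h(self, map_law, map_treatment):
        hg = np.linspace(0, 1, 11)
        hf = heteroplasmy_transfer_map(hg, map_treatment, map_law)
        shift = hg - hf
        k = int(np.argmax(shift))
        assert 0.3 <= hg[k] <= 0.8
        assert np.all(shift >= -1e-9)

    def test_stochastic_can_raise_h_near_indiscriminate(self, map_law):
        """At high h and xi near 1, drift can leave a cell *more* mutant
        after treatment than before."""
        params = TreatmentParams(I0=122.82, b=46.68, xi=0.95, n_rounds=1)
        from mitoctrl import _kernels
        from mitoctrl.stochastic import spawn_seeds

        h0, n_reps = 0.9, 300
        ss = steady_state_for_h(map_law, h0)
        w0, m0 = int(round(ss.w)), int(round(ss.m))
        st = np.array([28.0])
        W, M = _kernels.treat_ssa_ensemble(
            map_law.kind_code(), map_law.param_array(), map_law.mu,
            params.xi, params.I0, params.b, params.mu_z, 28.0, 1,
            np.full(n_reps, w0, np.int64), np.full(n_reps, m0, np.int64),
            st, spawn_seeds(77, n_reps))
        tot = (W + M)[:, 0]
        hf = M[tot > 0, 0] / tot[tot > 0]
        assert np.mean(hf > h0) > 0.05


class TestPopulationTreatment:
    def test_degenerate_population_matches_single_cell_map(self, map_law,
                                                           map_treatment):
        hs = np.full(120, 0.6)
        out = treat_cell_population(hs, map_treatment, map_law, seed=3)
        from dataclasses import replace

        one = replace(map_treatment, n_rounds=1)
        hf = heteroplasmy_transfer_map(np.array([0.6]), one, map_law,
                                       mode="stochastic", n_reps=120, seed=9)
        assert out.per_round_mean_h[0] == pytest.approx(hf[0], abs=0.05)

    def test_efficacy_decreases_with_variance(self, map_law, map_treatment):
        from mitoctrl.synthetic import synth_heteroplasmy_population

        finals = []
        for var, family in ((0.004, "beta"), (0.04, "beta"),
                            (0.10, "two-spike")):
            hs = synth_heteroplasmy_population(0.8, var, 150, family=family,
                                               seed=5)
            out = treat_cell_population(hs, map_treatment, map_law, seed=9)
            finals.append(out.per_round_mean_h[-1])
        assert finals[0] < finals[1] < finals[2]

    def test_threshold_probability_decreases_each_round(self, map_law,
                                                        map_treatment):
        from mitoctrl.synthetic import synth_heteroplasmy_population

        hs = synth_heteroplasmy_population(0.8, 0.02, 200, seed=2)
        out = treat_cell_population(hs, map_treatment, map_law, seed=4)
        assert np.all(np.diff(out.per_round_p_above) <= 1e-9)

    def test_rejects_invalid_h(self, map_law, map_treatment):
        with pytest.raises(ValueError):
            treat_cell_population(np.array([0.5, 1.2]), map_treatment, map_law)


class TestProtocolChoice:
    def test_long_weak_beats_short_strong(self, map_law, map_init):
        """Matched horizon: the best slow-release protocol ends at a lower
        heteroplasmy than the best fast-pulse protocol."""
        best = {}
        for label, b in (("short", 46.68), ("long", 0.2)):
            r = optimize_treatment_strength(map_law, map_init, b=b, xi=0.72,
                                            horizon=28.0, objective="final_h",
                                            bounds=(0, 400))
            best[label] = r["objective"]
        assert best["long"] <= best["short"]

    def test_extinction_risk_monotone_in_strength(self):
        """Stochastic mode: stronger pulses wipe out more small cells."""
        from mitoctrl import _kernels
        from mitoctrl.stochastic import spawn_seeds

        law = LinearLaw(mu=0.07, c1=1.4e-2, w_opt=50.0, delta=1.0)
        st = np.array([28.0])
        extinct = []
        for I0 in (40.0, 120.0, 360.0):
            W, M = _kernels.treat_ssa_ensemble(
                law.kind_code(), law.param_array(), law.mu, 0.72, I0, 46.68,
                np.log(2), 28.0, 1, np.full(300, 10, np.int64),
                np.full(300, 40, np.int64), st, spawn_seeds(11, 300))
            extinct.append(np.mean((W + M)[:, 0] == 0))
        assert extinct[0] <= extinct[1] <= extinct[2]
        assert extinct[2] > extinct[0]

    def test_optimal_strength_vs_mutant_functionality(self, map_init):
        """Strongest treatment for the least functional mutants; treating
        nearly functional mutants is not worth the collateral damage."""
        from mitoctrl.bioenergetics import (default_cost_params,
                                            optimal_copy_number)

        cost = default_cost_params()
        w_opt = optimal_copy_number(cost)
        law = LinearLaw(mu=0.07, c1=7e-4, w_opt=w_opt, delta=1.0)
        init = steady_state_for_h(law, 0.8)
        opts = []
        for eps1 in (0.05, 0.35, 0.7, 0.95):
            r = optimize_treatment_strength(law, init, b=46.68, eps1=eps1,
                                            cost_params=cost, horizon=56.0,
                                            objective="cost", bounds=(0, 400),
                                            n_coarse=9, n_refine=1)
            opts.append(r["I0_opt"])
        assert all(a >= b - 1e-9 for a, b in zip(opts, opts[1:]))
        assert opts[0] > 100.0
        assert opts[-1] == pytest.approx(0.0, abs=1e-9)
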