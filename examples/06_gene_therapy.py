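"""Simulating mtZFN gene therapy at the fitted operating point.

Four transfection/recovery rounds with the fitted parameters
(I0, b, c1, xi, delta) = (122.82, 46.68, 1.9e-4, 0.72, 1.26) on an
80%-heteroplasmy cell, then the population-level message: heteroplasmy
variance, not just the mean, decides whether a tissue is treatable.
"""
import numpy as np

from mitoctrl import (LinearLaw, PopulationState, TreatmentParams,
                      simulate_treatment, synth_heteroplasmy_population,
                      treat_cell_population, zfn_peak)
from mitoctrl.synthetic import MAP_PARAMS

law = LinearLaw(mu=0.07, c1=MAP_PARAMS["c1"],
                w_opt=180 + MAP_PARAMS["delta"] * 720,
                delta=MAP_PARAMS["delta"])
tp = TreatmentParams(I0=MAP_PARAMS["I0"], b=MAP_PARAMS["b"],
                     xi=MAP_PARAMS["xi"], n_rounds=4)
t_star, z_star = zfn_peak(tp)
print(f"nuclease pulse: peak {z_star:.2f}/day at t = {t_star:.2f} d; "
      f"xi = {tp.xi} (wildtypes cleaved per mutant)")

res = simulate_treatment(law, tp, PopulationState(180, 720), n_times=3000)
first = res.times <= 28
t_min = res.times[first][np.argmin(res.rel_total[first])]
print(f"single cell, deterministic: copy number bottoms at "
      f"{res.rel_total[first].min() * 100:.0f}% of baseline, "
      f"{t_min:.1f} d after transfection")
print("per-round post-recovery heteroplasmy: "
      + ", ".join(f"{h:.2f}" for h in res.per_round_h))

print("\npopulation treatment, mean h = 0.8 with increasing variance:")
for var, family in ((0.004, "beta"), (0.04, "beta"), (0.10, "two-spike")):
    hs = synth_heteroplasmy_population(0.8, var, 150, family=family, seed=5)
    out = treat_cell_population(hs, tp, law, seed=9)
    print(f"  Var(h) = {var:5.3f}: mean h after 4 rounds = "
          f"{out.per_round_mean_h[-1]:.2f}, P(h > 0.6) = "
          f"{out.per_round_p_above[-1]:.2f}")
print("High-variance tissues hide near-homoplasmic cells at both extremes, "
      "which nuclease rounds barely move - the same mean responds far "
      "worse when carried by a minority of extreme cells.")
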