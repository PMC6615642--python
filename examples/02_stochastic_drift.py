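"""Stochastic drift of heteroplasmy under feedback control.

Simulates an ensemble of cells exactly (Gillespie) and shows the key
population-genetic facts: the cellular mean heteroplasmy is conserved, but
the tissue homogenate drifts towards m0/(m0 + delta*w0) when mutants are
weakly sensed, without any replicative advantage.
"""
import numpy as np

from mitoctrl import LinearLaw, PopulationState, ensemble_summary

law = LinearLaw(mu=0.07, c1=0.07 / 20.0, w_opt=20.0, delta=0.2)
init = PopulationState(15, 15)
summ = ensemble_summary(law, init, 750.0, n_cells=2000, seed=1, n_times=6)

predicted = init.m / (init.m + law.delta * init.w)
print("t (days)   mean cellular h   homogenate h   fixed-w   fixed-m")
for i, t in enumerate(summ.times):
    print(f"{t:8.0f}   {summ.mean_h[i]:15.3f}   {summ.homogenate_h[i]:12.3f}"
          f"   {summ.frac_fixed_w[i]:7.2f}   {summ.frac_fixed_m[i]:7.2f}")
print(f"\nlong-time homogenate prediction m0/(m0 + delta*w0) = {predicted:.3f}")
print("The cellular mean stays at 0.5 while the homogenate climbs: "
      "mutant-fixed cells settle at higher copy number (w_opt/delta), so "
      "pooled tissue DNA over-represents them - apparent selection with "
      "identical per-molecule rates.")
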