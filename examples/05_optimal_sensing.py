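"""How strongly should a cell sense its mutants?

Calibrates the linear and relaxed-replication controls to identical
mutant-free behaviour (c1 = mu*alpha_R/w_opt) and finds the mutant-sensing
weight delta that minimises the steady-state bioenergetic cost, as a
function of mutant functionality eps1.
"""
import numpy as np

from mitoctrl import (OptimisationSpec, calibrate_c1, default_cost_params,
                      optimal_copy_number, optimize_sensing)

print(f"calibration: alpha_R = 10, mu = 0.07/d, w_opt = 1000 -> "
      f"c1 = {calibrate_c1(10.0, 0.07, 1000.0):.1e} /molecule/day "
      f"(equal mutant-free variance w_opt/alpha_R = mu/c1 = 100)\n")

print("optimal mutant sensing delta_opt (steady-state objective, "
      "h0 in [0, 0.2]):")
for eps1 in (1.0, 0.7, 0.4, 0.15):
    cost = default_cost_params(eps1=eps1)
    spec = OptimisationSpec(cost=cost, horizon=None,
                            variance_correction=False,
                            h0_grid=np.linspace(0, 0.2, 10))
    res = optimize_sensing("linear", spec, w_opt=optimal_copy_number(cost))
    print(f"  eps1 = {eps1:4.2f}: delta_opt = {res['optimum']:6.3f}")
print("\nFully functional mutants should be counted like wildtypes "
      "(delta ~ 1 = copy-number control); the less output a mutant "
      "contributes, the less it should register in the feedback signal - "
      "exactly what sensing energy output instead of genomes achieves.")
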