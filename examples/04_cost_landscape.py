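"""The bioenergetic cost of mtDNA states.

Evaluates C(w,m) = |D - S| + alpha*(w*r_w + m*r_m) under the saturating
output model: demand-matched resource allocation, spare capacity at the
optimum, the heteroplasmy threshold, and the most-expensive intermediate
heteroplasmy h_max.
"""
import numpy as np

from mitoctrl import (cost_landscape, default_cost_params, h_max_at_total,
                      optimal_copy_number, solve_resource_rate, state_cost)

p = default_cost_params(eps1=0.3)
n_opt = optimal_copy_number(p)
sol = solve_resource_rate(n_opt, 0, p)
print(f"mutant-free optimum: N = {n_opt:.0f} mitochondria, each consuming "
      f"r_w = {sol.r_w:.2f} (of r_max = {p.r_max}) -> spare capacity "
      f"{100 * (1 - sol.r_w / p.r_max):.0f}%")

grid = np.linspace(20, 2000, 50)
ls = cost_landscape(p, grid, grid)
W, M = np.meshgrid(ls.w_grid, ls.m_grid)
H = M / (W + M)
print(f"heteroplasmy threshold on the grid: demand satisfiable only below "
      f"h = {H[ls.demand_ok].max():.2f} (eps1 = {p.eps1})")

print("\nmost expensive heteroplasmy at fixed total copy number "
      f"(N = {1.5 * n_opt:.0f}):")
for eps1 in (0.2, 0.5, 0.7, 0.9):
    pe = default_cost_params(eps1=eps1)
    print(f"  eps1 = {eps1}: h_max = {h_max_at_total(pe, 1.5 * n_opt):.2f}")
print("Severely impaired mutants (low eps1) make mutant homoplasmy the "
      "worst state; moderately impaired ones are most costly at an "
      "intermediate mix, because they consume less resource than they fail "
      "to produce.")
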