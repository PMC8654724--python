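"""Negative-diffusion instability at low cell density.

40 cells on [0, 47]: the flanks sit between the force-support edge
(rho = 0.667) and the stability threshold (rho = 0.901), where the
coarse-grained diffusion coefficient is negative.  The particle model
relaxes to a smooth two-level state; the PDE amplifies perturbations into
persistent oscillations that survive in the stationary solution — while
conserving mass exactly.
"""

import numpy as np

import tissuemech as tm

preset = tm.preset_low_density_1d()
micro, macro, grid = tm.run_micro_macro_1d(preset, save_every=1000)

print(f"domain [0, 47], {preset.ic.N} cells, dt = {preset.dt:g}, t up to {preset.T}")
m0, m1 = tm.total_mass(macro[0]), tm.total_mass(macro[-1])
print(f"PDE mass drift over the run: {abs(m1 - m0) / m0:.2e}\n")

pos, rho_micro = tm.density_field(micro[-1])
micro_grid = tm.micro_to_grid(pos, rho_micro, grid)

print(" element   x      rho (PDE)   rho (micro)")
for i, x in enumerate(grid.centers(0)):
    print(f"   {i:2d}   {x:6.2f}    {macro[-1].rho[i]:7.3f}     {micro_grid.rho[i]:7.3f}")

low = macro[0].rho < 0.901
print(f"\nelements starting below the 0.901 threshold: {np.nonzero(low)[0].tolist()}")
print("the PDE column alternates between ~0.45 and ~1.0 exactly there — the")
print("printed oscillation of the ill-posed regime; the micro column is smooth.")
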