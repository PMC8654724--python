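"""Coarse-grained pressure and diffusion coefficient of the center-based model.

The 1D pressure law p(V) = -V g(V)/mu induces the diffusion coefficient
rho dp/drho in the density-transport PDE.  For a force with an attraction
cutoff the coefficient changes sign at low density: the PDE is unstable
below that density and the force support ends where cells stop touching.
"""

import numpy as np

import tissuemech as tm

force = tm.ExpForceParams()  # mu=50, s=1, c=10, r_A=1.5
law = tm.CBMPressureLaw(force, d=1, mu=50.0)

rho_unstable, rho_vanish = tm.stability_thresholds(law)
print(f"force support ends below       rho = {rho_vanish:.3f}  (= 1/r_A)")
print(f"diffusion negative below       rho = {rho_unstable:.3f}")
print("between the two the PDE amplifies perturbations; above 0.901 it diffuses\n")

print(" rho      p(rho)     rho*dp/drho")
for rho in np.arange(0.6, 1.61, 0.1):
    p = law.pressure_of_rho(rho)
    D = rho * tm.dpdrho(rho, law)
    print(f" {rho:4.2f}  {p:+10.5f}  {D:+12.5f}")
print("\np = 0 at the equilibrium density rho = 1 (cell spacing = rest length s);")
print("the diffusion coefficient is what a linearised transport equation sees.")
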