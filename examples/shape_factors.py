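"""Regular-shape coarse-graining factors xi_d(J).

On the continuum level only the cell volume V = 1/rho is known; assuming
cells are regular J-gons (2D) or J-hedra (3D) recovers the inradius as
r = xi_d(J) V^(1/d).  These factors set every constant in the macroscopic
pressure laws.
"""

import tissuemech as tm

print("2D polygons:  xi_2(J) = (J tan(pi/J))^(-1/2)")
for J, name in [(3, "triangle"), (4, "square"), (5, "pentagon"), (6, "hexagon")]:
    print(f"  J={J:<2d} {name:<9s} xi_2 = {tm.xi_factor(2, J):.4f}")
print(f"  circle limit       xi_2 = {tm.xi_factor(2, tm.CIRCLE_LIMIT):.4f}")

print("\n3D polyhedra (Platonic closed forms):")
for J, name in [(4, "tetrahedron"), (6, "cube"), (8, "octahedron"), (12, "dodecahedron")]:
    print(f"  J={J:<2d} {name:<12s} xi_3 = {tm.xi_factor(3, J):.4f}")
print(f"  sphere limit          xi_3 = {tm.xi_factor(3, tm.CIRCLE_LIMIT):.4f}")

# The 2D pressure law p = -(J xi_2/2) V^(1/2) g(2 xi_2 V^(1/2)) at J=5:
xi = tm.xi_factor(2, 5)
print(f"\n2D pressure coefficients at J=5: leading {5 * xi / 2:.2f}, "
      f"force argument scaling {2 * xi:.2f}")
print("(these are the constants multiplying V^(1/2) and inside g in the "
      "coarse-grained center-based pressure)")
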