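# Methods

## Scope and model summary

`tissuemech` couples two levels of description of a mechanically interacting
cell population:

- **Discrete (micro):** N cells, each a Voronoi region of its center in a
  rectangular domain. Overdamped dynamics (`velocity = force / η`; inertia
  neglected, η = 1 by default and kept explicit). Center-based forces act
  along center–center directions; vertex-based forces act on Voronoi
  vertices of the 2D polygon mesh.
- **Continuum (macro):** the cell density ρ = 1/V transported by
  ∂ρ/∂t = μ∇·(ρ∇p) with a constitutive pressure p(ρ) derived from the micro
  forces, solved by a conservative finite-volume method (FVM) on equidistant
  1D / Cartesian 2D grids with zero-flux boundaries.

The derivation views the micro model as an FVM discretization of the macro
equation on the Voronoi mesh itself; matching the two velocity expressions
interface by interface yields the discrete pressure
`p_ij = −V_i g(r_ij)/(μ a_ij)` for the CBM, and the analogous vertex-mesh
identification for the VBM. Cell geometry unavailable on the macro level
(inradius r, perimeter a, interface a_ij) is closed by the regular-shape
factor ξ_d(J):

    r = ξ_d(J) V^(1/d),  V/a_ij = (J/d) ξ_d(J) V^(1/d),  a = (d/ξ_d) V^((d−1)/d)

with ξ₁ = 1/2, ξ₂(J) = (J tan(π/J))^(−1/2), and ξ₃ from the Platonic solids.

## Parameters that matter

| symbol | meaning | unit | default | rationale |
| --- | --- | --- | --- | --- |
| μ, s, c, r_A | exponential CBM force: strength, rest distance, adhesion decay, cutoff | v/L, L, 1/L, L | 50, 1, 10, 1.5 | the standard parameter set used throughout the experiments |
| ς, κ | WO area / perimeter force coefficients | — | 1, 1 (ς = 50 in the 1D chain) | only their ratio matters; scaling rescales time |
| J | assumed neighbor count in ξ_d | — | 2 (1D), 6 (2D), 12 (3D) | forced in 1D; dense hexagonal packing in 2D; kissing number in 3D. J = 5 (2D) and J = 10 (3D, via interpolation or user override of ξ₃) reproduce the printed d = 2, 3 pressure coefficients |
| η | viscosity | — | 1 | absorbed into force parameters by convention, kept explicit |
| Δt | forward-Euler step | t | preset per experiment (1.25e−4 … 1e−3) | explicit diffusion stability; a conservative dt estimate is reported in the run manifest but not enforced |

## Numerical choices

- **Bounded Voronoi regions:** every center is reflected across each domain
  face before tessellating (scipy Voronoi), so the regions of the original
  points are finite and exactly clipped by the rectangle; the cell areas
  partition the domain to 1e−10 relative. Double (corner) reflections are
  provably unnecessary inside a rectangle. For speed, only points within an
  adaptive buffer (4 mean spacings) of a face are reflected; the partition
  identity is verified and full mirroring is the automatic fallback.
- **CBM neighbor sums** run over all pairs within the cutoff r_A (KD-tree
  query), not only Voronoi neighbors — for dense packings the two agree.
- **Vertex pairing:** at an interior 3-valent vertex, the edge toward β is
  weighted by the cell *opposite* that edge (area term) and the two cells
  *flanking* it (perimeter terms). One shared helper encodes this for both
  WO and NH, which makes the first-order WO↔NH correspondence
  (λ r_edge = ς/V₀², κ = 2β, γ = 0) hold by construction; the test suite
  verifies the quadratic decay of the response difference.
- **g′ at the exponential cutoff:** the force is discontinuous at r_A as
  printed (no smoothing); derivatives use the interior branch at exactly
  r = r_A.
- **Stability thresholds:** ρ_vanish = (2ξ_d)^d / r_A^d in closed form;
  ρ_unstable from bracketing + Brent on g(r) + r g′(r) over (s, r_A) in the
  scaled coordinate r = 2ξ_d V^(1/d) (tolerance 1e−12). The second,
  very-high-density sign change in the repulsive regime is exposed as a
  separate diagnostic.
- **FVM:** interface density ½(ρ_i + ρ_j), element-center pressures, no
  upwinding or limiting — in the negative-diffusion regime the scheme is
  *supposed* to oscillate, and the package reproduces rather than suppresses
  that. ρ = 0 elements take p = 0; a step producing negative density raises
  an error (no clipping). Total mass is conserved to round-off by the
  generic scheme and the 1D CBM scheme. The 1D WO scheme uses the
  element-dependent discrete pressure p_j = V_i f(V_j)/μ as printed; its
  face terms cancel only to O(ΔV²), so its mass is conserved approximately,
  not exactly — this is a property of the scheme itself, not of the
  implementation.
- **Micro integration:** forward Euler; CBM re-tessellates every step by
  default (configurable; the tessellation dominates cost). The VBM state is
  the polygon mesh itself after initialization — no re-Voronoi, no T1/T2
  topological transitions; runs stop with an error on imminent edge collapse
  (below 1e−6 of the initial mean edge). 1D centers that would reorder or
  collide abort the step with a suggestion to reduce dt.
- **Frozen boundaries:** CBM cells whose Voronoi region touches the domain
  boundary, all boundary vertices (VBM), and the two end vertices (1D WO
  chain) are held fixed, so micro mass is conserved and matches the macro
  Neumann condition.

## Synthetic initial conditions (the stated world)

- **1D:** a base density plus a C¹ cosine bump (center, half-width,
  amplitude, peak or depletion). N and the profile jointly overdetermine the
  total mass, so the profile is rescaled uniformly to integrate to exactly N;
  centers sit at half-integer cumulative mass (cells carry unit mass), which
  makes the tessellated ρ_i track the profile within ~2% away from the
  clipped end cells. Presets: 40 cells on [0, 37] (peak over equilibrium,
  stable regime), 40 cells on [0, 47] (flanks inside the unstable band
  0.667 < ρ < 0.901), 39-cell WO chain on [0.5, 36.5] with ς = 50.
- **2D:** a triangular lattice with spacing h chosen for outer density
  ρ₀ = 2/(√3 h²) = 1.15 on [0, 40]² (≈ 1794 cells, within 5% of the
  published 1777, whose exact construction is not recoverable). The central
  disturbance is a radial transport map sending radius r to m(r) defined by
  cumulative-mass matching against a target profile: a cos² density bump
  (factor 1.65 over radius 3) compensated by a shallow annulus out to radius
  11.5 solved for **mass neutrality**. This keeps the disturbance strictly
  local: the map is the identity beyond the annulus, the central densities
  fall inside the published band [1.11, 1.97], and — crucially — the
  comparison region [8, 32]² holds the same mass in the micro and macro
  runs, which is what makes their region averages comparable at late times
  (a non-neutral disturbance lets the particle model leak the excess across
  the region boundary while the Neumann PDE cannot; measured discrepancy
  then grows to ~2%).

What the generators do **not** emulate: cell division and death, stochastic
motility, topological rearrangements, curved or growing domains, and the
pixel content of any published figure. A green paired-experiment test
establishes regime-level agreement (monotone decay, oscillation structure,
region averages), not trajectory-level equivalence.

## Known limitations

- The VBM is 2D only (3D vertex models are out of scope); 3D enters only
  through ξ₃ and the scalar shape relations. ξ₃ for non-Platonic J is an
  interpolation in 1/J (opt-in) or a user override — no regular 10-faced
  polyhedron exists.
- Long VBM runs without topological transitions eventually stop at an edge
  collapse; this is by design.
- The unstable PDE regime can drive a density negative for large time
  steps; the solver halts rather than regularizing.
- The WO 1D scheme's small mass defect (above) is inherited from its
  printed form.
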