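"""Paired micro/macro experiments: initial conditions, interpolation, metrics.

The experiment designs follow the published comparisons: a 1D cell chain
with a smooth density perturbation relaxing under CBM forces (stable,
diffusive regime), the same chain at low density where the coarse-grained
diffusion coefficient is negative (the PDE oscillates, the particle model
does not), a 1D Weliky-Oster chain (positive diffusion), and a 2D hexagonal
cell sheet with a radial central disturbance.  Each preset pairs the micro
model on domain A with the finite-volume PDE on domain B, initialised by
interpolating the micro density onto the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

from .fvm import DensityField, Grid, build_grid, fvm_step_cbm_1d, fvm_step_wo_1d, run_macro
from .forces import ExpForceParams
from .geometry import CellCenters, Domain, tessellate_2d
from .microsim import SimConfig, cbm_state, density_field, run, wo1d_state
from .pressure import CBMPressureLaw

__all__ = [
    "ICSpec1D",
    "ICSpec2D",
    "ic_1d",
    "ic_1d_vertices",
    "ic_2d_hex",
    "micro_to_grid",
    "line_profile",
    "compare",
    "preset_peak_relaxation_1d",
    "preset_low_density_1d",
    "preset_wo_relaxation_1d",
    "preset_hex_disturbance_2d",
    "run_micro_macro_1d",
    "run_micro_macro_2d",
]


@dataclass(frozen=True)
class ICSpec1D:
    """Smoothly perturbed 1D chain: density base + cosine bump.

    The bump is the C^1 profile amp/2 (1 + cos(pi (x-center)/width)) on
    |x - center| < width.  The requested profile is rescaled uniformly so it
    integrates to exactly N cells over the domain (N and the profile jointly
    overdetermine the mass otherwise).
    """

    N: int
    domain: Domain
    base_density: float = 1.0
    bump_center: float = 0.0
    bump_width: float = 1.0
    bump_amplitude: float = 0.0
    sign: str = "peak"  # or "depletion"

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need at least 2 cells")
        if self.domain.d != 1:
            raise ValueError("1D spec requires a 1D domain")
        if self.base_density <= 0 or self.bump_width <= 0 or self.bump_amplitude < 0:
            raise ValueError("base_density, bump_width > 0 and bump_amplitude >= 0")
        if self.sign not in ("peak", "depletion"):
            raise ValueError("sign must be 'peak' or 'depletion'")

    def profile(self, x: np.ndarray) -> np.ndarray:
        s = 1.0 if self.sign == "peak" else -1.0
        u = (np.asarray(x) - self.bump_center) / self.bump_width
        bump = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
        return self.base_density + s * self.bump_amplitude * bump


@dataclass(frozen=True)
class ICSpec2D:
    """Hexagonal 2D lattice with a radial central disturbance.

    Lattice spacing h sets the outer density 2/(sqrt(3) h^2); inside
    ``disturbance_radius`` of ``disturbance_center`` a smooth radial inward
    map raises the density by up to ``density_factor`` at the center, with
    an optional mass-neutralising depletion annulus out to
    ``compensation_radius``.
    """

    domain: Domain
    h: float
    disturbance_center: tuple[float, float] | None = None
    disturbance_radius: float = 0.0
    density_factor: float = 1.0
    compensation_radius: float | None = None
    jitter: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.domain.d != 2:
            raise ValueError("2D spec requires a 2D domain")
        if self.h <= 0:
            raise ValueError("lattice spacing h must be positive")
        if self.density_factor < 1.0:
            raise ValueError("density_factor must be >= 1")
        if self.disturbance_radius < 0 or self.jitter < 0:
            raise ValueError("radius and jitter must be non-negative")
        if (self.compensation_radius is not None
                and self.compensation_radius <= self.disturbance_radius):
            raise ValueError("compensation_radius must exceed disturbance_radius")


def _inverse_cdf_positions(spec: ICSpec1D, masses: np.ndarray) -> np.ndarray:
    lo, hi = spec.domain.lower[0], spec.domain.upper[0]
    xg = np.linspace(lo, hi, 8193)
    rho = spec.profile(xg)
    if np.any(rho <= 0):
        raise ValueError("density profile is non-positive somewhere in the domain")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (rho[1:] + rho[:-1]) * np.diff(xg))])
    scale = spec.N / cum[-1]  # rescale profile mass to exactly N cells
    return np.interp(masses, cum * scale, xg)


def ic_1d(spec: ICSpec1D) -> CellCenters:
    """Centers whose tessellated density tracks the requested profile.

    Cell i is placed at the (i - 1/2)-th unit of cumulative mass, so its
    Voronoi interval carries unit mass and rho_i = 1/V_i follows the profile
    (within ~2% away from the clipped end cells).  Endpoints are frozen.
    """
    x = _inverse_cdf_positions(spec, np.arange(spec.N) + 0.5)
    if np.any(np.diff(x) <= 0):
        raise ValueError("profile forces non-positive cell spacings")
    mask = np.zeros(spec.N, dtype=bool)
    mask[0] = mask[-1] = True
    return CellCenters(x, mask)


def ic_1d_vertices(spec: ICSpec1D) -> np.ndarray:
    """Interval boundaries for the 1D vertex chain: N cells, N+1 vertices.

    Vertex k sits at cumulative mass k, so cell k holds unit mass and its
    width is 1/rho at the cell location.
    """
    return _inverse_cdf_positions(spec, np.arange(spec.N + 1, dtype=float))


def ic_2d_hex(spec: ICSpec2D) -> CellCenters:
    """Triangular-lattice centers with a radial central disturbance.

    Points are moved inward by a radial transport map so the density follows
    a smooth target profile: a cos^2 bump (factor F over the disturbance
    radius), optionally balanced by a shallow compensating annulus out to
    ``compensation_radius`` that makes the disturbance mass-neutral and
    strictly local.  Cells whose Voronoi region touches the domain boundary
    are flagged frozen.
    """
    dom = spec.domain
    h = spec.h
    dy = math.sqrt(3.0) / 2.0 * h
    lo = np.asarray(dom.lower)
    ext = dom.extents
    ny = int(ext[1] / dy - 0.5)
    nx = int(ext[0] / h - 1.0)
    pts = []
    for j in range(ny + 1):
        y = lo[1] + (j + 0.5) * dy
        off = 0.25 * h if j % 2 == 0 else 0.75 * h
        xs = lo[0] + off + np.arange(nx + 1) * h
        xs = xs[xs < dom.upper[0] - 1e-9]
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    pts = np.vstack(pts)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.rng_seed)
        pts = pts + rng.normal(scale=spec.jitter * h, size=pts.shape)

    if spec.density_factor > 1.0 and spec.disturbance_radius > 0:
        center = np.asarray(
            spec.disturbance_center
            if spec.disturbance_center is not None
            else lo + 0.5 * ext
        )
        rel = pts - center
        r = np.hypot(rel[:, 0], rel[:, 1])
        # Radial transport map: move each point from radius r to m(r) so the
        # lattice density rho0 becomes the target radial profile
        #   rho(u)/rho0 = 1 + (F-1) cos^2(pi u / 2R)           for u < R
        #                 1 - D sin^2(pi (u-R) / (R2-R))       for R <= u < R2
        # (C^1 bump + compensating shallow annulus).  D is solved so the
        # disturbance is mass-neutral: the map is the identity beyond R2 and
        # the disturbance stays local.  Without a compensation radius the
        # inward displacement instead decays like 1/r (non-local, draws mass
        # from the whole sheet).
        R = spec.disturbance_radius
        R2 = spec.compensation_radius
        F = spec.density_factor
        rmax = float(r.max()) + 1.0
        ug = np.linspace(0.0, rmax, 8193)
        core = (F - 1.0) * np.where(ug < R, np.cos(np.pi * ug / (2 * R)) ** 2, 0.0)
        if R2 is not None:
            ann_shape = np.where(
                (ug >= R) & (ug < R2), np.sin(np.pi * (ug - R) / (R2 - R)) ** 2, 0.0
            )
            I_core = np.trapezoid(core * ug, ug)
            I_ann = np.trapezoid(ann_shape * ug, ug)
            D = I_core / I_ann
            if D >= 1.0:
                raise ValueError(
                    "compensation annulus too small for the requested density factor"
                )
            prof = 1.0 + core - D * ann_shape
        else:
            prof = 1.0 + core
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (prof[1:] * ug[1:] + prof[:-1] * ug[:-1]) * np.diff(ug)
        )])
        m = np.interp(0.5 * r**2, cum, ug)
        scale = np.ones_like(r)
        nz = r > 0
        scale[nz] = m[nz] / r[nz]
        pts = center + rel * scale[:, None]

    tree = cKDTree(pts)
    dmin = tree.query(pts, k=2)[0][:, 1].min()
    if dmin < 1e-3 * h:
        raise ValueError("compression causes center collisions; weaken the disturbance")

    centers = CellCenters(pts)
    tess, _ = tessellate_2d(centers, dom)
    return CellCenters(pts, tess.boundary)


# ---------------------------------------------------------------------------
# micro -> grid interpolation and comparison


def micro_to_grid(positions: np.ndarray, rho: np.ndarray, grid: Grid) -> DensityField:
    """Piecewise-linear interpolation of per-cell densities onto grid centers.

    1D: linear between neighboring cells (constant beyond the outermost
    samples).  2D: linear on the Delaunay triangulation of the sample
    positions with nearest-sample fallback outside the convex hull.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise ValueError("no density samples given")
    rho = np.asarray(rho, dtype=float)
    if grid.d == 1:
        x = positions[:, 0] if positions.shape[1] == 1 else positions.ravel()
        order = np.argsort(x)
        vals = np.interp(grid.centers(0), x[order], rho[order])
        return DensityField(grid, vals)
    xc, yc = np.meshgrid(grid.centers(0), grid.centers(1), indexing="ij")
    q = np.column_stack([xc.ravel(), yc.ravel()])
    vals = LinearNDInterpolator(positions, rho)(q)
    nan = np.isnan(vals)
    if np.any(nan):
        vals[nan] = NearestNDInterpolator(positions, rho)(q[nan])
    return DensityField(grid, vals.reshape(grid.shape))


def line_profile(f: DensityField, y: float) -> tuple[np.ndarray, np.ndarray]:
    """Row of element-center values nearest the given y (2D fields)."""
    if f.grid.d != 2:
        raise ValueError("line_profile requires a 2D field")
    dom = f.grid.domain
    if not dom.lower[1] <= y <= dom.upper[1]:
        raise ValueError(f"y={y} outside the domain [{dom.lower[1]}, {dom.upper[1]}]")
    j = int(np.argmin(np.abs(f.grid.centers(1) - y)))
    return f.grid.centers(0), f.rho[:, j]


def compare(micro_positions: np.ndarray, micro_rho: np.ndarray,
            macro: DensityField, region: Domain | None = None) -> dict:
    """L-infinity / L2 discrepancies and mass difference over a region.

    The micro samples are interpolated to the macro element centers inside
    the region; L2 is the element-volume-weighted norm.  Symmetric in the
    two inputs for the norms.
    """
    grid = macro.grid
    if region is None:
        region = grid.domain
    if grid.d == 1:
        centers = grid.centers(0)[:, None]
    else:
        xc, yc = np.meshgrid(grid.centers(0), grid.centers(1), indexing="ij")
        centers = np.column_stack([xc.ravel(), yc.ravel()])
    inside = region.contains(centers)
    if not np.any(inside):
        raise ValueError("region does not overlap the macro grid")
    micro_on_grid = micro_to_grid(micro_positions, micro_rho, grid)
    diff = (macro.rho.ravel() - micro_on_grid.rho.ravel())[inside]
    omega = grid.omega
    return {
        "linf": float(np.max(np.abs(diff))),
        "l2": float(np.sqrt(np.sum(omega * diff**2))),
        "mass_difference": float(np.sum(omega * diff)),
        "n_elements": int(inside.sum()),
    }


# ---------------------------------------------------------------------------
# experiment presets (parameters as printed in the source experiments)


@dataclass(frozen=True)
class Preset1D:
    kind: str  # 'cbm' or 'wo'
    ic: ICSpec1D
    dt: float
    T: float
    dx: float
    force: ExpForceParams | None = None
    sigma: float | None = None
    grid_domain: Domain | None = None


@dataclass(frozen=True)
class Preset2D:
    ic: ICSpec2D
    dt: float
    T: float
    dx: float
    force: ExpForceParams = field(default_factory=ExpForceParams)
    J: float = 6.0
    grid_domain: Domain | None = None


def preset_peak_relaxation_1d() -> Preset1D:
    """40-cell chain on [0, 37] with a central density peak, stable regime."""
    dom = Domain((0.0,), (37.0,))
    ic = ICSpec1D(N=40, domain=dom, base_density=1.0, bump_center=18.5,
                  bump_width=8.0, bump_amplitude=0.3)
    return Preset1D(kind="cbm", ic=ic, dt=1.25e-4, T=0.1, dx=1.95,
                    force=ExpForceParams())


def preset_low_density_1d() -> Preset1D:
    """40-cell chain on [0, 47]: low density flanks inside the unstable band."""
    dom = Domain((0.0,), (47.0,))
    ic = ICSpec1D(N=40, domain=dom, base_density=0.8, bump_center=23.5,
                  bump_width=8.0, bump_amplitude=0.5)
    return Preset1D(kind="cbm", ic=ic, dt=1e-3, T=3.0, dx=2.50,
                    force=ExpForceParams())


def preset_wo_relaxation_1d() -> Preset1D:
    """39-cell Weliky-Oster chain on [0.5, 36.5], positive diffusion."""
    dom = Domain((0.5,), (36.5,))
    ic = ICSpec1D(N=39, domain=dom, base_density=1.0, bump_center=18.5,
                  bump_width=8.0, bump_amplitude=0.3)
    return Preset1D(kind="wo", ic=ic, dt=4e-4, T=0.4, dx=1.90, sigma=50.0)


def preset_hex_disturbance_2d() -> Preset2D:
    """Hexagonal sheet on [0, 40]^2 (outer density 1.15, ~1780 cells) with a
    radial central disturbance; PDE solved on the interior [8, 32]^2."""
    dom = Domain((0.0, 0.0), (40.0, 40.0))
    h = math.sqrt(2.0 / (math.sqrt(3.0) * 1.15))
    ic = ICSpec2D(domain=dom, h=h, disturbance_radius=3.0, density_factor=1.65,
                  compensation_radius=11.5)
    return Preset2D(ic=ic, dt=2.5e-4, T=0.45, dx=1.263,
                    grid_domain=Domain((8.0, 8.0), (32.0, 32.0)))


# ---------------------------------------------------------------------------
# paired drivers


def run_micro_macro_1d(preset: Preset1D, save_every: int | None = None,
                       retessellate_every: int = 1):
    """Run the micro model and the paired 1D PDE from the same initial density.

    Returns (micro_traj, macro_traj, grid).  The PDE is initialised by
    interpolating the initial micro density onto the grid and advanced by
    the scheme matching the micro model (CBM flux-difference scheme or the
    1D WO scheme).
    """
    dom = preset.grid_domain or preset.ic.domain
    grid = build_grid(dom, preset.dx)
    n_steps = int(round(preset.T / preset.dt))
    if save_every is None:
        save_every = max(1, n_steps // 10)
    cfg = SimConfig(dt=preset.dt, T=preset.T, save_every=save_every,
                    retessellate_every=retessellate_every)

    if preset.kind == "cbm":
        state = cbm_state(ic_1d(preset.ic), preset.ic.domain)
        micro_traj = run(state, cfg, preset.force)
        pos0, rho0 = density_field(micro_traj[0])
        f0 = micro_to_grid(pos0, rho0, grid)
        macro_traj, _ = run_macro(f0, None, preset.dt, preset.T,
                                  save_every=save_every,
                                  stepper=fvm_step_cbm_1d, force=preset.force)
    elif preset.kind == "wo":
        state = wo1d_state(ic_1d_vertices(preset.ic), preset.ic.domain)
        micro_traj = run(state, cfg, None, sigma=preset.sigma)
        pos0, rho0 = density_field(micro_traj[0])
        f0 = micro_to_grid(pos0, rho0, grid)
        macro_traj, _ = run_macro(f0, None, preset.dt, preset.T,
                                  save_every=save_every,
                                  stepper=fvm_step_wo_1d, sigma=preset.sigma)
    else:
        raise ValueError(f"unknown preset kind {preset.kind!r}")
    return micro_traj, macro_traj, grid


def run_micro_macro_2d(preset: Preset2D, save_every: int | None = None):
    """Run the 2D CBM sheet and the paired PDE on the interior grid.

    Returns a dict with the trajectories, the grid, and the region-averaged
    densities of both solutions at the final time (micro average is
    area-weighted over cells whose centers lie in the grid domain).
    """
    gdom = preset.grid_domain or preset.ic.domain
    grid = build_grid(gdom, preset.dx)
    n_steps = int(round(preset.T / preset.dt))
    if save_every is None:
        save_every = max(1, n_steps // 5)
    cfg = SimConfig(dt=preset.dt, T=preset.T, save_every=save_every)

    state = cbm_state(ic_2d_hex(preset.ic), preset.ic.domain)
    micro_traj = run(state, cfg, preset.force)

    pos0, rho0 = density_field(micro_traj[0])
    f0 = micro_to_grid(pos0, rho0, grid)
    law = CBMPressureLaw(preset.force, d=2, J=preset.J, mu=1.0)
    macro_traj, manifest = run_macro(f0, law, preset.dt, preset.T,
                                     save_every=save_every)

    pos1, rho1 = density_field(micro_traj[-1])
    inside = gdom.contains(pos1)
    V1 = 1.0 / rho1[inside]
    micro_avg = float(inside.sum() / V1.sum())  # area-weighted mean density
    macro_avg = float(np.mean(macro_traj[-1].rho))
    return {
        "micro_traj": micro_traj,
        "macro_traj": macro_traj,
        "grid": grid,
        "micro_avg": micro_avg,
        "macro_avg": macro_avg,
        "manifest": manifest,
    }
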