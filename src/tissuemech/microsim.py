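"""Time integration of the discrete cell models (forward Euler, overdamped).

Three micro models are supported:

- ``cbm``: cell centers in 1D/2D advected by pairwise forces; the Voronoi
  tessellation (re-derived per step or batch) supplies cell volumes and
  densities rho_i = 1/V_i.
- ``vbm``: a 2D polygon mesh whose vertices are advected by Weliky-Oster or
  Nagai-Honda forces.  The polygon mesh itself is the state after
  initialization from a Voronoi diagram; no re-tessellation and no
  topological (T1/T2) transitions — runs stop on imminent edge collapse.
- ``wo1d``: the 1D Weliky-Oster chain: cells are intervals, the shared
  interval boundaries move with velocity sigma (rho_left - rho_right).

Cells (cbm) whose Voronoi region touches the domain boundary and boundary
vertices (vbm/wo1d) are frozen, which keeps the total mass in the domain
constant and mirrors the Neumann condition of the macro solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forces import WOParams, cbm_velocities, nh_vertex_velocity, wo_vertex_velocity
from .geometry import (
    CellCenters,
    Domain,
    Tessellation,
    VertexMesh,
    tessellate_1d,
    tessellate_2d,
)

__all__ = [
    "MicroState",
    "SimConfig",
    "cbm_state",
    "vbm_state",
    "wo1d_state",
    "step_cbm",
    "step_vbm",
    "step_wo_1d",
    "run",
    "density_field",
    "gcl_volume_update",
    "polygon_geometry",
]


@dataclass
class CellGeometry:
    """Areas and perimeters of a polygon mesh (duck-typed Tessellation slice)."""

    volumes: np.ndarray
    perimeters: np.ndarray


def polygon_geometry(coords: np.ndarray, polygons: list[list[int]]) -> CellGeometry:
    """Shoelace areas and perimeters of polygons given by ordered vertex ids."""
    vols = np.empty(len(polygons))
    pers = np.empty(len(polygons))
    for k, poly in enumerate(polygons):
        p = coords[poly]
        x, y = p[:, 0], p[:, 1]
        vols[k] = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        e = np.roll(p, -1, axis=0) - p
        pers[k] = np.hypot(e[:, 0], e[:, 1]).sum()
    return CellGeometry(volumes=vols, perimeters=pers)


@dataclass
class MicroState:
    """Snapshot of a micro model at time t.

    kind 'cbm': ``centers`` and ``tess`` are set.
    kind 'vbm': ``mesh``, ``polygons`` (per-cell ordered vertex ids) and the
        derived ``geometry`` are set; ``centers`` holds the initial seeds
        (for reference only).
    kind 'wo1d': ``vertices`` (sorted 1D boundary positions) and the derived
        cell intervals; cell i spans [vertices[i], vertices[i+1]].
    """

    kind: str
    domain: Domain
    t: float = 0.0
    centers: CellCenters | None = None
    tess: Tessellation | None = None
    mesh: VertexMesh | None = None
    polygons: list[list[int]] | None = None
    geometry: CellGeometry | None = None
    frozen_vertices: np.ndarray | None = None
    vertices: np.ndarray | None = None
    initial_mean_edge: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Forward-Euler run configuration."""

    dt: float
    T: float
    retessellate_every: int = 1
    save_every: int = 1
    rng_seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.retessellate_every < 1 or self.save_every < 1:
            raise ValueError("strides must be >= 1")


# ---------------------------------------------------------------------------
# state constructors


def cbm_state(centers: CellCenters, domain: Domain, freeze_boundary: bool = True) -> MicroState:
    """CBM state with a fresh tessellation; boundary cells are flagged frozen."""
    tess = (tessellate_1d(centers, domain) if domain.d == 1
            else tessellate_2d(centers, domain, build_mesh=False)[0])
    mask = centers.boundary_mask.copy()
    if freeze_boundary:
        mask |= tess.boundary
    c = CellCenters(centers.coords.copy(), mask)
    return MicroState(kind="cbm", domain=domain, centers=c, tess=tess)


def vbm_state(centers: CellCenters, domain: Domain) -> MicroState:
    """VBM state initialised from the Voronoi diagram of the given centers."""
    if domain.d != 2:
        raise ValueError("the vertex model is 2D")
    tess, mesh = tessellate_2d(centers, domain)
    geom = polygon_geometry(mesh.vertex_coords, tess.cell_polygons)
    edges = [
        np.linalg.norm(mesh.vertex_coords[b] - mesh.vertex_coords[a])
        for a in range(mesh.n_vertices)
        for b in mesh.vertex_adjacency[a]
        if a < b
    ]
    return MicroState(
        kind="vbm", domain=domain, centers=centers, mesh=mesh,
        polygons=tess.cell_polygons, geometry=geom,
        frozen_vertices=mesh.is_boundary.copy(),
        initial_mean_edge=float(np.mean(edges)),
    )


def wo1d_state(vertices: np.ndarray, domain: Domain) -> MicroState:
    """1D WO chain from sorted interval boundaries (first/last frozen)."""
    v = np.sort(np.asarray(vertices, dtype=float))
    if len(v) < 3:
        raise ValueError("need at least 3 vertices (2 cells)")
    if np.any(np.diff(v) <= 0):
        raise ValueError("vertices must be strictly increasing")
    frozen = np.zeros(len(v), dtype=bool)
    frozen[0] = frozen[-1] = True
    return MicroState(kind="wo1d", domain=domain, vertices=v, frozen_vertices=frozen)


# ---------------------------------------------------------------------------
# steppers


def step_cbm(state: MicroState, force, dt: float, retessellate: bool = True) -> MicroState:
    """Advance cell centers: x_i += dt v_i for non-frozen cells."""
    if state.kind != "cbm":
        raise ValueError("state is not a CBM state")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    c = state.centers
    v = cbm_velocities(c, force)
    v[c.boundary_mask] = 0.0
    x_new = c.coords + dt * v
    if c.d == 1:
        order = np.argsort(c.coords[:, 0])
        if np.any(np.diff(x_new[order, 0]) <= 0):
            raise ValueError(
                "step would reorder or collide 1D centers; reduce the time step"
            )
    new_centers = CellCenters(x_new, c.boundary_mask)
    tess = state.tess
    if retessellate and dt > 0:
        tess = (
            tessellate_1d(new_centers, state.domain)
            if state.domain.d == 1
            else tessellate_2d(new_centers, state.domain, build_mesh=False)[0]
        )
    return replace(state, centers=new_centers, tess=tess, t=state.t + dt)


def step_vbm(state: MicroState, force, dt: float) -> MicroState:
    """Advance polygon vertices with WO or NH forces; recompute areas/perimeters."""
    if state.kind != "vbm":
        raise ValueError("state is not a VBM state")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    mesh = state.mesh
    geom = state.geometry
    vel_fn = wo_vertex_velocity if isinstance(force, WOParams) else nh_vertex_velocity
    coords = mesh.vertex_coords.copy()
    for alpha in range(mesh.n_vertices):
        if state.frozen_vertices[alpha] or mesh.is_boundary[alpha]:
            continue
        coords[alpha] += dt * vel_fn(alpha, mesh, geom, force)
    new_geom = polygon_geometry(coords, state.polygons)
    if np.any(new_geom.volumes <= 0):
        bad = int(np.argmin(new_geom.volumes))
        raise ValueError(f"non-positive area for cell {bad} after step; reduce dt")
    # imminent edge collapse check (no topological transitions are performed)
    tol = 1e-6 * state.initial_mean_edge
    for a in range(mesh.n_vertices):
        for b in mesh.vertex_adjacency[a]:
            if a < b and np.linalg.norm(coords[b] - coords[a]) < tol:
                raise ValueError(f"edge ({a}, {b}) collapsed below tolerance; reduce dt")
    new_mesh = VertexMesh(coords, mesh.vertex_adjacency, mesh.vertex_incident_cells,
                          mesh.is_boundary)
    return replace(state, mesh=new_mesh, geometry=new_geom, t=state.t + dt)


def step_wo_1d(state: MicroState, sigma: float, dt: float) -> MicroState:
    """1D WO chain: interior vertex velocity sigma (1/V_left - 1/V_right)."""
    if state.kind != "wo1d":
        raise ValueError("state is not a 1D WO state")
    v = state.vertices
    V = np.diff(v)
    if np.any(V <= 0):
        raise ValueError("degenerate cell interval")
    vel = np.zeros_like(v)
    vel[1:-1] = sigma * (1.0 / V[:-1] - 1.0 / V[1:])
    vel[state.frozen_vertices] = 0.0
    v_new = v + dt * vel
    if np.any(np.diff(v_new) <= 0):
        raise ValueError("step would collapse a cell interval; reduce the time step")
    return replace(state, vertices=v_new, t=state.t + dt)


def run(state: MicroState, config: SimConfig, force, sigma: float | None = None
        ) -> list[MicroState]:
    """Repeated stepping to T with tessellation refresh and save strides.

    Deterministic given inputs.  ``force`` is the CBM force law or the
    WO/NH parameter set; for 'wo1d' pass ``sigma``.
    """
    n_steps = int(round(config.T / config.dt)) if config.T > 0 else 0
    traj = [_snapshot(state)]
    cur = state
    for n in range(n_steps):
        try:
            if cur.kind == "cbm":
                retess = (n + 1) % config.retessellate_every == 0 or n == n_steps - 1
                cur = step_cbm(cur, force, config.dt, retessellate=retess)
            elif cur.kind == "vbm":
                cur = step_vbm(cur, force, config.dt)
            elif cur.kind == "wo1d":
                cur = step_wo_1d(cur, sigma if sigma is not None else force.sigma,
                                 config.dt)
            else:
                raise ValueError(f"unknown model kind {cur.kind!r}")
        except ValueError as e:
            raise ValueError(f"step {n + 1}: {e}") from e
        if (n + 1) % config.save_every == 0 or n == n_steps - 1:
            traj.append(_snapshot(cur))
    return traj


def _snapshot(state: MicroState) -> MicroState:
    if state.kind == "cbm":
        return replace(state, centers=CellCenters(state.centers.coords.copy(),
                                                  state.centers.boundary_mask.copy()))
    if state.kind == "wo1d":
        return replace(state, vertices=state.vertices.copy())
    return replace(state)


# ---------------------------------------------------------------------------
# density extraction and diagnostics


def density_field(state: MicroState) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (center position, density rho_i = 1/V_i)."""
    if state.kind == "cbm":
        V = state.tess.volumes
        pos = state.centers.coords
    elif state.kind == "vbm":
        V = state.geometry.volumes
        pos = np.array([
            state.mesh.vertex_coords[poly].mean(axis=0) for poly in state.polygons
        ])
    elif state.kind == "wo1d":
        V = np.diff(state.vertices)
        pos = 0.5 * (state.vertices[:-1] + state.vertices[1:])[:, None]
    else:
        raise ValueError(f"unknown model kind {state.kind!r}")
    if np.any(V <= 0):
        raise ValueError("non-positive cell volume")
    return pos, 1.0 / V


def gcl_volume_update(state: MicroState, force, dt: float) -> np.ndarray:
    """Geometric-conservation-law volume estimate (diagnostic).

    V_i^{n+1} = V_i^n + dt sum_{j in J_i} n_ij . v_ij a_ij with the interface
    velocity v_ij taken as the mean of the two adjacent cell velocities —
    an alternative to re-tessellation after a CBM step.
    """
    if state.kind != "cbm" or state.tess is None:
        raise ValueError("requires a CBM state with a current tessellation")
    tess = state.tess
    v = cbm_velocities(state.centers, force)
    v[state.centers.boundary_mask] = 0.0
    V_new = tess.volumes.copy()
    for (i, j), a_ij in tess.interface_measures.items():
        n_ij = tess.interface_normals[(i, j)]
        v_ij = 0.5 * (v[i] + v[j])
        flux = float(np.dot(n_ij, v_ij)) * a_ij
        V_new[i] += dt * flux
        V_new[j] -= dt * flux
    return V_new
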