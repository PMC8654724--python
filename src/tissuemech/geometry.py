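"""Cell geometry: Voronoi tessellations and regular-shape coarse-graining factors.

A population of N biological cells is represented by its cell centers
``x_i`` in a rectangular domain.  The Voronoi tessellation of the centers
defines the cell geometry: the Voronoi region of center i is cell i, with
volume (length/area) ``V_i``, perimeter ``a_i``, interface measures ``a_ij``
against each neighbor j, and inradius ``r_i``.  The dual Delaunay edges
connect neighboring centers; center-based forces act along them, while
vertex-based forces act on the Voronoi vertices.

On the macro level only the cell volume V = 1/rho is available.  Assuming the
cell is a regular polygon (2D) or polyhedron (3D) with J neighbors closes the
missing geometry through the factor ``xi_d(J)`` in

    r = xi_d(J) V^(1/d),   V/a_ij = (J/d) xi_d(J) V^(1/d),
    a = (d/xi_d(J)) V^((d-1)/d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "Domain",
    "CellCenters",
    "Tessellation",
    "VertexMesh",
    "CIRCLE_LIMIT",
    "xi_factor",
    "shape_relations",
    "tessellate_1d",
    "tessellate_2d",
]

#: Marker for the J -> infinity (circle/sphere) limit of ``xi_factor``.
CIRCLE_LIMIT = math.inf

_DEGENERACY_TOL = 1e-12


class TessellationError(ValueError):
    """Raised for degenerate or invalid center configurations."""


@dataclass(frozen=True)
class Domain:
    """Axis-aligned rectangular domain in d = 1, 2 or 3 dimensions."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self):
        lo = tuple(float(v) for v in np.atleast_1d(self.lower))
        hi = tuple(float(v) for v in np.atleast_1d(self.upper))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if len(lo) != len(hi):
            raise ValueError("lower and upper must have the same length")
        if len(lo) not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2 or 3")
        for k, (a, b) in enumerate(zip(lo, hi)):
            if not a < b:
                raise ValueError(f"lower[{k}]={a} must be < upper[{k}]={b}")

    @property
    def d(self) -> int:
        return len(self.lower)

    @property
    def extents(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    @property
    def measure(self) -> float:
        return float(np.prod(self.extents))

    def contains(self, points: np.ndarray, strict: bool = False) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        if strict:
            return np.all((pts > lo) & (pts < hi), axis=1)
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass
class CellCenters:
    """Cell-center coordinates plus a per-cell frozen-boundary flag.

    ``coords`` has shape (N, d); 1D input may be given as a flat array.
    """

    coords: np.ndarray
    boundary_mask: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.ndim != 2:
            raise ValueError("coords must be (N, d)")
        self.coords = c
        if self.boundary_mask is None:
            self.boundary_mask = np.zeros(len(c), dtype=bool)
        else:
            self.boundary_mask = np.asarray(self.boundary_mask, dtype=bool)
            if self.boundary_mask.shape != (len(c),):
                raise ValueError("boundary_mask must have one flag per cell")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class Tessellation:
    """Per-cell Voronoi geometry in the caller's cell indexing.

    volumes[i] = V_i, perimeters[i] = a_i, neighbor_sets[i] = J_i,
    interface_measures[(i, j)] = a_ij (symmetric; 1 in 1D),
    interface_normals[(i, j)] = unit normal n_ij from cell i toward j,
    inradii[i] = r_i (distance from center to nearest cell boundary),
    cell_polygons (2D): ordered vertex index lists into the VertexMesh.
    """

    d: int
    volumes: np.ndarray
    perimeters: np.ndarray
    neighbor_sets: list[set[int]]
    interface_measures: dict[tuple[int, int], float]
    interface_normals: dict[tuple[int, int], np.ndarray]
    inradii: np.ndarray
    boundary: np.ndarray
    cell_polygons: list[list[int]] | None = None
    order: np.ndarray | None = None  # 1D: permutation sorting the centers

    @property
    def n(self) -> int:
        return len(self.volumes)

    def interface(self, i: int, j: int) -> float:
        return self.interface_measures[(i, j) if i < j else (j, i)]

    def normal(self, i: int, j: int) -> np.ndarray:
        key = (i, j) if i < j else (j, i)
        n = self.interface_normals[key]
        return n if i < j else -n


@dataclass
class VertexMesh:
    """Voronoi vertices of a 2D tessellation with incidence maps.

    vertex_coords: (M, 2); vertex_adjacency[v] = adjacent vertex ids;
    vertex_incident_cells[v] = cell ids with a corner at v;
    is_boundary[v]: vertex lies on the domain boundary (or is not 3-valent).
    """

    vertex_coords: np.ndarray
    vertex_adjacency: list[set[int]]
    vertex_incident_cells: list[set[int]]
    is_boundary: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    def edge(self, a: int, b: int) -> tuple[float, np.ndarray]:
        """Length r_ab and unit direction from vertex a to b."""
        r = self.vertex_coords[b] - self.vertex_coords[a]
        length = float(np.hypot(*r))
        if length <= 0.0:
            raise TessellationError(f"zero-length edge between vertices {a} and {b}")
        return length, r / length


# ---------------------------------------------------------------------------
# regular-shape factors

# Platonic-solid inradius-to-volume factors xi_3(J) with J faces:
# r = xi_3 V^(1/3).  Tetra 1/(2*3^(1/6)), cube 1/2, octa 1/(2^(2/3) 3^(1/6)),
# dodecahedron via its closed-form inradius/volume.
_XI3_PLATONIC = {
    4: 1.0 / (2.0 * 3.0 ** (1.0 / 6.0)),
    6: 0.5,
    8: 1.0 / (2.0 ** (2.0 / 3.0) * 3.0 ** (1.0 / 6.0)),
    12: (4.0 ** (1.0 / 3.0) * math.sqrt(250.0 + 110.0 * math.sqrt(5.0)))
    / (20.0 * (15.0 + 7.0 * math.sqrt(5.0)) ** (1.0 / 3.0)),
}


def xi_factor(d: int, J: float, *, interpolate: bool = False,
              override: float | None = None) -> float:
    """Inradius-to-volume factor xi_d(J) of a regular J-gon / J-hedron.

    Parameters
    ----------
    d : 1, 2 or 3.
    J : neighbor/edge/face count, or ``CIRCLE_LIMIT`` (math.inf) for the
        circle/sphere limit.  d=1 ignores J (xi_1 = 1/2).  d=2 requires
        J >= 3.  d=3 supports the Platonic J in {4, 6, 8, 12} and the limit.
    interpolate : for d=3 and other J, interpolate xi_3 piecewise-linearly
        in 1/J over the supported nodes instead of rejecting.
    override : explicit user-supplied xi value, returned as-is.
    """
    if override is not None:
        return float(override)
    if d == 1:
        return 0.5
    if d == 2:
        if J == CIRCLE_LIMIT:
            return 1.0 / math.sqrt(math.pi)
        if J < 3 or int(J) != J:
            raise ValueError(f"xi_2 requires integer J >= 3 or CIRCLE_LIMIT, got {J}")
        return 1.0 / math.sqrt(J * math.tan(math.pi / J))
    if d == 3:
        if J == CIRCLE_LIMIT:
            return (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        if J in _XI3_PLATONIC:
            return _XI3_PLATONIC[J]
        if interpolate and J > 4:
            nodes = sorted(_XI3_PLATONIC) + [CIRCLE_LIMIT]
            inv = np.array([1.0 / j for j in nodes])  # 1/inf = 0
            xi = np.array([xi_factor(3, j) for j in nodes])
            o = np.argsort(inv)
            return float(np.interp(1.0 / J, inv[o], xi[o]))
        raise ValueError(
            f"xi_3 is defined for J in {sorted(_XI3_PLATONIC)} or CIRCLE_LIMIT; "
            f"got J={J} (pass interpolate=True or an explicit override)"
        )
    raise ValueError(f"dimension must be 1, 2 or 3, got {d}")


def shape_relations(d: int, J: float, V: float, **xi_kwargs) -> tuple[float, float, float]:
    """Regular-shape relations (inradius r, ratio V/a_ij, perimeter a) at volume V.

    r = xi_d(J) V^(1/d);  V/a_ij = (J/d) xi_d(J) V^(1/d);
    a = (d/xi_d(J)) V^((d-1)/d).
    """
    if V <= 0:
        raise ValueError(f"cell volume must be positive, got {V}")
    xi = xi_factor(d, J, **xi_kwargs)
    v1d = V ** (1.0 / d)
    r = xi * v1d
    Jeff = 2.0 if d == 1 else J
    v_over_aij = Jeff * xi * v1d / d
    a = d / xi * V ** ((d - 1.0) / d)
    return r, v_over_aij, a


# ---------------------------------------------------------------------------
# 1D tessellation


def tessellate_1d(centers: CellCenters, domain: Domain) -> Tessellation:
    """Interval Voronoi tessellation: cell i spans the midpoints to its neighbors.

    End cells are clipped at the domain bounds so the intervals exactly
    partition the domain.  The returned arrays follow the caller's cell
    indexing; ``order`` carries the sorting permutation.
    """
    if domain.d != 1 or centers.d != 1:
        raise ValueError("tessellate_1d requires a 1D domain and 1D centers")
    x = centers.coords[:, 0]
    n = len(x)
    if n < 2:
        raise TessellationError("at least 2 centers are required in 1D")
    if not np.all(domain.contains(centers.coords, strict=True)):
        bad = np.nonzero(~domain.contains(centers.coords, strict=True))[0]
        raise TessellationError(f"centers outside the open domain: indices {bad.tolist()}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gaps = np.diff(xs)
    if np.any(gaps <= _DEGENERACY_TOL):
        k = int(np.argmax(gaps <= _DEGENERACY_TOL))
        i, j = int(order[k]), int(order[k + 1])
        raise TessellationError(f"duplicate/coincident centers: indices ({i}, {j})")

    lo, hi = domain.lower[0], domain.upper[0]
    edges = np.concatenate([[lo], 0.5 * (xs[:-1] + xs[1:]), [hi]])
    vol_sorted = np.diff(edges)

    volumes = np.empty(n)
    volumes[order] = vol_sorted
    inradii = np.empty(n)
    inradii[order] = np.minimum(xs - edges[:-1], edges[1:] - xs)
    boundary = np.zeros(n, dtype=bool)
    boundary[order[0]] = boundary[order[-1]] = True

    neighbor_sets: list[set[int]] = [set() for _ in range(n)]
    measures: dict[tuple[int, int], float] = {}
    normals: dict[tuple[int, int], np.ndarray] = {}
    for k in range(n - 1):
        i, j = int(order[k]), int(order[k + 1])
        neighbor_sets[i].add(j)
        neighbor_sets[j].add(i)
        key = (i, j) if i < j else (j, i)
        measures[key] = 1.0
        sgn = 1.0 if key == (i, j) else -1.0
        normals[key] = np.array([sgn])  # from lower-index cell toward the other

    perimeters = np.array([float(len(s)) for s in neighbor_sets])
    return Tessellation(
        d=1, volumes=volumes, perimeters=perimeters, neighbor_sets=neighbor_sets,
        interface_measures=measures, interface_normals=normals, inradii=inradii,
        boundary=boundary, order=order,
    )


# ---------------------------------------------------------------------------
# 2D tessellation


def _mirror_points(pts: np.ndarray, domain: Domain,
                   buffer: float | None = None) -> np.ndarray:
    """Reflect points across each domain face (2D: 4 face + 4 corner images).

    With ``buffer`` set, only points within that distance of a face are
    reflected (sufficient when the buffer exceeds the largest Voronoi cell
    radius; the caller verifies the resulting partition and falls back to
    full mirroring otherwise).  Double reflections are never needed: inside
    a rectangular domain a doubly reflected image is never closer than the
    point it images.
    """
    ghosts = []
    for axis in range(domain.d):
        for bound in (domain.lower[axis], domain.upper[axis]):
            if buffer is None:
                g = pts.copy()
            else:
                g = pts[np.abs(pts[:, axis] - bound) <= buffer].copy()
            g[:, axis] = 2.0 * bound - g[:, axis]
            ghosts.append(g)
    return np.vstack([pts] + ghosts)


def tessellate_2d(centers: CellCenters, domain: Domain,
                  build_mesh: bool = True) -> tuple[Tessellation, VertexMesh | None]:
    """Bounded Voronoi tessellation of 2D centers, clipped to the domain.

    Every center is mirrored across the four domain edges before calling
    scipy's Voronoi; the regions of the original points are then finite and
    exactly clipped by the domain boundary, so the cell areas partition the
    domain measure.  Returns the per-cell geometry and the Voronoi vertex
    mesh (vertices inside the closed domain, with adjacency and the cells
    incident to each vertex).  ``build_mesh=False`` skips the vertex mesh
    and per-cell polygon lists (cheaper; used by the center-based stepper).
    """
    if domain.d != 2 or centers.d != 2:
        raise ValueError("tessellate_2d requires a 2D domain and 2D centers")
    pts = centers.coords
    n = len(pts)
    if n < 3:
        raise TessellationError("at least 3 centers are required in 2D")
    if not np.all(domain.contains(pts, strict=True)):
        bad = np.nonzero(~domain.contains(pts, strict=True))[0]
        raise TessellationError(f"centers outside the open domain: indices {bad.tolist()}")
    spread = pts - pts.mean(axis=0)
    if np.linalg.svd(spread, compute_uv=False)[-1] < _DEGENERACY_TOL * max(
        1.0, float(np.abs(spread).max())
    ):
        raise TessellationError("centers are all collinear")

    # Adaptive buffered mirroring (cheap), verified by the partition check;
    # full mirroring as the safe fallback for sparse/irregular point sets.
    buffer = 4.0 * (domain.measure / n) ** (1.0 / domain.d)
    try:
        return _tessellate_2d_impl(pts, domain, Voronoi(_mirror_points(pts, domain, buffer)),
                                   build_mesh)
    except TessellationError:
        return _tessellate_2d_impl(pts, domain, Voronoi(_mirror_points(pts, domain)),
                                   build_mesh)


def _tessellate_2d_impl(pts: np.ndarray, domain: Domain, vor: Voronoi,
                        build_mesh: bool) -> tuple[Tessellation, VertexMesh | None]:
    n = len(pts)
    # Flattened region representation: vectorized shoelace/perimeter/inradius.
    regions = [vor.regions[vor.point_region[i]] for i in range(n)]
    counts = np.array([len(r) for r in regions])
    if np.any(counts < 3) or any(-1 in r for r in regions):
        bad = int(np.argmin(counts))
        raise TessellationError(f"unbounded region for cell {bad} after mirroring")
    flat = np.concatenate(regions)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    ends = np.cumsum(counts)
    nxt = np.arange(len(flat)) + 1
    nxt[ends - 1] = starts
    P = vor.vertices[flat]
    Q = vor.vertices[flat[nxt]]
    cross = P[:, 0] * Q[:, 1] - P[:, 1] * Q[:, 0]
    signed = 0.5 * np.add.reduceat(cross, starts)
    volumes = np.abs(signed)
    if np.any(volumes <= 0):
        raise TessellationError(
            f"degenerate (zero-area) region for cell {int(np.argmin(volumes))}"
        )
    edge = Q - P
    edge_len = np.hypot(edge[:, 0], edge[:, 1])
    perimeters = np.add.reduceat(edge_len, starts)
    ci = np.repeat(pts, counts, axis=0)
    dist = np.abs(edge[:, 0] * (ci[:, 1] - P[:, 1]) - edge[:, 1] * (ci[:, 0] - P[:, 0]))
    inradii = np.minimum.reduceat(dist / np.maximum(edge_len, 1e-300), starts)

    measure = domain.measure
    total = volumes.sum()
    if not math.isclose(total, measure, rel_tol=1e-9):
        raise TessellationError(
            f"Voronoi areas sum to {total}, domain measure is {measure}"
        )

    # Interfaces between original cells, from the ridge lists (vectorized prep).
    rp = np.asarray(vor.ridge_points)
    rv = np.asarray(vor.ridge_vertices)
    valid = (rv[:, 0] >= 0) & (rv[:, 1] >= 0)
    both_orig = valid & (rp[:, 0] < n) & (rp[:, 1] < n)
    seg = vor.vertices[rv[:, 1]] - vor.vertices[rv[:, 0]]
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    both_orig &= seg_len > _DEGENERACY_TOL  # drop cocircular vanishing ridges
    neighbor_sets: list[set[int]] = [set() for _ in range(n)]
    measures_d: dict[tuple[int, int], float] = {}
    normals: dict[tuple[int, int], np.ndarray] = {}
    idx = np.nonzero(both_orig)[0]
    lo_pt = np.minimum(rp[idx, 0], rp[idx, 1])
    hi_pt = np.maximum(rp[idx, 0], rp[idx, 1])
    rij = pts[hi_pt] - pts[lo_pt]
    rij_hat = rij / np.linalg.norm(rij, axis=1, keepdims=True)
    for k, (i, j) in enumerate(zip(lo_pt.tolist(), hi_pt.tolist())):
        neighbor_sets[i].add(j)
        neighbor_sets[j].add(i)
        measures_d[(i, j)] = float(seg_len[idx[k]])
        normals[(i, j)] = rij_hat[k]

    # Boundary cells: region touches the domain boundary.
    lo = np.asarray(domain.lower)
    hi = np.asarray(domain.upper)
    vert_on_bound = np.any((np.abs(P - lo) < 1e-9) | (np.abs(P - hi) < 1e-9), axis=1)
    boundary_cells = np.add.reduceat(vert_on_bound, starts) > 0

    polygons: list[list[int]] | None = None
    mesh: VertexMesh | None = None
    if build_mesh:
        # Compact local indexing of the vertices used by original cells.
        used = np.unique(flat)
        local = {int(v): k for k, v in enumerate(used)}
        vcoords = vor.vertices[used]
        m = len(used)
        polygons = []
        incident_cells: list[set[int]] = [set() for _ in range(m)]
        for i, region in enumerate(regions):
            loc = [local[v] for v in region]
            if signed[i] < 0:
                loc = loc[::-1]
            polygons.append(loc)
            for v in loc:
                incident_cells[v].add(i)
        adjacency: list[set[int]] = [set() for _ in range(m)]
        any_orig = valid & ((rp[:, 0] < n) | (rp[:, 1] < n)) & (seg_len > _DEGENERACY_TOL)
        for r in np.nonzero(any_orig)[0]:
            a, b = int(rv[r, 0]), int(rv[r, 1])
            if a in local and b in local:
                la, lb = local[a], local[b]
                adjacency[la].add(lb)
                adjacency[lb].add(la)
        on_bound = np.any(
            (np.abs(vcoords - lo) < 1e-9) | (np.abs(vcoords - hi) < 1e-9), axis=1
        )
        is_boundary = on_bound | np.array(
            [len(incident_cells[v]) < 3 or len(adjacency[v]) != 3 for v in range(m)]
        )
        mesh = VertexMesh(
            vertex_coords=vcoords, vertex_adjacency=adjacency,
            vertex_incident_cells=incident_cells, is_boundary=is_boundary,
        )

    tess = Tessellation(
        d=2, volumes=volumes, perimeters=perimeters, neighbor_sets=neighbor_sets,
        interface_measures=measures_d, interface_normals=normals, inradii=inradii,
        boundary=boundary_cells, cell_polygons=polygons,
    )
    return tess, mesh
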