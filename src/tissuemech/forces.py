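"""Micro-level force laws of the center-based (CBM) and vertex-based (VBM) models.

CBM: the pair force between two cell centers at distance r has magnitude
g(r) along the center-to-center direction, with repulsion for r < s,
adhesion for s < r < r_A, and zero beyond the cutoff r_A.  Two standard
choices are provided: an exponential law mu (r - s) exp(-c (r - s)) and a
polynomial repulsion/adhesion law with ranges r_R < r_A.

VBM (2D): forces act on the Voronoi vertices.  The Weliky-Oster (WO) model
pushes each vertex along its three outgoing edges with magnitudes depending
on the area of the cell opposite each edge and the perimeters of the two
cells flanking it.  The Nagai-Honda (NH) model is an energy-gradient variant
that linearizes to WO for small deviations from the ideal area/perimeter;
`match_nh_to_wo` and `match_wo_to_cbm` encode the parameter correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CellCenters, Tessellation, VertexMesh

__all__ = [
    "ExpForceParams",
    "PolyForceParams",
    "WOParams",
    "NHParams",
    "g_exp",
    "g_exp_prime",
    "g_poly",
    "g_poly_prime",
    "poly_zero_distance",
    "cbm_velocities",
    "wo_force_function",
    "wo_vertex_velocity",
    "nh_vertex_velocity",
    "match_wo_to_cbm",
    "match_nh_to_wo",
    "f_from_cbm",
]


@dataclass(frozen=True)
class ExpForceParams:
    """Exponential CBM force: g(r) = mu (r - s) exp(-c (r - s)) for r <= r_A."""

    mu: float = 50.0
    s: float = 1.0
    c: float = 10.0
    r_A: float = 1.5
    eta: float = 1.0

    def __post_init__(self):
        if self.s <= 0 or self.mu <= 0 or self.c <= 0 or self.eta <= 0:
            raise ValueError("mu, s, c, eta must be positive")
        if self.r_A <= self.s:
            raise ValueError("cutoff r_A must exceed the rest distance s")

    def g(self, r):
        return g_exp(r, self)

    def dg(self, r):
        return g_exp_prime(r, self)


@dataclass(frozen=True)
class PolyForceParams:
    """Polynomial CBM force with repulsion range r_R and adhesion range r_A."""

    c_r: float
    c_a: float
    r_R: float
    r_A: float
    n: int = 1
    eta: float = 1.0

    def __post_init__(self):
        if not 0 < self.r_R < self.r_A:
            raise ValueError("ranges must satisfy 0 < r_R < r_A")
        if self.c_a >= self.c_r:
            raise ValueError("adhesion c_a must be smaller than repulsion c_r")
        if self.c_r <= 0 or self.c_a < 0:
            raise ValueError("c_r > 0 and c_a >= 0 required")
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError("exponent n must be a non-negative integer")
        if self.c_a > 0:
            s = poly_zero_distance(self)
            if not 0 < s < self.r_R:
                raise ValueError(f"derived rest distance s={s} outside (0, r_R)")

    @property
    def s(self) -> float:
        return poly_zero_distance(self) if self.c_a > 0 else self.r_R

    def g(self, r):
        return g_poly(r, self)

    def dg(self, r):
        return g_poly_prime(r, self)


@dataclass(frozen=True)
class WOParams:
    """Weliky-Oster vertex force coefficients (area sigma, perimeter kappa)."""

    sigma: float = 1.0
    kappa: float = 1.0
    eta: float = 1.0

    def __post_init__(self):
        if self.sigma < 0 or self.kappa < 0:
            raise ValueError("sigma and kappa must be non-negative")
        if self.sigma == 0 and self.kappa == 0:
            raise ValueError("sigma and kappa cannot both vanish")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass(frozen=True)
class NHParams:
    """Nagai-Honda vertex force coefficients with ideal area V0 and perimeter a0."""

    lam: float
    beta: float
    gamma: float
    V0: float
    a0: float
    eta: float = 1.0

    def __post_init__(self):
        if self.V0 <= 0 or self.a0 <= 0:
            raise ValueError("ideal area V0 and perimeter a0 must be positive")
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be non-negative")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


# ---------------------------------------------------------------------------
# CBM scalar force laws


def _check_nonneg_r(r):
    if np.any(np.asarray(r) < 0):
        raise ValueError("distance r must be non-negative")


def g_exp(r, p: ExpForceParams):
    """Exponential pair-force magnitude; discontinuous cutoff at r = r_A."""
    _check_nonneg_r(r)
    r = np.asarray(r, dtype=float)
    out = np.where(r <= p.r_A, p.mu * (r - p.s) * np.exp(-p.c * (r - p.s)), 0.0)
    return out if out.ndim else float(out)


def g_exp_prime(r, p: ExpForceParams):
    """Analytic derivative g'(r); the interior branch is used at r = r_A."""
    _check_nonneg_r(r)
    r = np.asarray(r, dtype=float)
    interior = p.mu * np.exp(-p.c * (r - p.s)) * (1.0 - p.c * (r - p.s))
    out = np.where(r <= p.r_A, interior, 0.0)
    return out if out.ndim else float(out)


def g_poly(r, p: PolyForceParams):
    """Polynomial pair-force magnitude; continuous at r_R and r_A."""
    _check_nonneg_r(r)
    r = np.asarray(r, dtype=float)
    m = p.n + 1
    adh = np.where(r <= p.r_A, p.c_a * (1.0 - r / p.r_A) ** m, 0.0)
    rep = np.where(r <= p.r_R, -p.c_r * (1.0 - r / p.r_R) ** m, 0.0)
    out = adh + rep
    return out if out.ndim else float(out)


def g_poly_prime(r, p: PolyForceParams):
    _check_nonneg_r(r)
    r = np.asarray(r, dtype=float)
    m = p.n + 1
    adh = np.where(r <= p.r_A, -p.c_a * m / p.r_A * (1.0 - r / p.r_A) ** (m - 1), 0.0)
    rep = np.where(r <= p.r_R, p.c_r * m / p.r_R * (1.0 - r / p.r_R) ** (m - 1), 0.0)
    out = adh + rep
    return out if out.ndim else float(out)


def poly_zero_distance(p: PolyForceParams) -> float:
    """Rest distance s where the polynomial force changes sign (s < r_R)."""
    if p.c_a >= p.c_r:
        raise ValueError("requires c_a < c_r")
    if p.c_a == 0:
        return p.r_R
    e = 1.0 / (p.n + 1)
    cr, ca = p.c_r**e, p.c_a**e
    return p.r_A * p.r_R * (cr - ca) / (cr * p.r_A - ca * p.r_R)


# ---------------------------------------------------------------------------
# CBM velocities


def cbm_velocities(centers: CellCenters, force, tess: Tessellation | None = None) -> np.ndarray:
    """Overdamped center velocities v_i = (1/eta) sum_j r_hat_ij g(r_ij).

    The pair sum runs over all pairs within the cutoff r_A, found with a
    KD-tree query (not restricted to Voronoi neighbors).  Frozen boundary
    cells get a velocity too; the integrator zeroes their motion.
    """
    x = centers.coords
    n, d = x.shape
    v = np.zeros((n, d))
    tree = cKDTree(x)
    pairs = tree.query_pairs(force.r_A, output_type="ndarray")
    if len(pairs) == 0:
        return v
    i, j = pairs[:, 0], pairs[:, 1]
    rij = x[j] - x[i]
    dist = np.linalg.norm(rij, axis=1)
    if np.any(dist <= 0):
        k = int(np.argmax(dist <= 0))
        raise ValueError(f"coincident centers: pair ({i[k]}, {j[k]})")
    gmag = np.asarray(force.g(dist)) / force.eta
    contrib = (gmag / dist)[:, None] * rij
    np.add.at(v, i, contrib)
    np.add.at(v, j, -contrib)
    return v


# ---------------------------------------------------------------------------
# VBM vertex forces


def wo_force_function(V: float, a: float, b: float, p: WOParams) -> float:
    """WO edge force magnitude f(V, a, b) = sigma/V + kappa (a + b)."""
    if V <= 0:
        raise ValueError("cell area V must be positive")
    return p.sigma / V + p.kappa * (a + b)


def _vertex_edge_cells(alpha: int, mesh: VertexMesh) -> list[tuple[int, int, tuple[int, int]]]:
    """For an interior 3-valent vertex, pair each outgoing edge with cells.

    Returns (beta, opposite_cell, (flank1, flank2)) per adjacent vertex beta:
    the two cells sharing the edge alpha-beta flank it, the remaining
    incident cell of alpha is opposite the edge.
    """
    if mesh.is_boundary[alpha]:
        raise ValueError(f"vertex {alpha} is a boundary vertex")
    cells = mesh.vertex_incident_cells[alpha]
    nbrs = mesh.vertex_adjacency[alpha]
    if len(cells) != 3 or len(nbrs) != 3:
        raise ValueError(f"vertex {alpha} is not an interior 3-valent vertex")
    out = []
    for beta in sorted(nbrs):
        flank = cells & mesh.vertex_incident_cells[beta]
        opp = cells - flank
        if len(flank) != 2 or len(opp) != 1:
            raise ValueError(
                f"edge ({alpha}, {beta}) is not flanked by exactly two incident cells"
            )
        f1, f2 = sorted(flank)
        out.append((beta, next(iter(opp)), (f1, f2)))
    return out


def wo_vertex_velocity(alpha: int, mesh: VertexMesh, tess: Tessellation,
                       p: WOParams) -> np.ndarray:
    """WO velocity of interior vertex alpha.

    Each outgoing edge direction r_hat_ab is weighted by
    f(V_opposite, a_flank1, a_flank2).
    """
    v = np.zeros(2)
    for beta, opp, (f1, f2) in _vertex_edge_cells(alpha, mesh):
        _, rhat = mesh.edge(alpha, beta)
        f = wo_force_function(tess.volumes[opp], tess.perimeters[f1],
                              tess.perimeters[f2], p)
        v += f * rhat
    return v / p.eta


def nh_vertex_velocity(alpha: int, mesh: VertexMesh, tess: Tessellation,
                       p: NHParams) -> np.ndarray:
    """NH velocity of interior vertex alpha.

    Edge alpha->beta receives the area term -lam (V_opp - V0) r_ab from the
    opposite cell and the perimeter terms 2 beta (a - a0) + gamma from the
    two flanking cells (the per-cell form assigns each cell's perimeter term
    to the two edges it flanks).
    """
    v = np.zeros(2)
    for beta, opp, (f1, f2) in _vertex_edge_cells(alpha, mesh):
        r_ab, rhat = mesh.edge(alpha, beta)
        w = -p.lam * (tess.volumes[opp] - p.V0) * r_ab
        for k in (f1, f2):
            w += 2.0 * p.beta * (tess.perimeters[k] - p.a0) + p.gamma
        v += w * rhat
    return v / p.eta


# ---------------------------------------------------------------------------
# parameter correspondences between models


def match_wo_to_cbm(p: ExpForceParams, V0: float) -> WOParams:
    """WO coefficients reproducing CBM small perturbations in 1D.

    The 1D matching g'(s) = sigma / V0^2 gives sigma = g'(s) V0^2 (for the
    exponential law g'(s) = mu); the perimeter term has no 1D analogue
    (kappa = 0, sigma-only law).
    """
    if V0 <= 0:
        raise ValueError("equilibrium cell size V0 must be positive")
    gp = float(p.dg(p.s))
    # WOParams forbids sigma=kappa=0; gp>0 for valid laws.
    return WOParams(sigma=gp * V0**2, kappa=0.0, eta=p.eta)


def match_nh_to_wo(p: WOParams, V0: float, r_edge: float, a0: float | None = None) -> NHParams:
    """NH coefficients matching WO to first order around equilibrium:
    lam r_edge = sigma / V0^2, kappa = 2 beta, gamma = 0."""
    if V0 <= 0 or r_edge <= 0:
        raise ValueError("V0 and r_edge must be positive")
    if a0 is None:
        a0 = 6.0 * r_edge  # regular hexagon perimeter at edge length r_edge
    return NHParams(lam=p.sigma / (r_edge * V0**2), beta=p.kappa / 2.0,
                    gamma=0.0, V0=V0, a0=a0, eta=p.eta)


def f_from_cbm(V: float, force, J: float, xi2: float) -> float:
    """Vertex-model force function induced by a CBM law in 2D:
    f(V) = -(J xi_2 / 2)^2 g(2 xi_2 sqrt(V)).

    Plugging this f into the vertex scheme (or the WO pressure) reproduces
    the CBM macroscopic pressure, so the macro law is representation-free.
    """
    if V <= 0:
        raise ValueError("cell area V must be positive")
    return -((J * xi2 / 2.0) ** 2) * float(force.g(2.0 * xi2 * np.sqrt(V)))
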