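"""Coarse-grained constitutive pressure laws p(V) and their diffusion coefficients.

Regarding the discrete cell model as a finite-volume discretization of the
mass-conservation law with a Darcy closure v = -mu grad p identifies the
micro forces with a discrete pressure gradient.  Closing the missing cell
geometry with the regular-shape factor xi_d(J) yields macroscopic laws:

CBM:  p(V) = -(J xi_d / (d mu)) V^(1/d) g(2 xi_d V^(1/d))
      (1D: p = -V g(V) / mu)
WO:   p(V) = (2 / (J xi_2 mu)) V^(1/2) (sigma/V - 4 kappa cos(2 pi/J) V^(1/2)/xi_2)
Gas:  p(rho) = K rho^gamma  (isentropic power law)

The induced diffusion coefficient in d rho/dt = mu div(rho dp/drho grad rho)
is rho dp/drho.  For CBM laws with an attraction cutoff r_A, dp/drho changes
sign at low density: the PDE is unstable for rho below `rho_unstable_below`
and the force support ends at `rho_vanish_below` = (2 xi_d)^d / r_A^d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import xi_factor

__all__ = [
    "CBMPressureLaw",
    "WOPressureLaw",
    "PowerLawPressure",
    "cbm_pressure",
    "cbm_interface_pressure",
    "wo_pressure",
    "wo_discrete_pressure_1d",
    "power_law_pressure",
    "dpdrho",
    "stability_thresholds",
]


def _check_positive(name, value):
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CBMPressureLaw:
    """Macroscopic pressure law induced by a center-based force law g.

    `force` must expose g(r), dg(r) and the cutoff r_A (ExpForceParams or
    PolyForceParams).  J defaults per dimension: 2 (1D, forced), 6 (2D,
    dense packing), 12 (3D, kissing number).
    """

    force: object
    d: int = 1
    J: float | None = None
    mu: float = 1.0
    xi: float | None = None

    kind = "cbm"

    def __post_init__(self):
        if self.d not in (1, 2, 3):
            raise ValueError("d must be 1, 2 or 3")
        J = self.J
        if self.d == 1:
            J = 2.0
        elif J is None:
            J = 6.0 if self.d == 2 else 12.0
        object.__setattr__(self, "J", float(J))
        if self.xi is None:
            object.__setattr__(self, "xi", xi_factor(self.d, self.J))
        _check_positive("mu", self.mu)

    def pressure(self, V):
        return cbm_pressure(V, self)

    def pressure_of_rho(self, rho):
        """p(rho) with the convention p = 0 at rho = 0 (empty elements)."""
        rho = np.asarray(rho, dtype=float)
        if np.any(rho < 0):
            raise ValueError("rho must be non-negative")
        out = np.zeros_like(rho, dtype=float)
        pos = rho > 0
        out[pos] = cbm_pressure(1.0 / rho[pos], self)
        return out if out.ndim else float(out)

    def dpdrho(self, rho):
        return dpdrho(rho, self)

    @property
    def equilibrium_volume(self) -> float:
        """V0 with 2 xi_d V0^(1/d) = s: the zero of the pressure."""
        return (self.force.s / (2.0 * self.xi)) ** self.d


@dataclass(frozen=True)
class WOPressureLaw:
    """Macroscopic pressure law induced by the 2D Weliky-Oster vertex model."""

    sigma: float
    kappa: float
    J: float = 6.0
    mu: float = 1.0
    xi: float | None = None

    kind = "weliky_oster"
    d = 2

    def __post_init__(self):
        if self.sigma < 0 or self.kappa < 0:
            raise ValueError("sigma and kappa must be non-negative")
        if self.xi is None:
            object.__setattr__(self, "xi", xi_factor(2, self.J))
        _check_positive("mu", self.mu)

    def pressure(self, V):
        return wo_pressure(V, self)

    def pressure_of_rho(self, rho):
        rho = np.asarray(rho, dtype=float)
        if np.any(rho < 0):
            raise ValueError("rho must be non-negative")
        out = np.zeros_like(rho, dtype=float)
        pos = rho > 0
        out[pos] = wo_pressure(1.0 / rho[pos], self)
        return out if out.ndim else float(out)

    def dpdrho(self, rho):
        return dpdrho(rho, self)


@dataclass(frozen=True)
class PowerLawPressure:
    """Isentropic-gas closure p = K rho^gamma with K > 0, gamma > 1."""

    K: float = 1.0
    gamma: float = 1.4
    mu: float = 1.0

    kind = "power_law"

    def __post_init__(self):
        _check_positive("K", self.K)
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        _check_positive("mu", self.mu)

    def pressure(self, V):
        _check_positive("V", V)
        return power_law_pressure(1.0 / np.asarray(V, dtype=float), self.K, self.gamma)

    def pressure_of_rho(self, rho):
        rho = np.asarray(rho, dtype=float)
        if np.any(rho < 0):
            raise ValueError("rho must be non-negative")
        out = self.K * rho**self.gamma
        return out if out.ndim else float(out)

    def dpdrho(self, rho):
        return dpdrho(rho, self)


# ---------------------------------------------------------------------------
# pressure evaluations


def cbm_pressure(V, law: CBMPressureLaw):
    """p(V) = -(J xi_d/(d mu)) V^(1/d) g(2 xi_d V^(1/d)); 1D: -V g(V)/mu."""
    _check_positive("V", V)
    V = np.asarray(V, dtype=float)
    v1d = V ** (1.0 / law.d)
    out = -(law.J * law.xi / (law.d * law.mu)) * v1d * np.asarray(
        law.force.g(2.0 * law.xi * v1d)
    )
    return out if out.ndim else float(out)


def cbm_interface_pressure(V_i, V_j, law: CBMPressureLaw, a_ij: float | None = None,
                           r_ij: float | None = None):
    """Pressure at the i-j cell interface.

    With the exact geometry (a_ij, r_ij) given: p_ij = -(V_i/(mu a_ij)) g(r_ij)
    — the discrete micro/macro bridge.  Without it, the regular-shape closure
    p_ij = -(J xi_d/(d mu)) V_i^(1/d) g(xi_d (V_i^(1/d) + V_j^(1/d))).
    """
    _check_positive("V_i", V_i)
    _check_positive("V_j", V_j)
    if a_ij is not None or r_ij is not None:
        if a_ij is None or r_ij is None:
            raise ValueError("give both a_ij and r_ij, or neither")
        if a_ij <= 0:
            raise ValueError("a_ij must be positive")
        return -(V_i / (law.mu * a_ij)) * float(law.force.g(r_ij))
    v1 = V_i ** (1.0 / law.d)
    v2 = V_j ** (1.0 / law.d)
    return -(law.J * law.xi / (law.d * law.mu)) * v1 * float(
        law.force.g(law.xi * (v1 + v2))
    )


def wo_pressure(V, law: WOPressureLaw):
    """p(V) = (2/(J xi_2 mu)) V^(1/2) (sigma/V - 4 kappa cos(2 pi/J) V^(1/2)/xi_2)."""
    _check_positive("V", V)
    V = np.asarray(V, dtype=float)
    sq = np.sqrt(V)
    out = (2.0 / (law.J * law.xi * law.mu)) * sq * (
        law.sigma / V - 4.0 * law.kappa * math.cos(2.0 * math.pi / law.J) * sq / law.xi
    )
    return out if out.ndim else float(out)


def wo_discrete_pressure_1d(V_i, V_j, sigma: float, mu: float = 1.0):
    """1D WO discrete pressure p_j = V_i f(V_j)/mu with f(V) = sigma/V.

    The i-dependence is deliberate (the continuous 1D WO pressure is the
    constant sigma/mu); this quantity is a flux ingredient of the dedicated
    1D WO scheme, not a pointwise field.
    """
    _check_positive("V_i", V_i)
    _check_positive("V_j", V_j)
    _check_positive("sigma", sigma)
    return (np.asarray(V_i, dtype=float) / mu) * (sigma / np.asarray(V_j, dtype=float))


def power_law_pressure(rho, K: float, gamma: float):
    _check_positive("rho", rho)
    _check_positive("K", K)
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    out = K * np.asarray(rho, dtype=float) ** gamma
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# diffusion coefficients and stability


def dpdrho(rho, law):
    """Analytic dp/drho of a pressure law; rho dp/drho is the diffusion coefficient.

    CBM: (J xi_d/(d^2 mu)) rho^(-(d+1)/d) (g(2 xi_d rho^(-1/d))
          + 2 xi_d rho^(-1/d) g'(2 xi_d rho^(-1/d)))
    WO:  (2/(J xi_2 mu)) (sigma/(2 rho^(1/2)) + 4 kappa cos(2 pi/J)/(xi_2 rho^2))
    power law: K gamma rho^(gamma-1).
    """
    _check_positive("rho", rho)
    rho = np.asarray(rho, dtype=float)
    if law.kind == "cbm":
        d = law.d
        arg = 2.0 * law.xi * rho ** (-1.0 / d)
        g = np.asarray(law.force.g(arg))
        gp = np.asarray(law.force.dg(arg))
        out = (law.J * law.xi / (d * d * law.mu)) * rho ** (-(d + 1.0) / d) * (g + arg * gp)
    elif law.kind == "weliky_oster":
        out = (2.0 / (law.J * law.xi * law.mu)) * (
            law.sigma / (2.0 * np.sqrt(rho))
            + 4.0 * law.kappa * math.cos(2.0 * math.pi / law.J) / (law.xi * rho**2)
        )
    elif law.kind == "power_law":
        out = law.K * law.gamma * rho ** (law.gamma - 1.0)
    else:
        raise ValueError(f"unknown pressure-law kind {law.kind!r}")
    out = np.asarray(out)
    return out if out.ndim else float(out)


def stability_thresholds(law: CBMPressureLaw) -> tuple[float | None, float]:
    """Low-density stability structure of a CBM pressure law.

    Returns ``(rho_unstable_below, rho_vanish_below)``:

    - ``rho_vanish_below`` = (2 xi_d)^d / r_A^d: below this density the
      scaled center distance exceeds the cutoff r_A, the force (hence the
      pressure and the diffusion) vanishes.
    - ``rho_unstable_below``: the largest density inside the force support at
      which dp/drho changes sign; the PDE has negative diffusion (is
      unstable) for densities between the two thresholds.  ``None`` if
      dp/drho does not change sign in the support (always stable there).

    Found by sampling + Brent bracketing of h(r) = g(r) + r g'(r) on
    (s, r_A) in the scaled coordinate r = 2 xi_d V^(1/d), to 1e-10.
    """
    if law.kind != "cbm":
        raise ValueError("stability thresholds are defined for CBM laws")
    f = law.force
    rho_vanish = (2.0 * law.xi) ** law.d / f.r_A**law.d

    def h(r):
        return float(f.g(r)) + r * float(f.dg(r))

    # dp/drho > 0 at the equilibrium r = s (h(s) = s g'(s) > 0); look for the
    # first sign change between s and the cutoff.
    rs = np.linspace(f.s, f.r_A, 2049)
    hv = np.array([h(r) for r in rs])
    sign_change = np.nonzero(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)[0]
    if len(sign_change) == 0:
        return None, rho_vanish
    k = sign_change[0]
    root = brentq(h, rs[k], rs[k + 1], xtol=1e-12, rtol=8.9e-16)
    V_star = (root / (2.0 * law.xi)) ** law.d
    return 1.0 / V_star, rho_vanish


def high_density_sign_change(law: CBMPressureLaw) -> float | None:
    """Diagnostic: sign change of dp/drho in the repulsive regime (r < s).

    For the exponential force this is the second root of the quadratic
    g + r g' = 0, at very high density; the low-density instability is the
    physically relevant one reported by ``stability_thresholds``.
    """
    if law.kind != "cbm":
        raise ValueError("defined for CBM laws")
    f = law.force

    def h(r):
        return float(f.g(r)) + r * float(f.dg(r))

    rs = np.linspace(f.s * 1e-6, f.s, 2049)
    hv = np.array([h(r) for r in rs])
    sign_change = np.nonzero(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)[0]
    if len(sign_change) == 0:
        return None
    k = sign_change[-1]
    root = brentq(h, rs[k], rs[k + 1], xtol=1e-12, rtol=8.9e-16)
    return 1.0 / (root / (2.0 * law.xi)) ** law.d
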