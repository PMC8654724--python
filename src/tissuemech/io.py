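"""Plain-text interfaces: center sets and fields as CSV, force configs as TOML.

CSV layouts
-----------
- centers: header ``x[,y]``, optional ``is_boundary`` column.
- tessellation summary: ``cell_id,V,a,n_neighbors,is_boundary``.
- density field: ``i[,j],x[,y],rho``.

TOML force sections use the conventional parameter names:
``[force.cbm_exp]`` (mu, s, c, r_A, eta), ``[force.cbm_poly]`` (c_r, c_a,
r_R, r_A, n, eta), ``[force.wo]`` (sigma, kappa, eta), ``[force.nh]``
(lambda, beta, gamma, V0, a0, eta), and ``[pressure]`` (kind, d, J, mu).
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .fvm import DensityField, Grid
from .geometry import CellCenters, Tessellation
from .forces import ExpForceParams, NHParams, PolyForceParams, WOParams
from .pressure import CBMPressureLaw, PowerLawPressure, WOPressureLaw

__all__ = [
    "read_centers_csv",
    "write_centers_csv",
    "write_tessellation_csv",
    "read_field_csv",
    "write_field_csv",
    "load_forces_toml",
    "load_pressure_law_toml",
]

_AXES = ("x", "y", "z")


def write_centers_csv(path, centers: CellCenters) -> None:
    cols = {_AXES[k]: centers.coords[:, k] for k in range(centers.d)}
    cols["is_boundary"] = centers.boundary_mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_centers_csv(path) -> CellCenters:
    df = pd.read_csv(path)
    axes = [a for a in _AXES if a in df.columns]
    if not axes:
        raise ValueError(f"{path}: no coordinate columns (expected x[,y[,z]])")
    coords = df[axes].to_numpy(dtype=float)
    mask = df["is_boundary"].to_numpy(dtype=bool) if "is_boundary" in df.columns else None
    return CellCenters(coords, mask)


def write_tessellation_csv(path, tess: Tessellation) -> None:
    pd.DataFrame({
        "cell_id": np.arange(tess.n),
        "V": tess.volumes,
        "a": tess.perimeters,
        "n_neighbors": [len(s) for s in tess.neighbor_sets],
        "is_boundary": tess.boundary.astype(int),
    }).to_csv(path, index=False)


def write_field_csv(path, f: DensityField) -> None:
    g = f.grid
    if g.d == 1:
        df = pd.DataFrame({"i": np.arange(g.shape[0]), "x": g.centers(0),
                           "rho": f.rho})
    else:
        ii, jj = np.meshgrid(np.arange(g.shape[0]), np.arange(g.shape[1]),
                             indexing="ij")
        xc, yc = np.meshgrid(g.centers(0), g.centers(1), indexing="ij")
        df = pd.DataFrame({"i": ii.ravel(), "j": jj.ravel(), "x": xc.ravel(),
                           "y": yc.ravel(), "rho": f.rho.ravel()})
    df.to_csv(path, index=False)


def read_field_csv(path, grid: Grid) -> DensityField:
    df = pd.read_csv(path)
    rho = np.empty(grid.shape)
    if grid.d == 1:
        rho[df["i"].to_numpy()] = df["rho"].to_numpy()
    else:
        rho[df["i"].to_numpy(), df["j"].to_numpy()] = df["rho"].to_numpy()
    return DensityField(grid, rho)


def load_forces_toml(path) -> dict:
    """Parse the ``[force.*]`` sections into parameter objects."""
    with open(Path(path), "rb") as fh:
        cfg = tomllib.load(fh)
    force = cfg.get("force", {})
    out = {}
    if "cbm_exp" in force:
        s = force["cbm_exp"]
        out["cbm_exp"] = ExpForceParams(mu=s["mu"], s=s["s"], c=s["c"],
                                        r_A=s["r_A"], eta=s.get("eta", 1.0))
    if "cbm_poly" in force:
        s = force["cbm_poly"]
        out["cbm_poly"] = PolyForceParams(c_r=s["c_r"], c_a=s["c_a"], r_R=s["r_R"],
                                          r_A=s["r_A"], n=s.get("n", 1),
                                          eta=s.get("eta", 1.0))
    if "wo" in force:
        s = force["wo"]
        out["wo"] = WOParams(sigma=s["sigma"], kappa=s["kappa"], eta=s.get("eta", 1.0))
    if "nh" in force:
        s = force["nh"]
        out["nh"] = NHParams(lam=s["lambda"], beta=s["beta"], gamma=s.get("gamma", 0.0),
                             V0=s["V0"], a0=s["a0"], eta=s.get("eta", 1.0))
    return out


def load_pressure_law_toml(path):
    """Build a pressure law from the ``[pressure]`` section plus its force."""
    with open(Path(path), "rb") as fh:
        cfg = tomllib.load(fh)
    if "pressure" not in cfg:
        raise ValueError(f"{path}: missing [pressure] section")
    p = cfg["pressure"]
    kind = p["kind"]
    forces = load_forces_toml(path)
    if kind == "cbm":
        force_key = p.get("force", "cbm_exp")
        return CBMPressureLaw(forces[force_key], d=p.get("d", 1),
                              J=p.get("J"), mu=p.get("mu", 1.0))
    if kind == "weliky_oster":
        wo = forces["wo"]
        return WOPressureLaw(sigma=wo.sigma, kappa=wo.kappa,
                             J=p.get("J", 6), mu=p.get("mu", 1.0))
    if kind == "power_law":
        return PowerLawPressure(K=p["K"], gamma=p["gamma"], mu=p.get("mu", 1.0))
    raise ValueError(f"unknown pressure kind {kind!r}")
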