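"""Resistance surfaces and circuit-theory effective resistance on rasters.

A resistance surface assigns every raster cell a positive cost to gene
flow.  The raster is turned into a resistor network (cells = nodes, edges
between 8- or 4-neighbours, edge conductance = mean of the two cell
conductances, diagonal edges scaled by 1/sqrt(2)), and the effective
resistance between the cells containing two sample points is the
two-terminal resistance of that network, obtained from the graph Laplacian.
Effective resistance is a metric: symmetric, zero only within a cell, and
satisfying the triangle inequality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .rasters import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ResistanceSurface",
    "ResistanceDistanceMatrix",
    "build_resistance_surface",
    "pairwise_circuit_resistance",
]

#: smallest admissible cell resistance after sanitization
RESISTANCE_FLOOR = 0.001


@dataclass
class ResistanceSurface:
    """A raster of strictly positive, finite resistance values."""

    grid: RasterGrid
    provenance: str = "raw"

    def __post_init__(self) -> None:
        v = self.grid.values
        finite = v[~np.isnan(v)]
        if finite.size == 0:
            raise ValueError("resistance surface has no valid cells")
        if (finite < 0).any():
            raise ValueError("negative resistance values")
        if (finite < RESISTANCE_FLOOR).any():
            raise ValueError(f"resistance values below the floor {RESISTANCE_FLOOR}")


def build_resistance_surface(
    raster: RasterGrid,
    mode: str = "raw",
    habitat_classes: tuple = (1,),
    habitat_resistance: float = 0.1,
    nonhabitat_resistance: float = 0.9,
    null_value: float = 0.5,
    points: pd.DataFrame | None = None,
    buffer_deg: float = 1.0,
    provenance: str | None = None,
) -> ResistanceSurface:
    """Derive a resistance surface from a raw raster layer.

    Modes:

    ``habitat``
        cells whose value is in ``habitat_classes`` get low resistance
        (default 0.1), all others high (default 0.9);
    ``invert``
        max(value) - value (e.g. inverted forest cover, so open land
        resists movement);
    ``raw``
        values used directly (elevation, roughness, climate layers);
    ``null``
        every valid cell set to a constant (default 0.5) - the
        geographic-distance-only surface.

    When ``points`` (a frame with lon/lat columns) is given, the raster is
    cropped to the point extent plus ``buffer_deg`` decimal degrees to limit
    boundary effects.  Zero-valued cells are raised to 0.001.
    """
    grid = raster.copy()
    if points is not None:
        lon = points["lon"].to_numpy(float)
        lat = points["lat"].to_numpy(float)
        grid = grid.crop(lon.min() - buffer_deg, lat.min() - buffer_deg,
                         lon.max() + buffer_deg, lat.max() + buffer_deg)
    v = grid.values
    valid = ~np.isnan(v)
    if mode == "habitat":
        out = np.where(np.isin(v, np.asarray(habitat_classes, dtype=float)),
                       habitat_resistance, nonhabitat_resistance)
    elif mode == "invert":
        out = np.nanmax(v) - v
    elif mode == "raw":
        out = v.copy()
    elif mode == "null":
        out = np.full_like(v, null_value)
    else:
        raise ValueError(f"unknown resistance mode {mode!r}")
    out = np.where(valid, out, np.nan)
    finite = out[valid]
    if (finite < 0).any():
        raise ValueError("transform produced negative resistances")
    out[valid & (out < RESISTANCE_FLOOR)] = RESISTANCE_FLOOR
    grid.values = out
    tag = provenance if provenance is not None else {
        "habitat": "habitat", "invert": "inverted", "raw": "raw",
        "null": "geographic_null",
    }[mode]
    return ResistanceSurface(grid, tag)


@dataclass
class ResistanceDistanceMatrix:
    """Symmetric matrix of pairwise effective resistances between points."""

    values: np.ndarray
    provenance: str
    point_ids: list

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("resistance distance matrix must be square")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        finite = v[np.isfinite(v)]
        if (finite < -1e-9).any():
            raise ValueError("effective resistances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.point_ids, columns=self.point_ids)


def _grid_laplacian(res: np.ndarray, neighborhood: int, averaging: str):
    """Sparse Laplacian of the cell network; returns (L, node index grid)."""
    nrows, ncols = res.shape
    valid = ~np.isnan(res)
    node = -np.ones(res.shape, dtype=np.int64)
    node[valid] = np.arange(valid.sum())
    cond = 1.0 / res

    if neighborhood == 8:
        offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, 1.0 / np.sqrt(2.0)),
                   (1, -1, 1.0 / np.sqrt(2.0))]
    elif neighborhood == 4:
        offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    else:
        raise ValueError("neighborhood must be 4 or 8")

    rows, cols, vals = [], [], []
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a_ok = valid[r0, c0] & valid[r1, c1]
        na = node[r0, c0][a_ok]
        nb = node[r1, c1][a_ok]
        if averaging == "conductance":
            g = 0.5 * (cond[r0, c0][a_ok] + cond[r1, c1][a_ok])
        elif averaging == "resistance":
            g = 1.0 / (0.5 * (res[r0, c0][a_ok] + res[r1, c1][a_ok]))
        else:
            raise ValueError("averaging must be 'conductance' or 'resistance'")
        g = g * scale
        rows.extend([na, nb])
        cols.extend([nb, na])
        vals.extend([-g, -g])
    n_nodes = int(valid.sum())
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    vals = np.concatenate(vals) if vals else np.empty(0)
    off = sp.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    deg = -np.asarray(off.sum(axis=1)).ravel()
    lap = off + sp.diags(deg)
    return lap.tocsc(), node


def pairwise_circuit_resistance(
    surface: ResistanceSurface,
    points: pd.DataFrame,
    neighborhood: int = 8,
    averaging: str = "conductance",
) -> ResistanceDistanceMatrix:
    """Effective resistance between the raster cells holding each point.

    Solves the grounded graph-Laplacian system once per focal node (sparse
    LU factorization shared across solves) and recovers all pairwise
    resistances from the node potentials:
    R(i, j) = u_i[i] + u_j[j] - u_i[j] - u_j[i], where u_k solves
    L_grounded u_k = e_k.  Points sharing a cell are at resistance zero;
    disconnected pairs are reported as infinite with a warning.
    """
    grid = surface.grid
    n_pts = len(points)
    ids = (points["id"].tolist() if "id" in points.columns else list(range(n_pts)))
    lap, node = _grid_laplacian(grid.values, neighborhood, averaging)

    focal = np.empty(n_pts, dtype=np.int64)
    for k, (lon, lat) in enumerate(zip(points["lon"], points["lat"])):
        r, c = grid.index_of(float(lon), float(lat))
        if node[r, c] < 0:
            raise ValueError(f"point ({lon}, {lat}) falls on a nodata cell")
        focal[k] = node[r, c]

    n_nodes = lap.shape[0]
    n_comp, labels = connected_components(-lap, directed=False)
    comp = labels[focal]
    out = np.zeros((n_pts, n_pts))
    if n_comp > 1 and len(set(comp)) > 1:
        warnings.warn("some point pairs are disconnected; reporting infinite resistance")

    uniq, inv = np.unique(focal, return_inverse=True)
    # one grounded solve per unique focal node, per connected component
    potentials = {}
    for comp_id in set(labels[uniq]):
        nodes_in = np.flatnonzero(labels == comp_id)
        if nodes_in.size == 1:
            for f in uniq[labels[uniq] == comp_id]:
                potentials[f] = {f: 0.0}
            continue
        ground = nodes_in[0]
        sub_index = -np.ones(n_nodes, dtype=np.int64)
        keep = nodes_in[nodes_in != ground]
        sub_index[keep] = np.arange(keep.size)
        lg = lap[np.ix_(keep, keep)].tocsc()
        lu = splu(lg)
        foc_here = uniq[labels[uniq] == comp_id]
        for f in foc_here:
            if f == ground:
                potentials[f] = {g: 0.0 for g in foc_here}
                continue
            rhs = np.zeros(keep.size)
            rhs[sub_index[f]] = 1.0
            u = lu.solve(rhs)
            pot = {}
            for g in foc_here:
                pot[g] = 0.0 if g == ground else float(u[sub_index[g]])
            potentials[f] = pot

    for a in range(n_pts):
        for b in range(a + 1, n_pts):
            fa, fb = focal[a], focal[b]
            if fa == fb:
                out[a, b] = out[b, a] = 0.0
            elif comp[a] != comp[b]:
                out[a, b] = out[b, a] = np.inf
            else:
                r = (potentials[fa][fa] + potentials[fb][fb]
                     - potentials[fa][fb] - potentials[fb][fa])
                out[a, b] = out[b, a] = max(r, 0.0)
    return ResistanceDistanceMatrix(out, surface.provenance, ids)
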