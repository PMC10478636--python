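"""Rasterization of the annotated channel graph and CCP4 map export.

Channels are visualized dynamically: a grid over one unit cell stores, at
every point, the local bottleneck radius of the largest vertex free-space
sphere containing the point.  Displaying the map at isolevel r' then shows
exactly the space a sphere of radius r' can roam on an infinite periodic
path.  Two auxiliary modes store the local clearance radius (sphere may be
placed, but possibly not moved) and the plain distance to the nearest atom
surface.  Maps must be contoured at absolute radius values, not at sigma
levels.

Grids are written as CCP4/MRC mode-2 maps covering exactly one unit cell
(axis order X fastest, start 0,0,0, map-header symmetry P1 — the grid values
already incorporate the crystal symmetry).
"""
from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .bottleneck_engine import BottleneckAnnotation
from .channel_graph import ChannelGraph
from .crystal_io import CellGeometry
from .errors import MemoryCapError

MODE_BOTTLENECK = "bottleneck"
MODE_LOCAL_RADIUS = "local_radius"
MODE_ATOM_DISTANCE = "atom_distance"

DEFAULT_SPACING = 0.5  # A
MAX_GRID_POINTS = 64_000_000


@dataclass
class RadiusGrid:
    """Regular grid over one unit cell holding radii in Angstrom."""

    values: np.ndarray        # (nx, ny, nz) float32
    cell: CellGeometry
    mode: str
    spacing: float

    @property
    def dimensions(self):
        return self.values.shape


def _grid_shape(cell: CellGeometry, spacing: float):
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = tuple(int(np.ceil(L / spacing)) for L in cell.lengths)
    if int(np.prod(n)) > MAX_GRID_POINTS:
        suggestion = spacing * (np.prod(n) / MAX_GRID_POINTS) ** (1 / 3)
        raise MemoryCapError(
            f"grid of {n} points exceeds the memory cap; "
            f"use a spacing of at least {suggestion:.2f} A")
    return n


def rasterize(graph: ChannelGraph, annotation: BottleneckAnnotation,
              spacing: float = DEFAULT_SPACING, mode: str = MODE_BOTTLENECK,
              atoms: np.ndarray = None, r_u: float = 1.7) -> RadiusGrid:
    """Convert the annotated channel graph into a unit-cell radius grid.

    ``mode=bottleneck``: value = max r_b(v) over vertex spheres containing
    the point.  ``mode=local_radius``: max r(v) instead.
    ``mode=atom_distance``: distance to the nearest atom surface (requires
    ``atoms``, Cartesian positions of the unit-cell contents); negative
    inside atoms.
    """
    cell = graph.cell
    n = _grid_shape(cell, spacing)
    values = np.zeros(n, dtype=np.float64)

    if mode == MODE_ATOM_DISTANCE:
        if atoms is None or len(atoms) == 0:
            raise ValueError("atom_distance mode needs atom positions")
        values = _distance_grid(atoms, cell, n) - r_u
        return RadiusGrid(values.astype(np.float32), cell, mode, spacing)
    if mode not in (MODE_BOTTLENECK, MODE_LOCAL_RADIUS):
        raise ValueError(f"unknown grid mode {mode!r}")

    nvec = np.array(n)
    F = cell.frac_matrix
    # fractional half-extent of a Cartesian sphere per axis
    frac_per_A = np.linalg.norm(F, axis=1)
    vert_val = (annotation.per_vertex_overall if mode == MODE_BOTTLENECK
                else graph.vert_r)
    order = np.argsort(vert_val)   # ascending; later (larger) wins ties
    for v in order:
        val = vert_val[v]
        r = graph.vert_r[v]
        if r <= 0 or val <= 0:
            continue
        center = graph.vert_pos[v]
        cf = F @ center
        lo = np.floor((cf - r * frac_per_A) * nvec).astype(int)
        hi = np.ceil((cf + r * frac_per_A) * nvec).astype(int)
        ii = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
        gi, gj, gk = np.meshgrid(*ii, indexing="ij")
        fr = np.stack([gi / nvec[0], gj / nvec[1], gk / nvec[2]], axis=-1)
        pts = fr @ cell.cart_matrix.T
        inside = ((pts - center) ** 2).sum(-1) <= r * r
        if not inside.any():
            continue
        wi, wj, wk = (gi[inside] % n[0], gj[inside] % n[1],
                      gk[inside] % n[2])
        np.maximum.at(values, (wi, wj, wk), val)
    return RadiusGrid(values.astype(np.float32), cell, mode, spacing)


def _distance_grid(atoms: np.ndarray, cell: CellGeometry, n) -> np.ndarray:
    """Periodic distance from every grid point to the nearest atom center."""
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                  indexing="ij")).reshape(3, -1).T
    frac = atoms @ cell.frac_matrix.T
    frac -= np.floor(frac)
    tiled = (frac[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tree = cKDTree(tiled @ cell.cart_matrix.T)
    ii = [np.arange(n[k]) / n[k] for k in range(3)]
    gi, gj, gk = np.meshgrid(*ii, indexing="ij")
    pts = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3) @ cell.cart_matrix.T
    d, _ = tree.query(pts)
    return d.reshape(n)


# --------------------------------------------------------------------------
# CCP4 I/O
# --------------------------------------------------------------------------

def write_ccp4(grid: RadiusGrid, path) -> None:
    """Write a mode-2 (float32) CCP4/MRC map covering one unit cell."""
    g = gemmi.FloatGrid(*grid.dimensions)
    g.set_unit_cell(gemmi.UnitCell(grid.cell.a, grid.cell.b, grid.cell.c,
                                   grid.cell.alpha, grid.cell.beta,
                                   grid.cell.gamma))
    g.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    g.array[:] = grid.values
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_ccp4(path) -> RadiusGrid:
    """Read back a map written by :func:`write_ccp4`."""
    m = gemmi.read_ccp4_map(str(path))
    uc = m.grid.unit_cell
    cell = CellGeometry(uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma, "P 1")
    values = np.array(m.grid.array, dtype=np.float32)
    spacing = float(np.mean([uc.a / values.shape[0], uc.b / values.shape[1],
                             uc.c / values.shape[2]]))
    return RadiusGrid(values=values, cell=cell, mode=MODE_BOTTLENECK,
                      spacing=spacing)
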