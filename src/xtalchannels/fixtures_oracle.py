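"""Synthetic P1 crystals with analytically known channel geometry.

Real crystal structures cannot ship with the test suite, and their channel
geometry is not known in closed form anyway.  These generators build toy P1
crystals realizing the archetypal channel topologies — an open cubic lattice,
a straight tube, a tube whose periodic images do not line up (blocked), a
zigzag corridor that only closes through a neighboring cell, and a dead-end
cavity behind a throat — with expected bottleneck radii derived from pure
geometry at generation time (wall fixtures report the exact min distance of
the corridor centerline to the placed wall atoms, i.e. the analytic corridor
width including the wall-atom discretization correction).

A grid-based flood-fill oracle, the classical distance-map approach to
channel detection, provides an independent per-axis bottleneck estimate that
the Voronoi pipeline must match within the grid discretization bound
(half the maximal point-to-grid distance, sqrt(3)/2 * spacing).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .crystal_io import AtomSphere, CellGeometry, POLYMER, Structure

DEFAULT_RU = 1.7
WALL_SPACING = 1.0  # A, wall atom grid


@dataclass
class SyntheticCrystal:
    """A P1 toy crystal plus its analytically expected channel answer."""

    structure: Structure
    description: str
    # per-axis expected bottleneck radius in A, or None for "blocked"
    expected_axis: tuple = (None, None, None)

    @property
    def cell(self) -> CellGeometry:
        return self.structure.cell

    @property
    def expected_main(self):
        vals = [v for v in self.expected_axis if v is not None]
        return max(vals) if vals else None

    def write_pdb(self, path) -> None:
        """Write as a legitimate P1 PDB (CRYST1 + ATOM records)."""
        import gemmi
        st = gemmi.Structure()
        st.cell = gemmi.UnitCell(self.cell.a, self.cell.b, self.cell.c,
                                 self.cell.alpha, self.cell.beta,
                                 self.cell.gamma)
        st.spacegroup_hm = "P 1"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i, at in enumerate(self.structure.atoms):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(i % 9999 + 1, " ")
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element(at.element)
            a.pos = gemmi.Position(*at.position)
            a.occ = 1.0
            res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


def _structure_from_frac(frac: np.ndarray, cell: CellGeometry,
                         element: str = "C") -> Structure:
    pos = cell.to_cart(frac)
    atoms = [AtomSphere(position=p, element=element, name="CA", resname="GLY",
                        residue_id=("A", i % 9999 + 1, ""), component=POLYMER)
             for i, p in enumerate(pos)]
    return Structure(atoms=atoms, cell=cell)


def make_cubic_lattice(a: float, r_u: float = DEFAULT_RU,
                       base_frac=(0.0, 0.0, 0.0)) -> SyntheticCrystal:
    """One atom per cubic cell of side ``a``.

    The widest periodic path runs along a cell axis through the face
    centers, whose nearest atoms are the four face corners at distance
    a/sqrt(2); the expected per-axis bottleneck is a/sqrt(2) - r_u.
    """
    if a <= 2 * r_u:
        raise ValueError("cell too small for the unified radius")
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    expected = a / np.sqrt(2.0) - r_u
    st = _structure_from_frac(np.array([base_frac]), cell)
    return SyntheticCrystal(st, f"cubic lattice a={a}",
                            (expected, expected, expected))


# --------------------------------------------------------------------------
# carved-wall fixtures
# --------------------------------------------------------------------------

def _segment_distance(points: np.ndarray, p0: np.ndarray,
                      p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    L2 = float(d @ d)
    if L2 < 1e-18:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ d / L2, 0.0, 1.0)
    return np.linalg.norm(points - (p0 + t[:, None] * d), axis=1)


def _carve(cell: CellGeometry, polylines, carve_radius: float,
           spheres=(), wall_spacing: float = WALL_SPACING):
    """Fill the cell with a wall-atom grid, then delete atoms within
    ``carve_radius`` of any periodic image of the given polylines/spheres."""
    n = max(2, int(round(cell.a / wall_spacing)))
    ii = np.arange(n) / n
    gi, gj, gk = np.meshgrid(ii, ii, ii, indexing="ij")
    frac = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
    pts = cell.to_cart(frac)

    solvent = np.zeros(len(pts), dtype=bool)
    for shift in _neighbor_shifts():
        off = cell.to_cart(shift.astype(float))
        for poly in polylines:
            pc = cell.to_cart(np.asarray(poly, float)) + off
            for p0, p1 in zip(pc[:-1], pc[1:]):
                solvent |= _segment_distance(pts, p0, p1) < carve_radius
        for center, radius in spheres:
            c = cell.to_cart(np.asarray(center, float)) + off
            solvent |= np.linalg.norm(pts - c, axis=1) < radius
    return frac[~solvent]


def _neighbor_shifts():
    return np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                indexing="ij")).reshape(3, -1).T


def _centerline_clearance(cell: CellGeometry, kept_frac: np.ndarray,
                          polyline, r_u: float,
                          n_samples: int = 400) -> float:
    """Exact corridor bottleneck along a centerline: min over centerline
    samples of the periodic distance to the kept wall atoms, minus r_u."""
    tiled = (kept_frac[None, :, :]
             + _neighbor_shifts()[:, None, :]).reshape(-1, 3)
    tree = cKDTree(cell.to_cart(tiled))
    poly = np.asarray(polyline, float)
    samples = []
    for p0, p1 in zip(poly[:-1], poly[1:]):
        t = np.linspace(0, 1, max(2, int(n_samples
                                         * np.linalg.norm(p1 - p0))))
        samples.append(p0 + t[:, None] * (p1 - p0))
    pts = cell.to_cart(np.concatenate(samples))
    d, _ = tree.query(pts)
    return float(d.min()) - r_u


def make_straight_tube(a: float = 12.0, carve_radius: float = 4.0,
                       r_u: float = DEFAULT_RU) -> SyntheticCrystal:
    """A straight cylindrical channel along x; open along x only."""
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    poly = [(-0.1, 0.5, 0.5), (1.1, 0.5, 0.5)]
    kept = _carve(cell, [poly], carve_radius)
    st = _structure_from_frac(kept, cell)
    clearance = _centerline_clearance(cell, kept, poly, r_u)
    return SyntheticCrystal(st, f"straight tube a={a}",
                            (clearance, None, None))


def make_blocked_channel(a: float = 12.0, offset_frac: float = 0.5,
                         carve_radius: float = 2.6,
                         r_u: float = DEFAULT_RU) -> SyntheticCrystal:
    """A tube traversing the cell whose exit is laterally displaced by
    ``offset_frac``: its periodic images do not line up, so no macroscopic
    path exists although a single-cell view shows a traversing void."""
    if not 0.0 < offset_frac < 1.0:
        # offset 0 degenerates to the open straight tube
        if offset_frac == 0.0:
            return make_straight_tube(a, carve_radius, r_u)
        raise ValueError("offset_frac must be in [0, 1)")
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    y0 = 0.5 - offset_frac / 2.0
    poly = [(-0.05, y0, 0.5), (1.05, y0 + offset_frac, 0.5)]
    kept = _carve(cell, [poly], carve_radius)
    st = _structure_from_frac(kept, cell)
    return SyntheticCrystal(st, f"blocked channel offset={offset_frac}",
                            (None, None, None))


ZIGZAG_POLYLINE = [(-0.05, 0.25, 0.5), (0.25, 0.25, 0.5), (0.25, 0.75, 0.5),
                   (0.75, 0.75, 0.5), (0.75, 1.25, 0.5), (1.05, 1.25, 0.5)]


def make_zigzag_channel(a: float = 15.0, carve_radius: float = 3.6,
                        r_u: float = DEFAULT_RU) -> SyntheticCrystal:
    """A corridor with lattice period (1, 1, 0): it exits +x at one face
    position, re-enters -x at another, and only closes into a periodic path
    through a y-face crossing.  Detecting it requires the artificial
    periodic edges on the faces orthogonal to the swept axis.  Open along
    x and y (same corridor bottleneck), blocked along z."""
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    kept = _carve(cell, [ZIGZAG_POLYLINE], carve_radius)
    st = _structure_from_frac(kept, cell)
    clearance = _centerline_clearance(cell, kept, ZIGZAG_POLYLINE, r_u)
    return SyntheticCrystal(st, f"zigzag corridor a={a}",
                            (clearance, clearance, None))


def make_tube_with_side_cavity(a: float = 14.0, tube_radius: float = 3.4,
                               throat_radius: float = 2.4,
                               cavity_radius: float = 2.6,
                               r_u: float = DEFAULT_RU):
    """Straight tube along x plus an enclosed side cavity reachable only
    through a narrower throat.  Returns (crystal, tube clearance, throat
    clearance, cavity center fractional): cavity vertices must inherit the
    throat bottleneck, not their own larger local radius.  The throat is
    narrower than the default cutoff — analyze with a lowered r_min."""
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    tube = [(-0.1, 0.22, 0.5), (1.1, 0.22, 0.5)]
    cav_center = (0.5, 0.8, 0.5)
    throat = [(0.5, 0.22, 0.5), cav_center]
    kept = _carve(cell, [tube, throat], tube_radius,
                  spheres=[(cav_center, cavity_radius)])
    # re-carve: throat uses its own, smaller radius
    kept2 = _carve(cell, [tube], tube_radius,
                   spheres=[(cav_center, cavity_radius)])
    frac_throat = _carve_keep_only(cell, kept2, throat, throat_radius)
    st = _structure_from_frac(frac_throat, cell)
    tube_clear = _centerline_clearance(cell, frac_throat, tube, r_u)
    throat_clear = _centerline_clearance(cell, frac_throat, throat, r_u)
    return (SyntheticCrystal(st, "tube with side cavity",
                             (tube_clear, None, None)),
            tube_clear, throat_clear, np.array(cav_center))


def make_enclosed_cavity(a: float = 12.0, cavity_radius: float = 3.0,
                         r_u: float = DEFAULT_RU) -> SyntheticCrystal:
    """A spherical void with no outlet at all: reachable by nothing, so all
    its Voronoi vertices must carry a zero bottleneck radius (a fully
    enclosed void, the degenerate pocket case)."""
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    kept = _carve(cell, [], 0.0, spheres=[((0.5, 0.5, 0.5), cavity_radius)])
    st = _structure_from_frac(kept, cell)
    return SyntheticCrystal(st, "enclosed cavity", (None, None, None))


def _carve_keep_only(cell, kept_frac, polyline, radius):
    pts = cell.to_cart(kept_frac)
    solvent = np.zeros(len(pts), dtype=bool)
    for shift in _neighbor_shifts():
        off = cell.to_cart(shift.astype(float))
        pc = cell.to_cart(np.asarray(polyline, float)) + off
        for p0, p1 in zip(pc[:-1], pc[1:]):
            solvent |= _segment_distance(pts, p0, p1) < radius
    return kept_frac[~solvent]


# --------------------------------------------------------------------------
# grid flood-fill oracle
# --------------------------------------------------------------------------

class _LabelUF:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent
        while p.setdefault(x, x) != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _shift2(arr: np.ndarray, d0: int, d1: int, wrap0: bool) -> np.ndarray:
    """Shift a 2D label slab by (d0, d1); axis 1 always wraps (periodic),
    axis 0 wraps only when ``wrap0`` (it may be the non-periodic swept axis)."""
    out = np.roll(arr, d1, axis=1)
    if d0 == 0:
        return out
    if wrap0:
        return np.roll(out, d0, axis=0)
    shifted = np.zeros_like(out)
    if d0 > 0:
        shifted[d0:] = out[:-d0]
    else:
        shifted[:d0] = out[-d0:]
    return shifted


def _axis_traversable(clearance: np.ndarray, axis: int, r: float) -> bool:
    """Can a sphere of radius r traverse the cell periodically along axis?

    Components are computed with 26-connectivity, periodic wrap on the two
    orthogonal axes and *no* wrap along the swept axis; traversal holds when
    a component contains a low-face cell and a high-face cell adjacent to it
    across the periodic boundary (the face regions project onto each other).
    """
    mask = np.moveaxis(clearance, axis, 0) >= r
    if not mask.any():
        return False
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    uf = _LabelUF()

    def merge_wrap(arr_lo, arr_hi, wrap0):
        # 26-connectivity across a periodic face: lo adjacent to shifted hi
        for d0 in (-1, 0, 1):
            for d1 in (-1, 0, 1):
                h = _shift2(arr_hi, d0, d1, wrap0)
                both = (arr_lo > 0) & (h > 0)
                for la, lb in zip(arr_lo[both].ravel(), h[both].ravel()):
                    uf.union(int(la), int(lb))

    # slabs have axes (swept, other-orthogonal): swept must not wrap
    merge_wrap(labels[:, 0, :], labels[:, -1, :], wrap0=False)
    merge_wrap(labels[:, :, 0], labels[:, :, -1], wrap0=False)

    lo = labels[0]   # axes: the two orthogonal (periodic) directions
    hi = labels[-1]
    for d0 in (-1, 0, 1):
        for d1 in (-1, 0, 1):
            h = _shift2(hi, d0, d1, wrap0=True)
            both = (lo > 0) & (h > 0)
            for la, lb in zip(lo[both].ravel(), h[both].ravel()):
                if uf.find(int(la)) == uf.find(int(lb)):
                    return True
    return False


def _axis_traversable_single_cell(clearance: np.ndarray, axis: int,
                                  r: float) -> bool:
    """Naive single-cell view: does *any* void connect the two faces,
    ignoring whether the crossings project onto each other periodically?
    This is the check that wrongly calls a laterally displaced channel
    traversable."""
    mask = np.moveaxis(clearance, axis, 0) >= r
    if not mask.any():
        return False
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    lo = set(np.unique(labels[0])) - {0}
    hi = set(np.unique(labels[-1])) - {0}
    return bool(lo & hi)


def grid_flood_oracle(atoms_cart: np.ndarray, cell: CellGeometry,
                      spacing: float = 0.4, r_u: float = DEFAULT_RU,
                      single_cell: bool = False) -> dict:
    """Independent per-axis bottleneck estimates from a periodic distance
    grid + flood fill, accurate to ~sqrt(3)/2 * spacing.

    ``single_cell=True`` switches to the naive non-periodic face-to-face
    check (the motivating failure mode the periodic model corrects)."""
    from .maps_descriptors import _distance_grid
    check = (_axis_traversable_single_cell if single_cell
             else _axis_traversable)
    n = tuple(max(3, int(np.ceil(L / spacing))) for L in cell.lengths)
    clearance = _distance_grid(np.asarray(atoms_cart, float), cell, n) - r_u

    out = {}
    values = np.unique(clearance[clearance > 0])
    for axis in range(3):
        if len(values) == 0 or not check(clearance, axis, values[0]):
            out[axis] = 0.0
            continue
        lo_i, hi_i = 0, len(values) - 1   # invariant: values[lo_i] passes
        while lo_i < hi_i:
            mid = (lo_i + hi_i + 1) // 2
            if check(clearance, axis, values[mid]):
                lo_i = mid
            else:
                hi_i = mid - 1
        out[axis] = float(values[lo_i])
    return out


def oracle_bound(spacing: float) -> float:
    """Discretization bound of the grid oracle: half the largest distance of
    any point to its nearest grid node, plus a small numerical allowance."""
    return np.sqrt(3.0) * spacing / 2.0 + 0.05
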