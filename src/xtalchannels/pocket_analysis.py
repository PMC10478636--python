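"""Binding-pocket definition and pocket bottleneck radii.

A pocket is defined either from a bound ligand instance (every residue with
an atom within 6.5 A of any ligand atom, threshold inclusive) or from an
explicit residue list / PDB fragment.  The pocket space is the convex hull
of all pocket-residue atoms.  The question the soaking experimenter asks is
not whether Voronoi elements exist *inside* that hull — the binding event
itself is outside the model — but how wide a sphere can come *up to* the
pocket: r_b,poc is the largest local bottleneck radius among channel-graph
vertices within a search shell around the hull.

Because the channel graph lives in one unit cell while the pocket hull sits
wherever the asymmetric unit was deposited, vertex-to-hull distances are
minimized over the 27 neighboring lattice translates of each vertex.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .bottleneck_engine import (BottleneckAnnotation, locate_bottleneck)
from .channel_graph import ChannelGraph
from .crystal_io import Structure, WATER
from .errors import BottleneckNotFoundError, DegeneratePocketError

logger = logging.getLogger(__name__)

POCKET_RESIDUE_RADIUS = 6.5   # A, ligand-derived residue selection
DEFAULT_SEARCH_DISTANCE = 4.0  # A, shell around the hull (one hydration shell)

STATUS_OK = "ok"
STATUS_NO_ELEMENTS = "no_voronoi_elements"
STATUS_ENCLOSED_VOID = "enclosed_void"


@dataclass
class PocketDefinition:
    """Residue set + convex hull describing one binding pocket."""

    residues: set                 # residue_id tuples
    atom_positions: np.ndarray    # (N, 3) all atoms of pocket residues
    hull: ConvexHull = None       # None when degenerate (flat site)

    @property
    def degenerate(self) -> bool:
        return self.hull is None


@dataclass
class PocketResult:
    r_b_poc: float                 # widest access radius in the search shell
    inside_radius: float           # max r_b(v) of vertices inside the hull
    bottleneck_position: np.ndarray = None
    status: str = STATUS_OK
    n_shell_vertices: int = 0


def define_pocket(structure: Structure, ligand=None, residues=None,
                  radius: float = POCKET_RESIDUE_RADIUS) -> PocketDefinition:
    """Build a pocket from a ligand spec or an explicit residue id list.

    ``ligand`` is ``(resname, chain, resseq)`` with chain/resseq optional
    (None matches any instance).  A flat or too-small site yields a
    degenerate pocket (``hull is None``); downstream analysis reports the
    ``no_voronoi_elements`` status for it, mirroring the behavior on shallow
    surface sites.
    """
    if ligand is None and not residues:
        raise ValueError("either a ligand spec or a residue list is required")

    if ligand is not None:
        resname, chain, resseq = (tuple(ligand) + (None, None))[:3]
        lig_atoms = [a for a in structure.atoms
                     if a.resname.upper() == resname.upper()
                     and (chain is None or a.residue_id[0] == chain)
                     and (resseq is None or a.residue_id[1] == int(resseq))]
        if not lig_atoms:
            raise ValueError(f"ligand {ligand} not found in structure")
        lig_pos = np.array([a.position for a in lig_atoms])
        selected = set()
        for a in structure.atoms:
            if a.component == WATER or a in lig_atoms:
                continue
            d = np.linalg.norm(lig_pos - a.position, axis=1).min()
            if d <= radius + 1e-9:        # inclusive threshold
                selected.add(a.residue_id)
        lig_ids = {a.residue_id for a in lig_atoms}
        selected -= lig_ids
    else:
        selected = set(map(tuple, residues))

    pocket_atoms = [a.position for a in structure.atoms
                    if a.residue_id in selected and not a.is_hydrogen]
    pos = np.array(pocket_atoms).reshape(-1, 3)
    hull = None
    if len(pos) >= 4:
        try:
            hull = ConvexHull(pos)
            if hull.volume < 1e-6:
                hull = None
        except QhullError:
            hull = None
    if hull is None:
        logger.warning("degenerate (flat) pocket hull: %d atoms, "
                       "%d residues", len(pos), len(selected))
    return PocketDefinition(residues=selected, atom_positions=pos, hull=hull)


def residues_from_pdb_fragment(path) -> set:
    """Residue ids from a PDB fragment listing binding-site residues."""
    import gemmi
    st = gemmi.read_structure(str(path))
    out = set()
    for model in st:
        for chain in model:
            for res in chain:
                out.add((chain.name, res.seqid.num, res.seqid.icode.strip()))
        break
    return out


# --------------------------------------------------------------------------
# hull distances
# --------------------------------------------------------------------------

def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance from each point to a set of triangles (vectorized
    per point over triangles; standard region-based closest-point test)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    out = np.empty(len(points))
    for i, p in enumerate(points):
        ap = p - a
        d1 = (ab * ap).sum(1)
        d2 = (ac * ap).sum(1)
        bp = p - b
        d3 = (ab * bp).sum(1)
        d4 = (ac * bp).sum(1)
        cp = p - c
        d5 = (ab * cp).sum(1)
        d6 = (ac * cp).sum(1)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        v = np.where(np.abs(denom) > 1e-30, vb / np.where(denom == 0, 1, denom), 0)
        w = np.where(np.abs(denom) > 1e-30, vc / np.where(denom == 0, 1, denom), 0)
        closest = a + v[:, None] * ab + w[:, None] * ac

        # vertex regions
        m = (d1 <= 0) & (d2 <= 0)
        closest[m] = a[m]
        m = (d3 >= 0) & (d4 <= d3)
        closest[m] = b[m]
        m = (d6 >= 0) & (d5 <= d6)
        closest[m] = c[m]
        # edge AB
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        if m.any():
            t = d1[m] / (d1[m] - d3[m])
            closest[m] = a[m] + t[:, None] * ab[m]
        # edge AC
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        if m.any():
            t = d2[m] / (d2[m] - d6[m])
            closest[m] = a[m] + t[:, None] * ac[m]
        # edge BC
        m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        if m.any():
            t = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
            closest[m] = b[m] + t[:, None] * (c[m] - b[m])

        out[i] = np.sqrt(((p - closest) ** 2).sum(1).min())
    return out


def distance_to_hull(points: np.ndarray, hull: ConvexHull) -> np.ndarray:
    """Euclidean distance to a convex hull; 0 for interior points."""
    points = np.atleast_2d(points)
    eq = hull.equations
    inside = (points @ eq[:, :3].T + eq[:, 3] <= 1e-9).all(axis=1)
    out = np.zeros(len(points))
    if (~inside).any():
        tri = hull.points[hull.simplices]
        out[~inside] = _point_triangle_distances(points[~inside], tri)
    return out


def pocket_bottleneck(graph: ChannelGraph, annotation: BottleneckAnnotation,
                      pocket: PocketDefinition,
                      search_distance: float = DEFAULT_SEARCH_DISTANCE
                      ) -> PocketResult:
    """r_b,poc: widest bottleneck radius within reach of the pocket hull."""
    if search_distance <= 0:
        raise ValueError("search_distance must be positive")
    if pocket.degenerate:
        raise DegeneratePocketError(
            "pocket hull is flat or has fewer than 4 non-coplanar atoms")
    if graph.n_vertices == 0:
        return PocketResult(0.0, 0.0, status=STATUS_NO_ELEMENTS)

    # minimum image: consider all 27 lattice translates of every vertex
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                  indexing="ij")).reshape(3, -1).T
    lat = shifts @ graph.cell.cart_matrix.T
    best = np.full(graph.n_vertices, np.inf)
    inside_any = np.zeros(graph.n_vertices, dtype=bool)
    for s in lat:
        pts = graph.vert_pos + s
        # cheap prefilter on the hull bounding box
        lo = pocket.atom_positions.min(0) - search_distance - 1e-9
        hi = pocket.atom_positions.max(0) + search_distance + 1e-9
        cand = np.all((pts >= lo) & (pts <= hi), axis=1)
        if not cand.any():
            continue
        d = distance_to_hull(pts[cand], pocket.hull)
        idx = np.nonzero(cand)[0]
        closer = d < best[idx]
        best[idx[closer]] = d[closer]
        inside_any[idx[d == 0.0]] = True

    in_shell = best <= search_distance
    if not in_shell.any():
        return PocketResult(0.0, 0.0, status=STATUS_NO_ELEMENTS)

    rb = annotation.per_vertex_overall
    r_b_poc = float(rb[in_shell].max())
    inside_radius = float(rb[inside_any].max()) if inside_any.any() else 0.0
    if r_b_poc <= 0.0:
        return PocketResult(0.0, inside_radius, status=STATUS_ENCLOSED_VOID,
                            n_shell_vertices=int(in_shell.sum()))

    pos = None
    start = np.nonzero(in_shell & (rb >= r_b_poc - 1e-12))[0]
    try:
        pos, _ = locate_bottleneck(graph, annotation, r_b_poc, start)
    except BottleneckNotFoundError:
        logger.warning("pocket bottleneck edge not located")
    return PocketResult(r_b_poc, inside_radius, bottleneck_position=pos,
                        n_shell_vertices=int(in_shell.sum()))
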