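"""Clip the raw Voronoi diagram to one unit cell and make it periodic.

The raw diagram spans the padded super-cell.  Channels, however, are a
property of a single unit cell under periodic boundary conditions, so the
diagram is cut at the central cell boundary: edges crossing a cell face are
split there, introducing *surface vertices*.  Because the padded atom set is
(numerically) lattice-periodic, every crossing on a face has a twin crossing
on the opposite face produced by the lattice-translated image of the same
raw edge; each such pair is connected by an *artificial periodic edge* whose
traversal corresponds to stepping into the neighboring unit cell.  Elements
narrower than a user cutoff ``r_min`` are pruned.  The result — no longer a
Voronoi diagram — is the Voronoi channel graph.

All face bookkeeping is done in fractional space, so skewed cells need no
special casing; the cell is the half-open box [0, 1)^3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .crystal_io import AtomSet, CellGeometry
from .voronoi_core import RawVoronoiGraph, _segment_min_dist

logger = logging.getLogger(__name__)

EDGE_VORONOI = 0
EDGE_ARTIFICIAL = 1

#: tolerance for matching surface vertices on opposite faces, fractional units
PAIR_UV_TOL = 1e-4


@dataclass
class SurfaceVertexPair:
    """Two surface vertices related by one lattice translation along an axis."""

    face_axis: int            # 0, 1, 2
    vertex_low: int
    vertex_high: int
    face_uv: tuple            # fractional 2D coordinate on the face


@dataclass
class ChannelGraph:
    """Clipped, periodicity-aware Voronoi channel graph of one unit cell."""

    vert_pos: np.ndarray          # (V, 3) Cartesian
    vert_r: np.ndarray            # (V,)
    vert_surface_axis: np.ndarray  # (V,) -1 interior, else face axis
    edges: np.ndarray             # (E, 2) vertex ids
    edge_r: np.ndarray            # (E,)
    edge_kind: np.ndarray         # (E,) EDGE_VORONOI / EDGE_ARTIFICIAL
    edge_pair: np.ndarray         # (E,) pair id for artificial edges, else -1
    edge_foot: np.ndarray         # (E, 3) point of minimal generator distance
    pairs: list                   # list[SurfaceVertexPair]
    cell: CellGeometry = None
    r_min: float = 0.0
    n_unmatched: int = 0

    @property
    def n_vertices(self):
        return len(self.vert_pos)

    @property
    def n_edges(self):
        return len(self.edges)

    def adjacency(self):
        """vertex -> list of (edge id, other vertex)."""
        adj = [[] for _ in range(self.n_vertices)]
        for e, (i, j) in enumerate(self.edges):
            adj[i].append((e, j))
            adj[j].append((e, i))
        return adj


# --------------------------------------------------------------------------
# clipping
# --------------------------------------------------------------------------

@dataclass
class _Clipped:
    """Intermediate clipped graph prior to pairing/pruning."""

    vert_pos: np.ndarray
    vert_r: np.ndarray
    vert_surface_axis: np.ndarray
    edges: np.ndarray
    edge_r: np.ndarray
    edge_foot: np.ndarray
    # per surface vertex: (axis, side, u, v, raw_edge_id)
    surface_info: dict = field(default_factory=dict)
    cell: CellGeometry = None
    raw: RawVoronoiGraph = None
    atoms: AtomSet = None


def clip_to_unit_cell(raw: RawVoronoiGraph, cell: CellGeometry,
                      atoms: AtomSet) -> _Clipped:
    """Cut the raw diagram at the central-cell boundary.

    Vertices with fractional coordinates in [0,1)^3 are kept; an edge
    leaving the cell is split at its face crossing into a surface vertex
    whose radius is the generator distance at the crossing minus r_u.
    """
    F = cell.frac_matrix
    vfrac = raw.vert_pos @ F.T
    inside = np.all((vfrac >= 0.0) & (vfrac < 1.0), axis=1)

    old2new = np.full(len(raw.vert_pos), -1, dtype=np.int64)
    old2new[inside] = np.arange(int(inside.sum()))
    new_pos = [raw.vert_pos[inside]]
    new_r = [raw.vert_r[inside]]
    new_axis = [np.full(int(inside.sum()), -1, dtype=np.int64)]
    n_new = int(inside.sum())

    i0 = raw.edge_idx[:, 0]
    i1 = raw.edge_idx[:, 1]
    both_in = inside[i0] & inside[i1]

    edges = [np.stack([old2new[i0[both_in]], old2new[i1[both_in]]], axis=1)]
    edge_r = [raw.edge_r[both_in]]
    # foot points of fully interior edges
    gpos = atoms.positions[raw.edge_gen[both_in, 0]]
    _, foot = _segment_min_dist(raw.vert_pos[i0[both_in]],
                                raw.vert_pos[i1[both_in]], gpos)
    edge_foot = [foot]

    surface_info = {}
    ex_pos, ex_r, ex_ax = [], [], []
    ex_edges, ex_er, ex_foot = [], [], []

    crossing = np.nonzero(~both_in)[0]
    for e in crossing:
        a, b = i0[e], i1[e]
        f0, f1 = vfrac[a], vfrac[b]
        d = f1 - f0
        lo, hi = 0.0, 1.0
        lo_face = hi_face = None   # (axis, side)
        ok = True
        for k in range(3):
            if abs(d[k]) < 1e-15:
                if not (0.0 <= f0[k] <= 1.0):
                    ok = False
                    break
                continue
            t0 = (0.0 - f0[k]) / d[k]   # crossing of the low-face plane
            t1 = (1.0 - f0[k]) / d[k]   # crossing of the high-face plane
            if t0 < t1:
                tin, sin_, tout, sout = t0, "low", t1, "high"
            else:
                tin, sin_, tout, sout = t1, "high", t0, "low"
            if tin > lo:
                lo, lo_face = tin, (k, sin_)
            if tout < hi:
                hi, hi_face = tout, (k, sout)
        if not ok or hi <= lo + 1e-12:
            continue

        p0c, p1c = raw.vert_pos[a], raw.vert_pos[b]
        g = atoms.positions[raw.edge_gen[e, 0]]

        ids = []
        for t, face, orig in ((lo, lo_face, a), (hi, hi_face, b)):
            if face is None:
                ids.append(old2new[orig])
                continue
            pt = p0c + t * (p1c - p0c)
            fr = f0 + t * d
            axis, side = face
            uv = tuple(np.delete(fr, axis))
            vid = n_new + len(ex_pos)
            ex_pos.append(pt)
            ex_r.append(np.linalg.norm(pt - g) - raw.r_u)
            ex_ax.append(axis)
            surface_info[vid] = (axis, side, uv, int(e))
            ids.append(vid)
        seg0 = p0c + lo * (p1c - p0c)
        seg1 = p0c + hi * (p1c - p0c)
        dist, foot = _segment_min_dist(seg0, seg1, g)
        ex_edges.append(ids)
        ex_er.append(dist - raw.r_u)
        ex_foot.append(foot)

    if ex_pos:
        new_pos.append(np.array(ex_pos))
        new_r.append(np.array(ex_r))
        new_axis.append(np.array(ex_ax, dtype=np.int64))
        edges.append(np.array(ex_edges, dtype=np.int64))
        edge_r.append(np.array(ex_er))
        edge_foot.append(np.array(ex_foot))

    return _Clipped(
        vert_pos=np.concatenate(new_pos),
        vert_r=np.concatenate(new_r),
        vert_surface_axis=np.concatenate(new_axis),
        edges=(np.concatenate(edges) if edges else np.empty((0, 2), int)),
        edge_r=np.concatenate(edge_r),
        edge_foot=np.concatenate(edge_foot),
        surface_info=surface_info,
        cell=cell, raw=raw, atoms=atoms)


# --------------------------------------------------------------------------
# periodic pairing
# --------------------------------------------------------------------------

def _edge_signature(raw: RawVoronoiGraph, atoms: AtomSet, edge_id: int,
                    shift: np.ndarray):
    """Provenance key of a raw edge's three generator atoms, optionally
    translated by a lattice vector (for matching across the cell)."""
    gens = raw.edge_gen[edge_id]
    return frozenset(
        (int(atoms.source_index[g]), int(atoms.sym_op[g]),
         tuple(int(s) for s in (atoms.lattice_shift[g] + shift)))
        for g in gens)


def add_periodic_edges(clipped: _Clipped) -> ChannelGraph:
    """Pair opposite-face surface vertices and add artificial edges.

    Matching is primarily by generator identity under lattice translation
    (exact, provenance-based); a geometric fallback matches face coordinates
    within ``PAIR_UV_TOL``.  Unmatched surface vertices are dropped with a
    warning — they are numerical casualties at the padding boundary and
    count as clipped dead ends.
    """
    raw, atoms = clipped.raw, clipped.atoms
    by_face = {}
    for vid, (axis, side, uv, e) in clipped.surface_info.items():
        by_face.setdefault((axis, side), []).append((vid, uv, e))

    pairs = []
    matched = set()
    shift_vec = np.eye(3, dtype=int)
    disagreements = 0

    for axis in range(3):
        high = by_face.get((axis, "high"), [])
        low = by_face.get((axis, "low"), [])
        sig_low = {}
        for vid, uv, e in low:
            sig_low.setdefault(_edge_signature(raw, atoms, e, np.zeros(3, int)),
                               []).append(vid)
        uv_ids = [vid for vid, uv, e in low]
        uv_arr = (np.array([uv for _, uv, _ in low])
                  if low else np.empty((0, 2)))
        tree = cKDTree(uv_arr) if len(uv_arr) else None

        for vid, uv, e in high:
            partner = None
            sig = _edge_signature(raw, atoms, e, -shift_vec[axis])
            cands = [c for c in sig_low.get(sig, []) if c not in matched]
            if cands:
                partner = cands[0]
                # sanity: provenance match should also match geometrically
                puv = clipped.surface_info[partner][2]
                if max(abs(puv[0] - uv[0]), abs(puv[1] - uv[1])) > PAIR_UV_TOL:
                    disagreements += 1
            elif tree is not None:
                for j in tree.query_ball_point(np.asarray(uv), PAIR_UV_TOL,
                                               p=np.inf):
                    if uv_ids[j] not in matched:
                        partner = uv_ids[j]
                        break
            if partner is None:
                continue
            matched.add(vid)
            matched.add(partner)
            pairs.append(SurfaceVertexPair(face_axis=axis, vertex_low=partner,
                                           vertex_high=vid, face_uv=uv))

    unmatched = [vid for vid in clipped.surface_info if vid not in matched]
    if unmatched:
        logger.warning("%d unmatched surface vertices dropped "
                       "(clipped dead ends)", len(unmatched))
    if disagreements:
        logger.warning("%d surface pairs matched by identity but not "
                       "geometry", disagreements)

    # assemble: drop unmatched surface vertices
    keep = np.ones(len(clipped.vert_pos), dtype=bool)
    if unmatched:
        keep[np.array(unmatched, dtype=int)] = False
    graph = ChannelGraph(
        vert_pos=clipped.vert_pos, vert_r=clipped.vert_r,
        vert_surface_axis=clipped.vert_surface_axis,
        edges=clipped.edges, edge_r=clipped.edge_r,
        edge_kind=np.zeros(len(clipped.edges), dtype=np.int8),
        edge_pair=np.full(len(clipped.edges), -1, dtype=np.int64),
        edge_foot=clipped.edge_foot,
        pairs=pairs, cell=clipped.cell, n_unmatched=len(unmatched))

    # artificial edges: radius = min of member radii (passage through the
    # face is limited by the narrower side)
    if pairs:
        art = np.array([[p.vertex_low, p.vertex_high] for p in pairs])
        art_r = np.minimum(graph.vert_r[art[:, 0]], graph.vert_r[art[:, 1]])
        art_foot = 0.5 * (graph.vert_pos[art[:, 0]]
                          + graph.vert_pos[art[:, 1]])
        graph.edges = np.concatenate([graph.edges, art])
        graph.edge_r = np.concatenate([graph.edge_r, art_r])
        graph.edge_kind = np.concatenate(
            [graph.edge_kind, np.ones(len(pairs), dtype=np.int8)])
        graph.edge_pair = np.concatenate(
            [graph.edge_pair, np.arange(len(pairs), dtype=np.int64)])
        graph.edge_foot = np.concatenate([graph.edge_foot, art_foot])

    return _subset_graph(graph, keep_vertices=keep)


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------

def prune_min_radius(graph: ChannelGraph, r_min: float) -> ChannelGraph:
    """Discard all elements narrower than ``r_min``.

    Vertices below the cutoff take their incident edges with them; a pair
    losing either member loses its artificial edge and partner record; the
    result keeps no isolated vertices.  An empty outcome is a legitimate
    "no channels above cutoff" result, not an error.
    """
    if r_min < 0:
        raise ValueError("r_min must be >= 0")
    keep_v = graph.vert_r >= r_min
    out = _subset_graph(graph, keep_vertices=keep_v,
                        keep_edges=graph.edge_r >= r_min,
                        drop_isolated=True)
    out.r_min = r_min
    return out


def _subset_graph(graph: ChannelGraph, keep_vertices=None, keep_edges=None,
                  drop_isolated=False) -> ChannelGraph:
    V = graph.n_vertices
    keep_v = (np.ones(V, bool) if keep_vertices is None
              else np.asarray(keep_vertices, bool).copy())
    keep_e = (np.ones(graph.n_edges, bool) if keep_edges is None
              else np.asarray(keep_edges, bool).copy())
    keep_e &= keep_v[graph.edges[:, 0]] & keep_v[graph.edges[:, 1]]

    # pair consistency: pair dies with either member or its artificial edge
    pair_alive = np.ones(len(graph.pairs), bool)
    for pid, p in enumerate(graph.pairs):
        if not (keep_v[p.vertex_low] and keep_v[p.vertex_high]):
            pair_alive[pid] = False
    art = graph.edge_pair >= 0
    keep_e[art] &= pair_alive[graph.edge_pair[art]]
    # a pruned artificial edge also kills its pair record
    dead_pairs = graph.edge_pair[art & ~keep_e]
    pair_alive[dead_pairs] = False

    if drop_isolated:
        used = np.zeros(V, bool)
        used[graph.edges[keep_e].ravel()] = True
        keep_v &= used
        keep_e &= keep_v[graph.edges[:, 0]] & keep_v[graph.edges[:, 1]]

    old2new = np.full(V, -1, dtype=np.int64)
    old2new[keep_v] = np.arange(int(keep_v.sum()))
    pair_old2new = np.full(len(graph.pairs), -1, dtype=np.int64)
    new_pairs = []
    for pid, p in enumerate(graph.pairs):
        if pair_alive[pid] and keep_v[p.vertex_low] and keep_v[p.vertex_high]:
            pair_old2new[pid] = len(new_pairs)
            new_pairs.append(SurfaceVertexPair(
                face_axis=p.face_axis,
                vertex_low=int(old2new[p.vertex_low]),
                vertex_high=int(old2new[p.vertex_high]),
                face_uv=p.face_uv))

    new_edge_pair = graph.edge_pair[keep_e].copy()
    remap = new_edge_pair >= 0
    new_edge_pair[remap] = pair_old2new[new_edge_pair[remap]]

    return ChannelGraph(
        vert_pos=graph.vert_pos[keep_v],
        vert_r=graph.vert_r[keep_v],
        vert_surface_axis=graph.vert_surface_axis[keep_v],
        edges=old2new[graph.edges[keep_e]],
        edge_r=graph.edge_r[keep_e],
        edge_kind=graph.edge_kind[keep_e],
        edge_pair=new_edge_pair,
        edge_foot=graph.edge_foot[keep_e],
        pairs=new_pairs, cell=graph.cell, r_min=graph.r_min,
        n_unmatched=graph.n_unmatched)


def build_channel_graph(raw: RawVoronoiGraph, cell: CellGeometry,
                        atoms: AtomSet, r_min: float = 1.7) -> ChannelGraph:
    """clip -> pair -> prune convenience wrapper."""
    clipped = clip_to_unit_cell(raw, cell, atoms)
    graph = add_periodic_edges(clipped)
    return prune_min_radius(graph, r_min)


# --------------------------------------------------------------------------
# debug export
# --------------------------------------------------------------------------

def export_graph_tsv(graph: ChannelGraph, path, annotation=None) -> None:
    """Tab-separated dump: vertices (x y z r [rb rx ry rz]), edges (i j r kind)."""
    with open(path, "w") as fh:
        fh.write("# vertices\n")
        for i in range(graph.n_vertices):
            x, y, z = graph.vert_pos[i]
            row = f"v\t{i}\t{x:.4f}\t{y:.4f}\t{z:.4f}\t{graph.vert_r[i]:.4f}"
            if annotation is not None:
                rb = annotation.per_vertex_overall[i]
                rx, ry, rz = annotation.per_vertex_axis[i]
                row += f"\t{rb:.4f}\t{rx:.4f}\t{ry:.4f}\t{rz:.4f}"
            fh.write(row + "\n")
        fh.write("# edges\n")
        for e in range(graph.n_edges):
            i, j = graph.edges[e]
            kind = "artificial" if graph.edge_kind[e] else "voronoi"
            fh.write(f"e\t{i}\t{j}\t{graph.edge_r[e]:.4f}\t{kind}\n")
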