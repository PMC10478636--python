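"""Local bottleneck radii via a radius-descending union-find sweep.

For each cell axis the channel graph is swept once: edges are processed in
descending radius order and merged into disjoint vertex sets.  A set
represents an infinite periodic path along the swept axis as soon as it
contains *both* members of a surface-vertex pair on that axis — a channel
that leaves the cell through one face and re-enters through the opposite
face at the projecting position.  The moment a set first gains such a path,
every vertex it contains is annotated with the current edge radius: because
edges arrive in descending order, that radius is exactly the widest-path
bottleneck for those vertices.  Vertices that join a completed set later
inherit the (smaller) radius of the joining edge.

Artificial periodic edges on the two faces perpendicular to the swept axis
are excluded from that sweep (the checked surface must be non-passable, or
cavities cut by the boundary would masquerade as channels); artificial edges
on the other two face pairs participate normally, which is what makes
channels detectable when they wind through neighboring cells sideways.

The per-vertex local bottleneck radius r_b(v) is the maximum over the three
axis sweeps; the largest r_b(v) over the graph is the bottleneck radius of
the crystal's main channel (the "1D radius").  r_b(v) never exceeds the
local clearance r(v).
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .channel_graph import ChannelGraph, EDGE_ARTIFICIAL
from .errors import BottleneckNotFoundError


class UnionFindForest:
    """Union-find with rank/path compression and per-set surface payload."""

    def __init__(self, n: int, n_pairs: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)
        self.low = [None] * n      # pair-id sets, allocated lazily
        self.high = [None] * n
        self.members = [None] * n  # tracked until the set completes
        self.complete = np.zeros(n, dtype=bool)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:        # path compression
            p[i], i = root, p[i]
        return int(root)


def compute_axis_bottlenecks(graph: ChannelGraph, axis: int,
                             use_orthogonal_pairs: bool = True) -> np.ndarray:
    """Per-vertex bottleneck radii for periodic traversal along one axis.

    Returns an array of length V; vertices that no completed set ever
    reaches get 0 (unreachable on any periodic path along this axis).
    ``use_orthogonal_pairs=False`` additionally excludes the artificial
    edges on the faces orthogonal to the sweep — the single-cell view that
    misses channels winding through neighboring cells; it exists to
    demonstrate why those edges are needed and is not an analysis mode.
    """
    V = graph.n_vertices
    radii = np.zeros(V)
    if V == 0:
        return radii

    pair_axis = np.array([p.face_axis for p in graph.pairs], dtype=int) \
        if graph.pairs else np.empty(0, int)

    uf = UnionFindForest(V, len(graph.pairs))
    for pid, p in enumerate(graph.pairs):
        if p.face_axis != axis:
            continue
        lo = uf.low[p.vertex_low] or set()
        lo.add(pid)
        uf.low[p.vertex_low] = lo
        hi = uf.high[p.vertex_high] or set()
        hi.add(pid)
        uf.high[p.vertex_high] = hi

    # the swept faces are non-passable: exclude their artificial edges
    artificial = (graph.edge_kind == EDGE_ARTIFICIAL) & (graph.edge_pair >= 0)
    included = ~(artificial
                 & np.isin(graph.edge_pair,
                           np.nonzero(pair_axis == axis)[0]))
    if not use_orthogonal_pairs:
        included &= ~artificial
    order = np.lexsort((np.arange(graph.n_edges), -graph.edge_r))
    order = order[included[order]]

    parent = uf.parent
    for e in order:
        i, j = graph.edges[e]
        ri, rj = uf.find(int(i)), uf.find(int(j))
        if ri == rj:
            continue
        r_e = graph.edge_r[e]
        # union by size
        if uf.size[ri] < uf.size[rj]:
            ri, rj = rj, ri
        parent[rj] = ri
        uf.size[ri] += uf.size[rj]

        ci, cj = uf.complete[ri], uf.complete[rj]
        if ci and cj:
            continue
        if ci or cj:
            # the incomplete side gains access to the existing path
            inc = rj if ci else ri
            for m in _take_members(uf, inc):
                if radii[m] < r_e:
                    radii[m] = r_e
            uf.complete[ri] = True
            uf.low[ri] = uf.high[ri] = None
            continue
        low = _merge_sets(uf.low[ri], uf.low[rj])
        high = _merge_sets(uf.high[ri], uf.high[rj])
        if low and high and not low.isdisjoint(high):
            # first complete periodic path: annotate the whole set
            for m in _take_members(uf, ri) + _take_members(uf, rj):
                if radii[m] < r_e:
                    radii[m] = r_e
            uf.complete[ri] = True
            uf.low[ri] = uf.high[ri] = None
        else:
            uf.low[ri], uf.high[ri] = low, high
            mi = uf.members[ri] if uf.members[ri] is not None else [int(ri)]
            mj = uf.members[rj] if uf.members[rj] is not None else [int(rj)]
            mi.extend(mj)
            uf.members[ri] = mi
            uf.members[rj] = None
    return radii


def _take_members(uf, root):
    m = uf.members[root] if uf.members[root] is not None else [int(root)]
    uf.members[root] = None
    return m


def _merge_sets(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a | b


@dataclass
class BottleneckAnnotation:
    """Per-vertex and whole-crystal bottleneck radii."""

    per_vertex_axis: np.ndarray      # (V, 3)
    per_vertex_overall: np.ndarray   # (V,) r_b(v)
    per_axis_main: np.ndarray        # (3,)
    main_bottleneck_radius: float
    bottleneck_position: np.ndarray = None   # Cartesian A
    bottleneck_edge: int = -1

    @property
    def has_channel(self) -> bool:
        return self.main_bottleneck_radius > 0


def combine_axes(rx: np.ndarray, ry: np.ndarray,
                 rz: np.ndarray) -> BottleneckAnnotation:
    """r_b(v) = max over the three axis annotations."""
    per_axis = np.stack([rx, ry, rz], axis=1)
    overall = per_axis.max(axis=1) if len(per_axis) else np.zeros(0)
    return BottleneckAnnotation(
        per_vertex_axis=per_axis,
        per_vertex_overall=overall,
        per_axis_main=(per_axis.max(axis=0) if len(per_axis)
                       else np.zeros(3)),
        main_bottleneck_radius=float(overall.max()) if len(overall) else 0.0)


def annotate_bottlenecks(graph: ChannelGraph) -> BottleneckAnnotation:
    """Run the three axis sweeps and locate the main-channel bottleneck."""
    ann = combine_axes(compute_axis_bottlenecks(graph, 0),
                       compute_axis_bottlenecks(graph, 1),
                       compute_axis_bottlenecks(graph, 2))
    if ann.has_channel:
        start = int(np.argmax(ann.per_vertex_overall))
        try:
            pos, edge = locate_bottleneck(graph, ann,
                                          ann.main_bottleneck_radius, [start])
            ann.bottleneck_position = pos
            ann.bottleneck_edge = edge
        except BottleneckNotFoundError:
            pass
    return ann


def locate_bottleneck(graph: ChannelGraph, annotation: BottleneckAnnotation,
                      target_radius: float, start_region) -> tuple:
    """BFS for the first edge realizing ``target_radius``.

    The search walks only vertices with r_b >= target; the returned position
    is the point of the limiting edge closest to its generator atoms.
    """
    rb = annotation.per_vertex_overall
    eligible = rb >= target_radius - 1e-12
    adj = graph.adjacency()
    seen = np.zeros(graph.n_vertices, dtype=bool)
    queue = deque()
    for s in start_region:
        if eligible[s] and not seen[s]:
            seen[s] = True
            queue.append(int(s))
    while queue:
        v = queue.popleft()
        for e, w in adj[v]:
            if abs(graph.edge_r[e] - target_radius) <= 1e-9:
                return graph.edge_foot[e].copy(), int(e)
            if eligible[w] and not seen[w]:
                seen[w] = True
                queue.append(int(w))
    raise BottleneckNotFoundError(
        f"no reachable edge with radius {target_radius:.4f}")
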