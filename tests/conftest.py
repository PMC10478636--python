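"""Shared fixtures: synthetic crystals analyzed once per session, plus
graph builders and independent oracles used by several test modules."""
import numpy as np
import pytest

from xtalchannels import fixtures_oracle as fx
from xtalchannels.channel_graph import (ChannelGraph, EDGE_ARTIFICIAL,
                                        EDGE_VORONOI, SurfaceVertexPair)
from xtalchannels.pipeline import RunConfig, run

# analysis settings for the two fixture families: solid-wall crystals keep
# their buried atoms (the burial filter assumes non-percolating cores) and
# near-empty cells need a full cell of padding
DENSE_WALLS = dict(hydrogen_mode="keep", margin_frac=0.35, sas_filter=False)
SPARSE = dict(hydrogen_mode="keep", margin_frac=1.0)


@pytest.fixture(scope="session")
def cubic10():
    crystal = fx.make_cubic_lattice(10.0)
    result = run(RunConfig(**SPARSE), structure=crystal.structure)
    return crystal, result


@pytest.fixture(scope="session")
def tube():
    crystal = fx.make_straight_tube()
    result = run(RunConfig(**DENSE_WALLS), structure=crystal.structure)
    return crystal, result


@pytest.fixture(scope="session")
def blocked():
    crystal = fx.make_blocked_channel()
    result = run(RunConfig(**DENSE_WALLS), structure=crystal.structure)
    return crystal, result


@pytest.fixture(scope="session")
def zigzag():
    crystal = fx.make_zigzag_channel()
    result = run(RunConfig(**DENSE_WALLS), structure=crystal.structure)
    return crystal, result


@pytest.fixture(scope="session")
def side_cavity():
    crystal, tube_c, throat_c, cav_center = fx.make_tube_with_side_cavity()
    result = run(RunConfig(r_min=0.5, **DENSE_WALLS),
                 structure=crystal.structure)
    return crystal, result, tube_c, throat_c, np.array(cav_center)


def atom_positions(crystal):
    return np.array([a.position for a in crystal.structure.atoms])


# --------------------------------------------------------------------------
# abstract channel-graph builder (for engine unit tests)
# --------------------------------------------------------------------------

def build_graph(vert_r, voronoi_edges, pairs, positions=None):
    """Assemble a ChannelGraph from plain lists.

    ``voronoi_edges``: (i, j, r) triples; ``pairs``: (axis, vlow, vhigh)
    triples — each pair contributes one artificial edge with the min member
    radius.
    """
    vert_r = np.asarray(vert_r, dtype=float)
    V = len(vert_r)
    pos = (np.asarray(positions, float) if positions is not None
           else np.zeros((V, 3)))
    ed = [(int(i), int(j)) for i, j, _ in voronoi_edges]
    er = [float(r) for _, _, r in voronoi_edges]
    kind = [EDGE_VORONOI] * len(ed)
    epair = [-1] * len(ed)
    pair_objs = []
    for pid, (axis, lo, hi) in enumerate(pairs):
        pair_objs.append(SurfaceVertexPair(face_axis=int(axis),
                                           vertex_low=int(lo),
                                           vertex_high=int(hi),
                                           face_uv=(0.0, 0.0)))
        ed.append((int(lo), int(hi)))
        er.append(float(min(vert_r[lo], vert_r[hi])))
        kind.append(EDGE_ARTIFICIAL)
        epair.append(pid)
    E = len(ed)
    surf = np.full(V, -1)
    for axis, lo, hi in pairs:
        surf[lo] = surf[hi] = axis
    return ChannelGraph(
        vert_pos=pos, vert_r=vert_r, vert_surface_axis=surf,
        edges=np.array(ed, dtype=np.int64).reshape(E, 2),
        edge_r=np.array(er), edge_kind=np.array(kind, dtype=np.int8),
        edge_pair=np.array(epair, dtype=np.int64),
        edge_foot=np.zeros((E, 3)), pairs=pair_objs)


def random_graph(rng):
    """Random small periodic graph with consistent radii (r_e <= r_v)."""
    n_core = rng.integers(4, 9)
    pairs = []
    V = int(n_core)
    for axis in range(3):
        for _ in range(rng.integers(0, 3)):
            pairs.append((axis, V, V + 1))
            V += 2
    edges = set()
    n_edges = rng.integers(V, 2 * V + 4)
    while len(edges) < n_edges:
        i, j = rng.integers(0, V, 2)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    voronoi_edges = [(i, j, float(rng.uniform(0.5, 5.0))) for i, j in edges]
    vert_r = np.zeros(V)
    for i, j, r in voronoi_edges:
        vert_r[i] = max(vert_r[i], r)
        vert_r[j] = max(vert_r[j], r)
    vert_r += rng.uniform(0.0, 0.5, V)
    return build_graph(vert_r, voronoi_edges, pairs)


# --------------------------------------------------------------------------
# independent bottleneck oracles
# --------------------------------------------------------------------------

def threshold_oracle(graph, axis):
    """Per-vertex axis bottleneck by thresholded recomputation.

    For every distinct edge radius r', build the subgraph of edges with
    r_e >= r' (swept-axis artificial edges excluded), take connected
    components (scipy.sparse.csgraph) and mark components containing both
    members of a swept-axis surface pair as periodic; a vertex's radius is
    the largest r' whose component is periodic.  Same completion semantics
    as the sweep, independent computational path.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    V = graph.n_vertices
    out = np.zeros(V)
    axis_pairs = [p for p in graph.pairs if p.face_axis == axis]
    include = ~((graph.edge_kind == EDGE_ARTIFICIAL)
                & np.isin(graph.edge_pair,
                          [i for i, p in enumerate(graph.pairs)
                           if p.face_axis == axis]))
    for r in np.unique(graph.edge_r[include]):
        sel = include & (graph.edge_r >= r)
        if not sel.any():
            continue
        m = coo_matrix((np.ones(sel.sum()),
                        (graph.edges[sel, 0], graph.edges[sel, 1])),
                       shape=(V, V))
        _, labels = connected_components(m, directed=False)
        complete = {labels[p.vertex_low] for p in axis_pairs
                    if labels[p.vertex_low] == labels[p.vertex_high]}
        for v in range(V):
            if labels[v] in complete:
                out[v] = max(out[v], r)
    return out


def tiling_oracle(graph, axis, n_cells=3):
    """Flood fill on an explicit tiling: ``n_cells`` copies along the swept
    axis, quotient (wrap) on the orthogonal axes.  A vertex passes at radius
    r' when its copy in one cell is connected to its own translate in the
    next cell."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    V = graph.n_vertices
    axis_pair_ids = {i for i, p in enumerate(graph.pairs)
                     if p.face_axis == axis}

    # template edge lists, replicated per threshold
    intra = []      # (i, j, r): present in every cell copy
    inter = []      # (high, low, r): connects cell c to c+1
    for e in range(graph.n_edges):
        i, j = graph.edges[e]
        r = graph.edge_r[e]
        if graph.edge_kind[e] == EDGE_ARTIFICIAL and \
                graph.edge_pair[e] in axis_pair_ids:
            p = graph.pairs[graph.edge_pair[e]]
            inter.append((p.vertex_high, p.vertex_low, r))
        else:
            intra.append((i, j, r))
    intra = np.array(intra, dtype=float).reshape(-1, 3)
    inter = np.array(inter, dtype=float).reshape(-1, 3)

    out = np.zeros(V)
    for r in np.unique(graph.edge_r):
        rows, cols = [], []
        ia = intra[intra[:, 2] >= r]
        for c in range(n_cells):
            rows.append(ia[:, 0].astype(int) + c * V)
            cols.append(ia[:, 1].astype(int) + c * V)
        ie = inter[inter[:, 2] >= r]
        for c in range(n_cells - 1):
            rows.append(ie[:, 0].astype(int) + c * V)
            cols.append(ie[:, 1].astype(int) + (c + 1) * V)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        m = coo_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(V * n_cells, V * n_cells))
        _, labels = connected_components(m, directed=False)
        passed = labels[:V] == labels[V:2 * V]
        out[passed] = np.maximum(out[passed], r)
    return out
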