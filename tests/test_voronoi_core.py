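"""Delaunay/Voronoi geometry: perturbation, duality, closed-form radii and
the brute-force circumsphere oracle."""
import itertools

import numpy as np
import pytest

from xtalchannels.crystal_io import AtomSet, CellGeometry
from xtalchannels.errors import DegenerateInputError
from xtalchannels.voronoi_core import (UnifiedRadiusConfig,
                                       delaunay_tetrahedralize,
                                       extract_voronoi, perturb_positions)

R_U = 1.7
CFG = UnifiedRadiusConfig(r_u=R_U)


def _atomset(positions, cell=None):
    n = len(positions)
    return AtomSet(positions=np.asarray(positions, float),
                   elements=np.array(["C"] * n, dtype=object),
                   is_hydrogen=np.zeros(n, bool),
                   source_index=np.arange(n), sym_op=np.zeros(n, int),
                   lattice_shift=np.zeros((n, 3), int), cell=cell)


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

def test_zero_eps_is_identity():
    a = _atomset(np.random.default_rng(0).random((10, 3)))
    out = perturb_positions(a, 0.0, 42)
    np.testing.assert_array_equal(out.positions, a.positions)


def test_perturbation_bounded_and_deterministic():
    a = _atomset(np.random.default_rng(1).random((50, 3)))
    o1 = perturb_positions(a, 1e-6, 7)
    o2 = perturb_positions(a, 1e-6, 7)
    d = np.linalg.norm(o1.positions - a.positions, axis=1)
    assert d.max() <= 1e-6 + 1e-18
    np.testing.assert_array_equal(o1.positions, o2.positions)
    o3 = perturb_positions(a, 1e-6, 8)
    assert not np.array_equal(o1.positions, o3.positions)


# --------------------------------------------------------------------------
# tetrahedralization
# --------------------------------------------------------------------------

def _empty_circumsphere_holds(points, simplices, tol=1e-9):
    for simp in simplices:
        p = points[simp]
        a = p[0]
        d = p[1:] - a
        c = np.linalg.solve(d, 0.5 * (d * d).sum(1)) + a
        R = np.linalg.norm(c - a)
        others = np.delete(np.arange(len(points)), simp)
        if len(others) and np.linalg.norm(points[others] - c,
                                          axis=1).min() < R - tol:
            return False
    return True


def test_triangular_bipyramid_gives_two_tetrahedra():
    # apexes far enough that each apex lies outside the other half's
    # circumsphere -> the Delaunay split is through the shared base face
    s = 2.0
    base = [[s, 0, 0], [-s / 2, s * np.sqrt(3) / 2, 0],
            [-s / 2, -s * np.sqrt(3) / 2, 0]]
    pts = np.array(base + [[0, 0, 3.0], [0, 0, -3.0]])
    tri = delaunay_tetrahedralize(_atomset(pts))
    assert len(tri.simplices) == 2
    assert _empty_circumsphere_holds(pts, tri.simplices)


def test_squat_bipyramid_splits_through_the_apex_edge():
    # with close apexes the base-face split violates the empty-sphere
    # property; Delaunay must use the three tetrahedra around the apex axis
    s = 2.0
    base = [[s, 0, 0], [-s / 2, s * np.sqrt(3) / 2, 0],
            [-s / 2, -s * np.sqrt(3) / 2, 0]]
    pts = np.array(base + [[0, 0, 1.5], [0, 0, -1.5]])
    tri = delaunay_tetrahedralize(_atomset(pts))
    assert len(tri.simplices) == 3
    assert _empty_circumsphere_holds(pts, tri.simplices)


def test_coplanar_points_need_perturbation():
    flat = np.array([[float(i), float(j), 0.0]
                     for i in range(3) for j in range(3)])
    with pytest.raises(DegenerateInputError):
        delaunay_tetrahedralize(_atomset(flat))
    jiggled = perturb_positions(_atomset(flat), 1e-6, 0)
    tri = delaunay_tetrahedralize(jiggled)
    assert len(tri.simplices) >= 1


def test_perturbed_cube_satisfies_empty_sphere_property():
    # a cube is cospherical: Qhull keeps a few zero-volume slivers around
    # the degeneracy; the substantive tetrahedra must number 5 or 6
    # (diagonal choice), tile the cube, and obey the empty-sphere property
    # up to the near-tie tolerance of the common circumsphere
    cube = np.array(list(itertools.product([0.0, 3.0], repeat=3)))
    jiggled = perturb_positions(_atomset(cube), 1e-3, 3)
    tri = delaunay_tetrahedralize(jiggled)
    p = jiggled.positions[tri.simplices]
    vol = np.abs(np.linalg.det(p[:, 1:] - p[:, :1])) / 6.0
    substantive = tri.simplices[vol > 0.1]
    assert 5 <= len(substantive) <= 6
    assert vol.sum() == pytest.approx(27.0, rel=1e-3)
    assert _empty_circumsphere_holds(jiggled.positions, substantive,
                                     tol=0.05)


# --------------------------------------------------------------------------
# Voronoi extraction
# --------------------------------------------------------------------------

def test_regular_tetrahedron_closed_form():
    L = 4.0
    pts = L * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1],
                        [-1, -1, 1]]) / np.sqrt(8)
    # add a far satellite so Delaunay has >= 5 points; its tets are distinct
    far = np.array([[50.0, 0.0, 0.0]])
    aset = _atomset(np.vstack([pts, far]))
    raw = extract_voronoi(delaunay_tetrahedralize(aset), aset, CFG)
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(raw.vert_pos[:raw.n_tetra] - centroid, axis=1)
    v = int(np.argmin(d))
    assert d[v] < 1e-9
    assert raw.vert_r[v] == pytest.approx(L * np.sqrt(3 / 8) - R_U)


def test_shared_equilateral_face_edge_radius():
    # equilateral shared face of side s (circumradius s/sqrt(3)); the dual
    # edge joins the two circumcenters through the face circumcircle center,
    # so r_e = s/sqrt(3) - r_u
    s = 3.0 * np.sqrt(3.0)
    rb = s / np.sqrt(3.0)
    base = np.array([[rb, 0, 0], [-rb / 2, rb * np.sqrt(3) / 2, 0],
                     [-rb / 2, -rb * np.sqrt(3) / 2, 0]])
    pts = np.vstack([base, [[0, 0, 5.0]], [[0, 0, -5.0]]])
    aset = _atomset(pts)
    raw = extract_voronoi(delaunay_tetrahedralize(aset), aset, CFG)
    # the interior edge is the one between the two tetrahedron vertices
    interior = raw.edge_idx.max(axis=1) < raw.n_tetra
    assert interior.sum() == 1
    r = raw.edge_r[interior][0]
    assert r == pytest.approx(s / np.sqrt(3) - R_U, abs=1e-9)


def test_duality_vertex_count_and_generators():
    rng = np.random.default_rng(11)
    aset = _atomset(rng.uniform(0, 10, (30, 3)))
    tri = delaunay_tetrahedralize(aset)
    raw = extract_voronoi(tri, aset, CFG)
    assert raw.n_tetra == len(tri.simplices)
    # every interior edge's generators are the shared face of its two tets
    interior = raw.edge_idx.max(axis=1) < raw.n_tetra
    for (t, u), gens in zip(raw.edge_idx[interior],
                            raw.edge_gen[interior]):
        st, su = set(tri.simplices[t]), set(tri.simplices[u])
        assert set(gens) == st & su


def test_edge_radius_never_exceeds_endpoint_radii():
    rng = np.random.default_rng(12)
    aset = _atomset(rng.uniform(0, 12, (40, 3)))
    raw = extract_voronoi(delaunay_tetrahedralize(aset), aset, CFG)
    vr = raw.vert_r[raw.edge_idx]
    assert np.all(raw.edge_r <= vr.min(axis=1) + 1e-9)


def test_vertices_match_brute_force_circumsphere_construction():
    """Every empty-circumsphere 4-subset is a Delaunay tetrahedron and
    vice versa (generic position)."""
    rng = np.random.default_rng(13)
    pts = rng.uniform(0, 8, (14, 3))
    aset = _atomset(pts)
    tri = delaunay_tetrahedralize(aset)
    raw = extract_voronoi(tri, aset, CFG)

    brute = []
    for comb in itertools.combinations(range(len(pts)), 4):
        p = pts[list(comb)]
        d = p[1:] - p[0]
        if abs(np.linalg.det(d)) < 1e-9:
            continue
        c = np.linalg.solve(d, 0.5 * (d * d).sum(1)) + p[0]
        R = np.linalg.norm(c - p[0])
        others = np.delete(np.arange(len(pts)), list(comb))
        if np.linalg.norm(pts[others] - c, axis=1).min() > R + 1e-9:
            brute.append(c)
    brute = np.array(sorted(map(tuple, np.round(brute, 6))))
    got = np.array(sorted(map(tuple,
                              np.round(raw.vert_pos[:raw.n_tetra], 6))))
    np.testing.assert_allclose(got, brute, atol=1e-5)


def test_negative_radii_when_ru_exceeds_circumradius():
    pts = np.array([[0, 0, 0], [1.2, 0, 0], [0, 1.2, 0], [0, 0, 1.2],
                    [1.2, 1.2, 1.2]], dtype=float)
    aset = _atomset(pts)
    raw = extract_voronoi(delaunay_tetrahedralize(aset), aset,
                          UnifiedRadiusConfig(r_u=5.0))
    assert np.all(raw.vert_r[:raw.n_tetra] < 0)
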