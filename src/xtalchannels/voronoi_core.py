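"""Unified-radius Voronoi diagram of the padded atom set.

Atoms are modelled as spheres of a single unified radius ``r_u`` (default:
the 1.7 A carbon van der Waals radius), which turns the additively weighted
sphere problem into an ordinary point Voronoi diagram: every vertex/edge
clearance is the distance to the generating atom centers minus ``r_u``.

The diagram is obtained as the dual of a Delaunay tetrahedralization:
one Voronoi vertex per tetrahedron (its circumcenter), one Voronoi edge per
shared triangular face.  Convex-hull faces dualize to unbounded rays; they
are truncated at the padded-region boundary and can only matter when the
padding margin is unusually small — with the default half-cell margin they
never survive clipping to the central cell.

Local coplanarity (rings, symmetry) is broken by a tiny random perturbation
of the input points, as in the reference method.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial import QhullError

from .crystal_io import AtomSet
from .errors import DegenerateInputError


@dataclass(frozen=True)
class UnifiedRadiusConfig:
    """Geometric parameters of the unified-radius model."""

    r_u: float = 1.7               # unified atom radius, A
    perturbation_eps: float = 1e-6  # A
    rng_seed: int = 0

    def __post_init__(self):
        if self.r_u <= 0:
            raise ValueError("r_u must be positive")
        if self.perturbation_eps < 0:
            raise ValueError("perturbation_eps must be >= 0")


@dataclass
class RawVoronoiGraph:
    """Voronoi diagram of the padded set, before unit-cell clipping.

    ``vert_pos[i]`` is the circumcenter of tetrahedron ``i`` and ``vert_r``
    its circumradius minus ``r_u``.  Edge ``k`` connects ``edge_idx[k]`` and
    carries the three generator atom indices of the dual Delaunay face in
    ``edge_gen``; ``edge_r`` is the minimal distance of the edge segment to
    those generators minus ``r_u``.  Truncated hull rays appear as extra
    vertices appended after the tetrahedron circumcenters.
    """

    vert_pos: np.ndarray      # (V, 3)
    vert_r: np.ndarray        # (V,)
    edge_idx: np.ndarray      # (E, 2) vertex ids
    edge_r: np.ndarray        # (E,)
    edge_gen: np.ndarray      # (E, 3) atom ids
    r_u: float = 1.7
    n_tetra: int = 0


def perturb_positions(atoms: AtomSet, eps: float = 1e-6,
                      seed: int = 0) -> AtomSet:
    """Displace every atom by an independent uniform-in-ball vector, |d|<=eps."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if eps == 0 or len(atoms) == 0:
        return atoms
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((len(atoms), 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radii = eps * rng.random(len(atoms)) ** (1.0 / 3.0)
    out = atoms.take(slice(None))
    out.positions = atoms.positions + v * radii[:, None]
    return out


def delaunay_tetrahedralize(points) -> Delaunay:
    """Delaunay tetrahedralization (Qhull); raises on degenerate input."""
    pos = points.positions if isinstance(points, AtomSet) else np.asarray(points)
    if len(pos) < 5:
        raise DegenerateInputError("need at least 5 points")
    try:
        return Delaunay(pos)
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate input: {exc}") from exc


def _circumcenters(pts: np.ndarray, simplices: np.ndarray):
    """Vectorized circumcenters + circumradii of tetrahedra."""
    p = pts[simplices]                  # (T, 4, 3)
    a = p[:, 0]
    d = p[:, 1:] - a[:, None, :]        # (T, 3, 3)
    rhs = 0.5 * (d * d).sum(-1)         # (T, 3)
    centers = np.empty((len(simplices), 3))
    ok = np.abs(np.linalg.det(d)) > 1e-12
    if ok.any():
        centers[ok] = np.linalg.solve(d[ok], rhs[ok][..., None])[..., 0] + a[ok]
    if (~ok).any():
        for t in np.nonzero(~ok)[0]:
            sol, *_ = np.linalg.lstsq(d[t], rhs[t], rcond=None)
            centers[t] = sol + a[t]
    radii = np.linalg.norm(centers - a, axis=1)
    return centers, radii


def _segment_min_dist(p0, p1, gen_pos):
    """Min over segment [p0,p1] of the (common) distance to the generator
    atoms of the dual face; returns (dist, foot point).

    Every point of the dual line is equidistant to the three face atoms, so
    the distance to one of them suffices; the minimum over the segment is at
    the projection of the atom onto the segment (clamped), which coincides
    with the planar circumcircle radius when the foot is interior.
    """
    d = p1 - p0
    L2 = (d * d).sum(-1)
    a = gen_pos - p0
    s = np.where(L2 > 1e-18, (a * d).sum(-1) / np.maximum(L2, 1e-18), 0.0)
    s = np.clip(s, 0.0, 1.0)
    foot = p0 + s[..., None] * d
    return np.linalg.norm(foot - gen_pos, axis=-1), foot


def extract_voronoi(tetra: Delaunay, atoms: AtomSet,
                    config: UnifiedRadiusConfig) -> RawVoronoiGraph:
    """Dualize a tetrahedralization into the raw Voronoi vertex/edge graph."""
    pts = tetra.points
    simp = tetra.simplices
    nbr = tetra.neighbors
    T = len(simp)
    centers, radii = _circumcenters(pts, simp)
    r_u = config.r_u

    # interior edges: shared faces, recorded once (t < u)
    t_idx, face_j = np.nonzero(nbr >= 0)
    u_idx = nbr[t_idx, face_j]
    first = t_idx < u_idx
    t_sel, j_sel, u_sel = t_idx[first], face_j[first], u_idx[first]
    # generators: the simplex of t without its j-th vertex
    all4 = simp[t_sel]
    mask = np.ones((len(t_sel), 4), dtype=bool)
    mask[np.arange(len(t_sel)), j_sel] = False
    gens = all4[mask].reshape(-1, 3)
    dist, _ = _segment_min_dist(centers[t_sel], centers[u_sel], pts[gens[:, 0]])

    vert_pos = [centers]
    vert_r = [radii - r_u]
    edge_i = [t_sel]
    edge_j = [u_sel]
    edge_r = [dist - r_u]
    edge_gen = [gens]

    # hull faces -> rays truncated at the padded-region boundary
    hull_t, hull_j = np.nonzero(nbr == -1)
    if len(hull_t) and atoms.cell is not None:
        extra_pos, extra_r, ei, ej, er, eg = _hull_rays(
            tetra, atoms, centers, hull_t, hull_j, r_u, T)
        if len(extra_pos):
            vert_pos.append(extra_pos)
            vert_r.append(extra_r)
            edge_i.append(ei)
            edge_j.append(ej)
            edge_r.append(er)
            edge_gen.append(eg)

    return RawVoronoiGraph(
        vert_pos=np.concatenate(vert_pos),
        vert_r=np.concatenate(vert_r),
        edge_idx=np.stack([np.concatenate(edge_i), np.concatenate(edge_j)], 1),
        edge_r=np.concatenate(edge_r),
        edge_gen=np.concatenate(edge_gen),
        r_u=r_u, n_tetra=T)


def _hull_rays(tetra, atoms, centers, hull_t, hull_j, r_u, T,
               margin: float = 0.75):
    """Truncate unbounded dual rays at a fractional bounding box."""
    pts = tetra.points
    simp = tetra.simplices
    cell = atoms.cell
    F = cell.frac_matrix

    new_pos, new_r, ei, ej, er, eg = [], [], [], [], [], []
    vid = T
    for t, j in zip(hull_t, hull_j):
        tri = np.delete(simp[t], j)
        a0, a1, a2 = pts[tri]
        n = np.cross(a1 - a0, a2 - a0)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            continue
        n /= nn
        opp = pts[simp[t, j]]
        if np.dot(n, opp - a0) > 0:
            n = -n
        start = centers[t]
        # clip ray start + s*n to frac box [-margin, 1+margin]^3
        f0 = F @ start
        fd = F @ n
        s_lo, s_hi = 0.0, np.inf
        ok = True
        for k in range(3):
            if abs(fd[k]) < 1e-15:
                if not (-margin - 1e-12 <= f0[k] <= 1 + margin + 1e-12):
                    ok = False
                    break
            else:
                t1 = (-margin - f0[k]) / fd[k]
                t2 = (1 + margin - f0[k]) / fd[k]
                s_lo = max(s_lo, min(t1, t2))
                s_hi = min(s_hi, max(t1, t2))
        if not ok or s_hi <= s_lo + 1e-12:
            continue
        end = start + s_hi * n
        dist, _ = _segment_min_dist(start, end, a0)
        new_pos.append(end)
        new_r.append(np.linalg.norm(end - a0) - r_u)
        ei.append(t)
        ej.append(vid)
        er.append(dist - r_u)
        eg.append(tri)
        vid += 1
    if not new_pos:
        return (np.empty((0, 3)), np.empty(0), np.empty(0, int),
                np.empty(0, int), np.empty(0), np.empty((0, 3), int))
    return (np.array(new_pos), np.array(new_r), np.array(ei, dtype=int),
            np.array(ej, dtype=int), np.array(er), np.array(eg, dtype=int))
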