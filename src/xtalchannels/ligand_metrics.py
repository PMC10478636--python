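"""Minimum projection radius of small-molecule conformers.

The crystal-traversal model compares channel bottleneck radii with a single
size proxy of the ligand: project the van der Waals spheres of one conformer
onto a plane and take the radius of the smallest circle enclosing all
projected disks; minimizing that radius over all projection directions gives
the *minimum projection radius* (MPR) — the radius of the thinnest circular
tunnel the rigid conformer could in principle slide through lengthwise.
For a conformational ensemble the relevant number is the minimum of the
per-conformer MPRs.

Directions are sampled with a prefix-nested low-discrepancy sequence on the
hemisphere (projection is symmetric under direction inversion) followed by a
local Nelder-Mead refinement; enlarging the direction budget can therefore
only lower the result.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

#: Bondi (1964) van der Waals radii, with the 1.1 A hydrogen radius of
#: Rowland & Taylor; elements not listed fall back to gemmi's table.
VDW_RADII = {
    "H": 1.10, "D": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "B": 1.92, "SI": 2.10, "AS": 1.85, "TE": 2.06, "XE": 2.16, "KR": 2.02,
    "AR": 1.88, "HE": 1.40, "NE": 1.54,
}


def vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        import gemmi
        r = gemmi.Element(element).vdw_r
        if not r or r <= 0:
            r = 1.7
    return float(r)


@dataclass
class ConformerDisk:
    """One conformer as a set of van der Waals spheres."""

    positions: np.ndarray   # (N, 3)
    radii: np.ndarray       # (N,)
    name: str = ""

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.radii = np.broadcast_to(
            np.asarray(self.radii, float), (len(self.positions),)).copy()
        if len(self.positions) == 0:
            raise ValueError("conformer needs at least one atom")


# --------------------------------------------------------------------------
# smallest enclosing circle of disks (2D)
# --------------------------------------------------------------------------

def enclosing_circle_radius(pts2d: np.ndarray, radii: np.ndarray,
                            tol: float = 1e-9) -> float:
    """Radius of the smallest circle containing all disks (center_i, r_i).

    Minimizes the convex function  g(c) = max_i(|c - p_i| + r_i).  The
    two-disk solution is used as a certificate/initial guess; otherwise a
    derivative-free simplex search refines the center.
    """
    if len(pts2d) == 1:
        return float(radii[0])
    # farthest pair (inflated): exact for the two-support case
    d = np.linalg.norm(pts2d[:, None, :] - pts2d[None, :, :], axis=-1)
    span = d + radii[:, None] + radii[None, :]
    i, j = np.unravel_index(np.argmax(span), span.shape)
    if i == j:
        return float(radii.max())
    dir_ij = pts2d[j] - pts2d[i]
    nrm = np.linalg.norm(dir_ij)
    c0 = 0.5 * (pts2d[i] + pts2d[j])
    if nrm > 1e-12:
        c0 = c0 + (radii[j] - radii[i]) / (2.0 * nrm) * dir_ij
    R0 = 0.5 * span[i, j]

    def g(c):
        return float((np.linalg.norm(pts2d - c, axis=1) + radii).max())

    if g(c0) <= R0 + tol:
        return R0
    res = minimize(g, c0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500})
    return min(g(res.x), g(c0))


# --------------------------------------------------------------------------
# direction sampling
# --------------------------------------------------------------------------

def _hemisphere_directions(n: int) -> np.ndarray:
    """First n terms of an R2 low-discrepancy sequence mapped area-preserving
    onto the upper hemisphere; prefixes are nested by construction."""
    g = 1.32471795724474602596  # plastic constant
    i = np.arange(1, n + 1)
    u = np.mod(0.5 + i / g, 1.0)            # cos(theta) in [0,1)
    v = np.mod(0.5 + i / g ** 2, 1.0)
    z = u
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * v
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def _direction(theta_phi):
    t, p = theta_phi
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def _projected_radius(conf: ConformerDisk, direction: np.ndarray) -> float:
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0., 1., 0.])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    pts2d = conf.positions @ np.stack([e1, e2], axis=1)
    return enclosing_circle_radius(pts2d, conf.radii)


def min_projection_radius(conf: ConformerDisk, n_directions: int = 512,
                          refine: bool = True) -> float:
    """MPR of one conformer: min over directions of the enclosing-circle
    radius of the projected van der Waals disks."""
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if len(conf.positions) == 1:
        return float(conf.radii[0])

    dirs = _hemisphere_directions(n_directions)
    vals = np.array([_projected_radius(conf, d) for d in dirs])
    best = float(vals.min())
    if not refine:
        return best
    d0 = dirs[int(np.argmin(vals))]
    theta0 = float(np.arccos(np.clip(d0[2], -1, 1)))
    phi0 = float(np.arctan2(d0[1], d0[0]))

    def f(tp):
        return _projected_radius(conf, _direction(tp))

    res = minimize(f, np.array([theta0, phi0]), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
    return min(best, float(res.fun))


def ensemble_min(conformers) -> float:
    """Minimum of the minimum projection radii over a conformer ensemble."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty conformer ensemble")
    return min(min_projection_radius(c) if isinstance(c, ConformerDisk) else c
               for c in conformers)


# --------------------------------------------------------------------------
# file input
# --------------------------------------------------------------------------

def read_conformers(path, ion_radius: float = None):
    """Read conformers from SDF (multi-conformer) or PDB.

    ``ion_radius`` overrides the radius for single-atom species, where a
    literature ionic radius is usually more appropriate than the neutral-atom
    van der Waals value.
    """
    path = str(path)
    confs = []
    if path.lower().endswith((".sdf", ".mol", ".sd")):
        from rdkit import Chem
        for idx, mol in enumerate(Chem.SDMolSupplier(path, removeHs=False,
                                                     sanitize=False)):
            if mol is None:
                continue
            pos = mol.GetConformer().GetPositions()
            elems = [a.GetSymbol() for a in mol.GetAtoms()]
            confs.append(_make_conf(pos, elems, f"{path}#{idx}", ion_radius))
    else:
        import gemmi
        st = gemmi.read_structure(path)
        for model in st:
            pos, elems = [], []
            for chain in model:
                for res in chain:
                    for at in res:
                        pos.append([at.pos.x, at.pos.y, at.pos.z])
                        elems.append(at.element.name)
            if pos:
                confs.append(_make_conf(np.array(pos), elems,
                                        f"{path}#{model.name}", ion_radius))
    if not confs:
        raise ValueError(f"no conformers read from {path}")
    return confs


def _make_conf(pos, elems, name, ion_radius):
    if len(elems) == 1 and ion_radius is not None:
        radii = np.array([ion_radius])
    else:
        radii = np.array([vdw_radius(e) for e in elems])
    return ConformerDisk(np.asarray(pos, float), radii, name=name)
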