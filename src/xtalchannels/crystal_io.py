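"""Crystal structure input, component classification and symmetry expansion.

This module turns a PDB/mmCIF file into the numeric atom set that the
Voronoi stage consumes:

* parse the asymmetric unit and the cell (CRYST1 / _cell + _symmetry),
* classify every atom as polymer / covalent modification / ligand / water /
  ion,
* optionally place idealized hydrogens and shift all hydrogens toward their
  bonded heavy atom to compensate the unified-radius model,
* expand space-group symmetry plus lattice translations into a padded
  super-cell (roughly eight unit cells for the default half-cell margin),
* discard buried atoms by a spherical-probe solvent-accessibility test,
* compute Matthews coefficient and solvent content.

Cartesian coordinates are in Angstrom throughout; fractional coordinates of
the central cell live in [0, 1).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import (EmptyStructureError, MemoryCapError,
                     NoCrystalGeometryError)
from ._residue_topology import (BACKBONE_BONDS, H_BOND_LENGTH,
                                HYDROGEN_COUNTS, SIDECHAIN_BONDS)

logger = logging.getLogger(__name__)

# component classes
POLYMER = "polymer"
COVALENT_MODIFICATION = "covalent_modification"
LIGAND = "ligand"
WATER = "water"
ION = "ion"

#: average protein density (Matthews 1968), Da per cubic Angstrom
PROTEIN_DENSITY = 0.81

#: default number of padded atoms tolerated before the run is aborted;
#: sized to the ~6 GB memory heuristic of the reference workflow
DEFAULT_ATOM_CAP = 6_000_000

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


# --------------------------------------------------------------------------
# cell geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Unit-cell parameters, space-group operators and coordinate transforms."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    spacegroup: str = "P 1"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise NoCrystalGeometryError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise NoCrystalGeometryError("cell angles must be in (0, 180)")
        cell = gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)
        sg = gemmi.find_spacegroup_by_name(self.spacegroup)
        if sg is None:
            raise NoCrystalGeometryError(
                f"unknown space-group symbol {self.spacegroup!r}")
        ops = list(sg.operations())
        rot = np.array([op.rot for op in ops], dtype=float) / ops[0].DEN
        tran = np.array([op.tran for op in ops], dtype=float) / ops[0].DEN
        object.__setattr__(self, "_gemmi_cell", cell)
        object.__setattr__(self, "frac_matrix", np.array(cell.frac.mat))
        object.__setattr__(self, "cart_matrix", np.array(cell.orth.mat))
        object.__setattr__(self, "sym_rotations", rot)
        object.__setattr__(self, "sym_translations", tran)

    @property
    def n_sym(self) -> int:
        return len(self.sym_rotations)

    @property
    def cell_volume(self) -> float:
        return self._gemmi_cell.volume

    @property
    def V_a(self) -> float:
        """Volume per asymmetric unit in A^3."""
        return self.cell_volume / self.n_sym

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def to_frac(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.frac_matrix.T

    def to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.cart_matrix.T

    def lattice_vector(self, axis: int) -> np.ndarray:
        """Cartesian lattice vector of one cell axis (column of cart matrix)."""
        return self.cart_matrix[:, axis].copy()


# --------------------------------------------------------------------------
# atoms
# --------------------------------------------------------------------------

@dataclass(eq=False)
class AtomSphere:
    """One atom of the asymmetric unit."""

    position: np.ndarray
    element: str
    name: str = ""
    resname: str = ""
    residue_id: tuple = ("", 0, "")      # (chain, resseq, icode)
    component: str = LIGAND
    is_hydrogen: bool = False
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if not 0.0 <= self.occupancy <= 1.0 + 1e-9:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class Structure:
    """Asymmetric unit + cell."""

    atoms: list
    cell: CellGeometry
    name: str = ""

    @property
    def mass_Da(self) -> float:
        """Protein mass M of the asymmetric unit (polymer + covalent
        modifications, hydrogens included)."""
        m = 0.0
        for at in self.atoms:
            if at.component in (POLYMER, COVALENT_MODIFICATION):
                m += gemmi.Element(at.element).weight
        return m

    def positions(self, components=None) -> np.ndarray:
        sel = [a.position for a in self.atoms
               if components is None or a.component in components]
        return (np.array(sel).reshape(-1, 3) if sel
                else np.empty((0, 3)))


@dataclass
class AtomSet:
    """Flat numpy view of a (padded) collection of atom spheres.

    Provenance columns record for every copy which asymmetric-unit atom it
    came from, which symmetry operator generated it and which lattice
    translation was applied; surface-pair matching in the channel-graph
    stage keys on these.
    """

    positions: np.ndarray              # (N, 3) Cartesian A
    elements: np.ndarray               # (N,)  str
    is_hydrogen: np.ndarray            # (N,)  bool
    source_index: np.ndarray           # (N,)  int, asymmetric-unit atom
    sym_op: np.ndarray                 # (N,)  int
    lattice_shift: np.ndarray          # (N, 3) int
    cell: CellGeometry = None

    def __len__(self):
        return len(self.positions)

    def take(self, idx) -> "AtomSet":
        return AtomSet(self.positions[idx], self.elements[idx],
                       self.is_hydrogen[idx], self.source_index[idx],
                       self.sym_op[idx], self.lattice_shift[idx], self.cell)


@dataclass(frozen=True)
class CrystalDescriptors:
    """Matthews coefficient and solvent content."""

    matthews_VM: float        # A^3 / Da
    solvent_fraction: float   # p_solv
    delta: float = PROTEIN_DENSITY

    @property
    def protein_fraction(self) -> float:
        return 1.0 - self.solvent_fraction


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

def _cell_is_valid(cell: gemmi.UnitCell) -> bool:
    # gemmi uses a 1x1x1 dummy cell when CRYST1 is absent
    return cell.volume > 1.001 and min(cell.a, cell.b, cell.c) > 1.001


def parse_structure(path, fmt: str = "auto") -> Structure:
    """Read a crystal structure from PDB or mmCIF.

    Only the first model is retained (with a warning when more exist); for
    alternate locations the highest-occupancy altloc per atom is kept, ties
    broken by the lexicographically first altloc identifier.

    Raises
    ------
    NoCrystalGeometryError
        if the file carries no valid cell (e.g. NMR/cryo-EM entries).
    EmptyStructureError
        if no atoms remain after parsing.
    """
    path = str(path)
    if fmt == "auto":
        st = gemmi.read_structure(path)
    elif fmt == "pdb":
        st = gemmi.read_pdb(path)
    elif fmt == "mmcif":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if not _cell_is_valid(st.cell):
        raise NoCrystalGeometryError(
            f"{path}: no crystal geometry (missing or invalid CRYST1)")
    sg_name = st.spacegroup_hm or "P 1"
    cell = CellGeometry(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma, sg_name)

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if len(st) > 1:
        logger.warning("%s: %d models present, using the first one",
                       path, len(st))
    model = st[0]

    atoms = []
    for chain in model:
        for res in chain:
            # altloc policy: per atom name keep highest occupancy,
            # ties -> lexicographically first altloc id
            best = {}
            for at in res:
                key = at.name
                cur = best.get(key)
                if (cur is None or at.occ > cur.occ + 1e-9
                        or (abs(at.occ - cur.occ) <= 1e-9
                            and (at.altloc or "~") < (cur.altloc or "~"))):
                    best[key] = at
            for at in best.values():
                elem = at.element.name
                atoms.append(AtomSphere(
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    element=elem,
                    name=at.name,
                    resname=res.name,
                    residue_id=(chain.name, res.seqid.num,
                                res.seqid.icode.strip()),
                    is_hydrogen=elem in ("H", "D"),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    altloc=at.altloc or "",
                    b_factor=at.b_iso,
                ))
    if not atoms:
        raise EmptyStructureError(f"{path}: empty structure")
    structure = Structure(atoms=atoms, cell=cell, name=path)
    return classify_components(structure)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def _covalent_radius(element: str) -> float:
    r = gemmi.Element(element).covalent_r
    return r if r > 0 else 0.77


def classify_components(structure: Structure,
                        covalent_slack: float = 0.4) -> Structure:
    """Label every atom polymer / water / ligand / ion / covalent_modification.

    HET groups with a heavy atom closer to a polymer heavy atom than the sum
    of covalent radii plus ``covalent_slack`` are labelled
    ``covalent_modification`` (glycans, covalent inhibitors, ...) and are
    treated as part of the protein downstream.
    """
    per_residue = {}
    for at in structure.atoms:
        per_residue.setdefault((at.residue_id, at.resname), []).append(at)

    het_residues = []
    for (rid, resname), res_atoms in per_residue.items():
        info = gemmi.find_tabulated_residue(resname)
        if resname in _WATER_NAMES or (info and info.is_water()):
            comp = WATER
        elif info and (info.is_amino_acid() or info.is_nucleic_acid()):
            # any chain of standard residues counts as polymer, however short
            comp = POLYMER
        else:
            heavy = [a for a in res_atoms if not a.is_hydrogen]
            if len(heavy) == 1 and gemmi.Element(heavy[0].element).is_metal:
                comp = ION
            else:
                comp = LIGAND
                het_residues.append((rid, resname, res_atoms))
        for a in res_atoms:
            a.component = comp

    # covalent-modification detection against polymer heavy atoms
    poly = [a for a in structure.atoms
            if a.component == POLYMER and not a.is_hydrogen]
    if poly and het_residues:
        tree = cKDTree(np.array([a.position for a in poly]))
        poly_r = np.array([_covalent_radius(a.element) for a in poly])
        for rid, resname, res_atoms in het_residues:
            bonded = False
            for a in res_atoms:
                if a.is_hydrogen:
                    continue
                ra = _covalent_radius(a.element)
                idx = tree.query_ball_point(a.position,
                                            ra + poly_r.max() + covalent_slack)
                for j in idx:
                    d = np.linalg.norm(a.position - poly[j].position)
                    if d < ra + poly_r[j] + covalent_slack:
                        bonded = True
                        break
                if bonded:
                    break
            if bonded:
                for a in res_atoms:
                    a.component = COVALENT_MODIFICATION
    return structure


# --------------------------------------------------------------------------
# hydrogens
# --------------------------------------------------------------------------

_TET_HALF = math.radians(54.735)  # half tetrahedral angle


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _perp(v):
    u = _unit(v)
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0., 1., 0.])
    return _unit(np.cross(u, ref))


def _complete_positions(center, neighbors, n_h, geometry, length, ref=None):
    """Idealized hydrogen directions for a heavy atom.

    ``neighbors`` are positions of bonded heavy atoms, ``ref`` a second-shell
    reference used to stagger rotatable hydrogens (anti conformation).
    """
    us = [_unit(np.asarray(p) - center) for p in neighbors]
    out = []
    if geometry == "sp2":
        if len(us) >= 2:
            d = -_unit(us[0] + us[1])
            out = [d]
        elif len(us) == 1:
            # in-plane NH2 (amide/guanidinium): plane from neighbor + ref
            u1 = us[0]
            if ref is not None:
                w = _unit(np.asarray(ref) - center)
                p = _unit(w - np.dot(w, u1) * u1)
            else:
                p = _perp(u1)
            c60, s60 = math.cos(math.radians(60)), math.sin(math.radians(60))
            out = [-u1 * c60 + p * s60, -u1 * c60 - p * s60][:n_h]
            if n_h == 1:
                out = [-u1 * c60 - p * s60] if ref is not None else [out[0]]
        else:
            out = [np.array([0.0, 0.0, 1.0])]
    else:  # sp3
        if len(us) == 3:
            out = [-_unit(us[0] + us[1] + us[2])]
        elif len(us) == 2:
            b = -_unit(us[0] + us[1])
            p = _unit(np.cross(us[0], us[1]))
            out = [b * math.cos(_TET_HALF) + p * math.sin(_TET_HALF),
                   b * math.cos(_TET_HALF) - p * math.sin(_TET_HALF)][:n_h]
        elif len(us) == 1:
            u1 = us[0]
            if ref is not None:
                w = _unit(np.asarray(ref) - center)
                p = _unit(w - np.dot(w, u1) * u1)
                p = -p  # anti (staggered) azimuth
            else:
                p = _perp(u1)
            ang = math.pi - math.radians(109.47)  # from the -bond direction
            axis = -u1
            e2 = _unit(np.cross(axis, p))
            for k in range(n_h):
                phi = 2.0 * math.pi * k / max(n_h, 1)
                d = (axis * math.cos(ang)
                     + (p * math.cos(phi) + e2 * math.sin(phi)) * math.sin(ang))
                out.append(_unit(d))
        else:
            out = [np.array([0.0, 0.0, 1.0])]
    return [center + length * d for d in out[:n_h]]


def _residue_maps(structure):
    res_atoms = {}
    for at in structure.atoms:
        res_atoms.setdefault(at.residue_id, {})[at.name] = at
    return res_atoms


def place_hydrogens(structure: Structure) -> int:
    """Generate idealized hydrogens for standard amino-acid residues.

    Residues that already carry hydrogens, and residues without a bundled
    template, are left untouched (the latter with a warning).  Returns the
    number of hydrogens added.
    """
    res_index = {}
    order = []
    for at in structure.atoms:
        key = at.residue_id
        if key not in res_index:
            res_index[key] = {"resname": at.resname, "atoms": {}}
            order.append(key)
        res_index[key]["atoms"].setdefault(at.name, at)

    # peptide connectivity: residues adjacent in file order on the same chain
    # whose C-N distance is bond-like
    added = []
    n_warn = 0
    for i, key in enumerate(order):
        entry = res_index[key]
        resname, atoms = entry["resname"], entry["atoms"]
        comp = next(iter(atoms.values())).component
        if comp not in (POLYMER, COVALENT_MODIFICATION):
            continue
        if resname not in HYDROGEN_COUNTS:
            info = gemmi.find_tabulated_residue(resname)
            if info and info.is_amino_acid():
                logger.warning("no hydrogen template for residue %s; skipped",
                               resname)
                n_warn += 1
            continue
        if any(a.is_hydrogen for a in atoms.values()):
            continue

        prev_c = next_n = None
        if i > 0 and order[i - 1][0] == key[0]:
            pa = res_index[order[i - 1]]["atoms"].get("C")
            na = atoms.get("N")
            if pa is not None and na is not None and \
                    np.linalg.norm(pa.position - na.position) < 1.7:
                prev_c = pa
        if i + 1 < len(order) and order[i + 1][0] == key[0]:
            na = res_index[order[i + 1]]["atoms"].get("N")
            ca = atoms.get("C")
            if na is not None and ca is not None and \
                    np.linalg.norm(na.position - ca.position) < 1.7:
                next_n = na

        bonds = BACKBONE_BONDS + SIDECHAIN_BONDS[resname]
        nbrs = {}
        for a1, a2 in bonds:
            if a1 in atoms and a2 in atoms:
                nbrs.setdefault(a1, []).append(a2)
                nbrs.setdefault(a2, []).append(a1)

        for name, (n_h, geom) in HYDROGEN_COUNTS[resname].items():
            if name not in atoms:
                continue
            heavy = atoms[name]
            neigh = [atoms[n].position for n in nbrs.get(name, [])]
            ref = None
            if name == "N":
                if prev_c is not None:
                    neigh.append(prev_c.position)
                    ref = prev_c.position  # amide H anti to the carbonyl C
                else:
                    n_h, geom = (2, "sp3") if resname == "PRO" else (3, "sp3")
            if ref is None and nbrs.get(name):
                # second-shell reference for staggering rotors
                first = nbrs[name][0]
                for nn in nbrs.get(first, []):
                    if nn != name and nn in atoms:
                        ref = atoms[nn].position
                        break
            length = H_BOND_LENGTH.get(heavy.element, 1.0)
            for pos in _complete_positions(heavy.position, neigh, n_h, geom,
                                           length, ref):
                added.append(AtomSphere(
                    position=pos, element="H", name="H" + name,
                    resname=resname, residue_id=key, component=comp,
                    is_hydrogen=True, occupancy=heavy.occupancy,
                    b_factor=heavy.b_factor))
    structure.atoms.extend(added)
    return len(added)


def prepare_hydrogens(structure: Structure, mode: str = "keep",
                      r_u: float = 1.7) -> Structure:
    """Apply the hydrogen policy and the unified-radius hydrogen shift.

    Hydrogens (van der Waals radius 1.1 A) are much smaller than the unified
    atom radius, so every hydrogen is moved ``r_u - 1.1`` A toward its bonded
    heavy atom to reduce the overestimated excluded volume.  ``mode``:
    ``keep`` existing hydrogens, ``place`` idealized ones where missing, or
    ``none`` to strip hydrogens altogether.
    """
    if r_u < 1.1:
        raise ValueError("r_u must be >= 1.1 A")
    if mode not in ("keep", "place", "none"):
        raise ValueError(f"unknown hydrogen mode {mode!r}")

    if mode == "none":
        structure.atoms = [a for a in structure.atoms if not a.is_hydrogen]
        return structure
    if mode == "place":
        place_hydrogens(structure)

    shift = r_u - 1.1
    heavy = [a for a in structure.atoms if not a.is_hydrogen]
    hydrogens = [a for a in structure.atoms if a.is_hydrogen]
    if hydrogens and heavy:
        tree = cKDTree(np.array([a.position for a in heavy]))
        kept = []
        for h in hydrogens:
            d, j = tree.query(h.position)
            if d > 1.6:
                logger.warning("hydrogen %s/%s has no bonded heavy atom "
                               "within 1.6 A; dropped", h.residue_id, h.name)
                continue
            if shift > 0 and d > 1e-9:
                u = (heavy[j].position - h.position) / d
                h.position = h.position + u * min(shift, d)
            kept.append(h)
        structure.atoms = heavy + kept
    return structure


# --------------------------------------------------------------------------
# symmetry expansion
# --------------------------------------------------------------------------

def expand_to_padded_cell(structure: Structure, margin_frac=0.5,
                          include_het=(), atom_cap: int = DEFAULT_ATOM_CAP
                          ) -> AtomSet:
    """All symmetry/lattice copies with fractional coords in [-m, 1+m) per axis.

    Only polymer and covalent-modification atoms enter the expansion; ligand,
    water and ion residues are treated as free solvent unless their residue
    name appears in ``include_het``.
    """
    margin = np.broadcast_to(np.asarray(margin_frac, dtype=float), (3,))
    cell = structure.cell
    include = {h.upper() for h in include_het}

    sel = [a for a in structure.atoms
           if a.component in (POLYMER, COVALENT_MODIFICATION)
           or a.resname.upper() in include]
    if not sel:
        raise EmptyStructureError("no atoms selected for expansion")

    pos = np.array([a.position for a in sel])
    elements = np.array([a.element for a in sel], dtype=object)
    is_h = np.array([a.is_hydrogen for a in sel])
    frac = cell.to_frac(pos)

    out_pos, out_elem, out_h, out_src, out_op, out_shift = [], [], [], [], [], []
    n_atoms = len(sel)
    src = np.arange(n_atoms)
    for k, (R, t) in enumerate(zip(cell.sym_rotations, cell.sym_translations)):
        y = frac @ R.T + t
        base = np.floor(y).astype(int)
        y0 = y - base
        # candidate extra shifts per axis given the half-open window
        reach = int(np.ceil(margin.max())) + 1
        cand = [list(range(-reach, reach + 1))] * 3
        for nx in cand[0]:
            mx = _axis_ok(y0[:, 0], nx, margin[0])
            if not mx.any():
                continue
            for ny in cand[1]:
                my = mx & _axis_ok(y0[:, 1], ny, margin[1])
                if not my.any():
                    continue
                for nz in cand[2]:
                    m = my & _axis_ok(y0[:, 2], nz, margin[2])
                    if not m.any():
                        continue
                    extra = np.array([nx, ny, nz])
                    f = y0[m] + extra
                    out_pos.append(cell.to_cart(f))
                    out_elem.append(elements[m])
                    out_h.append(is_h[m])
                    out_src.append(src[m])
                    out_op.append(np.full(m.sum(), k))
                    out_shift.append(extra - base[m])
                    if sum(len(p) for p in out_pos) > atom_cap:
                        raise MemoryCapError(
                            f"padded atom set exceeds cap of {atom_cap} atoms; "
                            "raise --memory-cap or reduce the margin")

    return AtomSet(positions=np.concatenate(out_pos),
                   elements=np.concatenate(out_elem),
                   is_hydrogen=np.concatenate(out_h),
                   source_index=np.concatenate(out_src),
                   sym_op=np.concatenate(out_op),
                   lattice_shift=np.concatenate(out_shift),
                   cell=cell)


def _axis_ok(y0, n, m):
    y = y0 + n
    return (y >= -m) & (y < 1.0 + m)


# --------------------------------------------------------------------------
# solvent-accessibility pre-filter
# --------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform directions on the unit sphere (Fibonacci spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def filter_solvent_exposed(atoms: AtomSet, probe_radius: float = 1.4,
                           r_u: float = 1.7, n_points: int = 128) -> AtomSet:
    """Keep only atoms with nonzero solvent-accessible surface.

    All atoms carry the unified radius ``r_u``; a surface sample point at
    distance ``r_u + probe_radius`` from the atom center is accessible when
    it lies outside every neighbor's expanded sphere.  Buried atoms cannot
    bound a solvent channel, so discarding them leaves all channel radii
    unchanged (up to numerical tolerance) while shrinking the Voronoi input.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    n = len(atoms)
    if n <= 2:
        return atoms
    rho = r_u + probe_radius
    dirs = _sphere_points(n_points) * rho
    tree = cKDTree(atoms.positions)
    pairs = tree.query_ball_tree(tree, 2.0 * rho - 1e-9)
    keep = np.zeros(n, dtype=bool)
    pos = atoms.positions
    for i in range(n):
        nbr = [j for j in pairs[i] if j != i]
        if not nbr:
            keep[i] = True
            continue
        samples = pos[i] + dirs
        d2 = ((samples[:, None, :] - pos[nbr][None, :, :]) ** 2).sum(-1)
        keep[i] = bool((d2 > (rho - 1e-9) ** 2).all(axis=1).any())
    return atoms.take(keep)


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------

def compute_descriptors(structure: Structure) -> CrystalDescriptors:
    """Matthews coefficient V_M = V_a / M and solvent content
    p_solv = 1 - M / (delta * V_a) with delta = 0.81 Da/A^3."""
    M = structure.mass_Da
    if M <= 0:
        raise EmptyStructureError("no polymer mass; descriptors undefined")
    V_a = structure.cell.V_a
    p_solv = 1.0 - M / (PROTEIN_DENSITY * V_a)
    if not 0.0 <= p_solv <= 1.0:
        warnings.warn(f"solvent fraction {p_solv:.3f} outside [0,1]; clamped")
        p_solv = min(max(p_solv, 0.0), 1.0)
    return CrystalDescriptors(matthews_VM=V_a / M, solvent_fraction=p_solv)
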