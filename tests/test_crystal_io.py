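"""Parsing, classification, hydrogen handling, symmetry expansion,
burial filtering and crystal descriptors."""
import warnings

import gemmi
import numpy as np
import pytest

from xtalchannels import (EmptyStructureError, NoCrystalGeometryError,
                          parse_structure)
from xtalchannels.crystal_io import (COVALENT_MODIFICATION, ION, LIGAND,
                                     POLYMER, PROTEIN_DENSITY, WATER,
                                     AtomSet, AtomSphere, CellGeometry,
                                     Structure, classify_components,
                                     compute_descriptors,
                                     expand_to_padded_cell,
                                     filter_solvent_exposed, place_hydrogens,
                                     prepare_hydrogens)
from xtalchannels.errors import MemoryCapError
from xtalchannels._residue_topology import template_hydrogen_count

CRYST1 = "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"


def _atom_line(serial, name, resname, chain, resseq, x, y, z,
               element, occ=1.0, altloc=" ", record="ATOM"):
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2}\n")


def _write(tmp_path, text, name="toy.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

def test_minimal_p1_cell(tmp_path):
    path = _write(tmp_path, CRYST1 + _atom_line(1, "CA", "GLY", "A", 1,
                                                1, 2, 3, "C") + "END\n")
    st = parse_structure(path)
    assert st.cell.n_sym == 1
    assert st.cell.V_a == pytest.approx(1000.0)
    assert len(st.atoms) == 1
    np.testing.assert_allclose(st.atoms[0].position, [1, 2, 3])


def test_missing_cryst1_is_an_error(tmp_path):
    path = _write(tmp_path, _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"))
    with pytest.raises(NoCrystalGeometryError):
        parse_structure(path)


def test_empty_structure_is_an_error(tmp_path):
    path = _write(tmp_path, CRYST1 + "END\n")
    with pytest.raises(EmptyStructureError):
        parse_structure(path)


def test_first_model_used_for_multimodel_files(tmp_path, caplog):
    text = (CRYST1 + "MODEL        1\n"
            + _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + _atom_line(2, "CA", "GLY", "A", 2, 3, 0, 0, "C")
            + "ENDMDL\nMODEL        2\n"
            + _atom_line(3, "CA", "GLY", "A", 1, 9, 9, 9, "C")
            + "ENDMDL\nEND\n")
    with caplog.at_level("WARNING"):
        st = parse_structure(_write(tmp_path, text))
    assert len(st.atoms) == 2           # model 1 only
    assert any("models" in r.message for r in caplog.records)


def test_highest_occupancy_altloc_kept(tmp_path):
    text = (CRYST1
            + _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C", 0.4, "A")
            + _atom_line(2, "CA", "GLY", "A", 1, 5, 0, 0, "C", 0.6, "B")
            + "END\n")
    st = parse_structure(_write(tmp_path, text))
    assert len(st.atoms) == 1
    assert st.atoms[0].position[0] == pytest.approx(5.0)


def test_spacegroup_operator_count(tmp_path):
    text = CRYST1.replace("P 1", "P 21 21 21") + \
        _atom_line(1, "CA", "GLY", "A", 1, 1, 1, 1, "C") + "END\n"
    st = parse_structure(_write(tmp_path, text))
    assert st.cell.n_sym == 4
    assert st.cell.V_a == pytest.approx(250.0)


def test_unknown_spacegroup_is_hard_error():
    with pytest.raises(NoCrystalGeometryError):
        CellGeometry(10, 10, 10, 90, 90, 90, "Q 5 5 5")


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def _toy(atoms, cell=None):
    return Structure(atoms, cell or CellGeometry(30, 30, 30, 90, 90, 90))


def _sphere(pos, element="C", name="C1", resname="UNL", rid=("A", 1, "")):
    return AtomSphere(position=np.asarray(pos, float), element=element,
                      name=name, resname=resname, residue_id=rid)


def test_component_classes():
    st = _toy([
        _sphere([0, 0, 0], "O", "O", "HOH", ("A", 100, "")),
        _sphere([5, 5, 5], "C", "CA", "GLY", ("A", 1, "")),
        _sphere([20, 20, 20], "S", "S", "SO4", ("A", 200, "")),
        _sphere([25, 25, 25], "NA", "NA", "NA", ("A", 300, "")),
    ])
    classify_components(st)
    comps = {a.resname: a.component for a in st.atoms}
    assert comps == {"HOH": WATER, "GLY": POLYMER, "SO4": LIGAND, "NA": ION}


def test_covalently_bound_het_treated_as_protein():
    # NAG C1 at bonding distance (1.45 A) from an Asn side-chain nitrogen
    st = _toy([
        _sphere([0, 0, 0], "N", "ND2", "ASN", ("A", 1, "")),
        _sphere([1.45, 0, 0], "C", "C1", "NAG", ("A", 201, "")),
        _sphere([2.8, 0.5, 0], "O", "O5", "NAG", ("A", 201, "")),
        _sphere([9, 9, 9], "S", "S", "SO4", ("A", 301, "")),   # 6+ A away
    ])
    classify_components(st)
    by_res = {a.resname: a.component for a in st.atoms}
    assert by_res["NAG"] == COVALENT_MODIFICATION
    assert by_res["SO4"] == LIGAND


# --------------------------------------------------------------------------
# hydrogens
# --------------------------------------------------------------------------

def test_hydrogen_shifted_toward_heavy_atom():
    c = _sphere([0, 0, 0], "C", "C", "GLY")
    h = AtomSphere(position=[1.09, 0, 0], element="H", name="H",
                   resname="GLY", residue_id=("A", 1, ""),
                   component=POLYMER, is_hydrogen=True)
    st = _toy([c, h])
    prepare_hydrogens(st, "keep", r_u=1.7)
    assert np.linalg.norm(st.atoms[1].position) == pytest.approx(0.49)


def test_no_shift_at_ru_equal_hydrogen_radius():
    c = _sphere([0, 0, 0], "C", "C", "GLY")
    h = AtomSphere(position=[1.09, 0, 0], element="H", name="H",
                   resname="GLY", residue_id=("A", 1, ""),
                   component=POLYMER, is_hydrogen=True)
    st = _toy([c, h])
    prepare_hydrogens(st, "keep", r_u=1.1)
    assert np.linalg.norm(st.atoms[1].position) == pytest.approx(1.09)


def test_orphan_hydrogen_dropped():
    h = AtomSphere(position=[0, 0, 0], element="H", name="H", resname="GLY",
                   residue_id=("A", 1, ""), component=POLYMER,
                   is_hydrogen=True)
    st = _toy([_sphere([5, 5, 5], "C", "CA", "GLY"), h])
    prepare_hydrogens(st, "keep", r_u=1.7)
    assert not any(a.is_hydrogen for a in st.atoms)


def test_mode_none_strips_hydrogens():
    h = AtomSphere(position=[1.0, 0, 0], element="H", name="H",
                   resname="GLY", residue_id=("A", 1, ""),
                   component=POLYMER, is_hydrogen=True)
    st = _toy([_sphere([0, 0, 0], "C", "CA", "GLY"), h])
    prepare_hydrogens(st, "none", r_u=1.7)
    assert len(st.atoms) == 1


def _glycine():
    geom = [("N", "N", [0.0, 0.0, 0.0]), ("CA", "C", [1.46, 0, 0]),
            ("C", "C", [2.0, 1.4, 0]), ("O", "O", [1.3, 2.4, 0]),
            ("OXT", "O", [3.2, 1.5, 0])]
    return _toy([AtomSphere(position=p, element=el, name=n, resname="GLY",
                            residue_id=("A", 1, ""), component=POLYMER)
                 for n, el, p in geom])


def test_glycine_placement_matches_template_count():
    st = _glycine()
    n = place_hydrogens(st)
    assert n == template_hydrogen_count("GLY", n_terminal=True,
                                        c_terminal=True) == 5
    # geometry sanity: every placed H sits at a standard bond length
    heavy = {a.name: a for a in st.atoms if not a.is_hydrogen}
    for h in st.atoms:
        if not h.is_hydrogen:
            continue
        d = min(np.linalg.norm(h.position - a.position)
                for a in heavy.values())
        assert 0.9 < d < 1.15


def test_placement_skips_residues_with_hydrogens():
    st = _glycine()
    place_hydrogens(st)
    n_atoms = len(st.atoms)
    assert place_hydrogens(st) == 0
    assert len(st.atoms) == n_atoms


# --------------------------------------------------------------------------
# symmetry expansion
# --------------------------------------------------------------------------

def _p1_structure(frac_positions, a=10.0):
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    atoms = [_sphere(cell.to_cart(np.asarray(f, float)), "C", "CA", "GLY",
                     ("A", i + 1, "")) for i, f in enumerate(frac_positions)]
    for at in atoms:
        at.component = POLYMER
    return Structure(atoms, cell)


def test_padded_copy_count_matches_brute_force():
    st = _p1_structure([(0.5, 0.5, 0.5)])
    out = expand_to_padded_cell(st, 0.5)
    # brute force: lattice offsets whose image lies in [-0.5, 1.5)
    count = sum(1 for nx in range(-2, 3) for ny in range(-2, 3)
                for nz in range(-2, 3)
                if all(-0.5 <= 0.5 + n < 1.5 for n in (nx, ny, nz)))
    assert len(out) == count == 8


def test_margin_zero_keeps_one_image_per_atom():
    st = _p1_structure([(0.25, 0.5, 0.75)])
    out = expand_to_padded_cell(st, 0.0)
    assert len(out) == 1
    frac = out.positions @ st.cell.frac_matrix.T
    assert np.all((frac >= 0) & (frac < 1))


def test_symmetry_expansion_against_operator_enumeration():
    cell = CellGeometry(10, 10, 10, 90, 90, 90, "P 21 21 21")
    atoms = [_sphere(cell.to_cart(np.array([0.1, 0.2, 0.3])), "C", "CA",
                     "GLY")]
    atoms[0].component = POLYMER
    st = Structure(atoms, cell)
    out = expand_to_padded_cell(st, 0.4)
    # oracle: apply every operator + every lattice shift, window filter
    ref = []
    x = np.array([0.1, 0.2, 0.3])
    for R, t in zip(cell.sym_rotations, cell.sym_translations):
        y = R @ x + t
        for n in np.ndindex(5, 5, 5):
            f = y + np.array(n) - 2
            if np.all((f >= -0.4) & (f < 1.4)):
                ref.append(f)
    ref = np.sort(np.array(sorted(map(tuple, np.round(ref, 6)))), axis=0)
    got = np.sort(np.array(sorted(map(tuple, np.round(
        out.positions @ cell.frac_matrix.T, 6)))), axis=0)
    np.testing.assert_allclose(got, ref, atol=1e-6)


def test_fractional_wrap_invariance():
    st1 = _p1_structure([(0.2, 0.6, 0.9)])
    st2 = _p1_structure([(1.2, -0.4, 2.9)])   # same atoms, shifted by lattice
    p1 = expand_to_padded_cell(st1, 0.5).positions
    p2 = expand_to_padded_cell(st2, 0.5).positions
    assert p1.shape == p2.shape
    key = lambda p: np.lexsort((p[:, 2], p[:, 1], p[:, 0]))
    np.testing.assert_allclose(p1[key(p1)], p2[key(p2)], atol=1e-9)


def test_ligands_and_waters_excluded_unless_requested():
    cell = CellGeometry(10, 10, 10, 90, 90, 90, "P 1")
    poly = _sphere([1, 1, 1], "C", "CA", "GLY")
    poly.component = POLYMER
    lig = _sphere([5, 5, 5], "S", "S", "SO4", ("A", 9, ""))
    lig.component = LIGAND
    st = Structure([poly, lig], cell)
    assert len(expand_to_padded_cell(st, 0.0)) == 1
    assert len(expand_to_padded_cell(st, 0.0, include_het=["SO4"])) == 2


def test_memory_cap_raises():
    st = _p1_structure([(0.1 * i, 0.05 * i, 0.02 * i) for i in range(10)])
    with pytest.raises(MemoryCapError):
        expand_to_padded_cell(st, 0.5, atom_cap=20)


# --------------------------------------------------------------------------
# burial filter
# --------------------------------------------------------------------------

def _atomset(positions):
    n = len(positions)
    return AtomSet(positions=np.asarray(positions, float),
                   elements=np.array(["C"] * n, dtype=object),
                   is_hydrogen=np.zeros(n, bool),
                   source_index=np.arange(n), sym_op=np.zeros(n, int),
                   lattice_shift=np.zeros((n, 3), int),
                   cell=CellGeometry(50, 50, 50, 90, 90, 90))


def test_isolated_and_touching_atoms_are_exposed():
    out = filter_solvent_exposed(_atomset([[0, 0, 0]]))
    assert len(out) == 1
    out = filter_solvent_exposed(_atomset([[0, 0, 0], [3.0, 0, 0],
                                           [20, 20, 20]]))
    assert len(out) == 3


def test_caged_atom_is_buried():
    # tight icosahedral-ish cage (two shells of sphere points) around origin
    from xtalchannels.crystal_io import _sphere_points
    cage = np.concatenate([_sphere_points(40) * 2.6,
                           _sphere_points(60) * 4.2])
    pts = np.concatenate([[[0.0, 0.0, 0.0]], cage])
    out = filter_solvent_exposed(_atomset(pts))
    kept = {tuple(p) for p in np.round(out.positions, 6)}
    assert (0.0, 0.0, 0.0) not in kept
    # the outer shell stays; the inner shell is itself buried by the outer
    assert len(out) >= 55


def test_burial_filter_is_idempotent():
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 15, (60, 3))
    once = filter_solvent_exposed(_atomset(pts))
    twice = filter_solvent_exposed(once)
    assert len(once) == len(twice)
    np.testing.assert_allclose(once.positions, twice.positions)


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------

def _structure_with_mass(n_carbons, a=10.0):
    cell = CellGeometry(a, a, a, 90, 90, 90, "P 1")
    atoms = []
    for i in range(n_carbons):
        at = _sphere([0, 0, i * 0.01], "C", "CA", "GLY", ("A", i + 1, ""))
        at.component = POLYMER
        atoms.append(at)
    return Structure(atoms, cell)


def test_solvent_content_formula():
    st = _structure_with_mass(1)
    # choose the cell so that M = 0.405 * V_a  ->  p_solv = 0.5 exactly
    mC = gemmi.Element("C").weight
    a = (mC / 0.405) ** (1 / 3)
    st = _structure_with_mass(1, a=a)
    d = compute_descriptors(st)
    assert d.solvent_fraction == pytest.approx(0.5)
    assert d.solvent_fraction + d.protein_fraction == 1.0
    assert d.matthews_VM == pytest.approx(st.cell.V_a / st.mass_Da)
    assert d.delta == PROTEIN_DENSITY


def test_fully_protein_cell_has_zero_solvent():
    mC = gemmi.Element("C").weight
    a = (mC / 0.81) ** (1 / 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = compute_descriptors(_structure_with_mass(1, a=a))
    assert d.solvent_fraction == pytest.approx(0.0, abs=1e-12)


def test_matthews_decreases_with_mass():
    v1 = compute_descriptors(_structure_with_mass(1)).matthews_VM
    v2 = compute_descriptors(_structure_with_mass(2)).matthews_VM
    assert v2 < v1


def test_zero_mass_is_an_error():
    cell = CellGeometry(10, 10, 10, 90, 90, 90, "P 1")
    lig = _sphere([0, 0, 0], "S", "S", "SO4")
    lig.component = LIGAND
    with pytest.raises(EmptyStructureError):
        compute_descriptors(Structure([lig], cell))


# --------------------------------------------------------------------------
# property tests
# --------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

frac = st.floats(-2, 3, allow_nan=False)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.tuples(frac, frac, frac), st.integers(-2, 2), st.integers(-2, 2),
       st.integers(-2, 2))
def test_expansion_is_lattice_shift_invariant(f, nx, ny, nz):
    st1 = _p1_structure([f])
    st2 = _p1_structure([(f[0] + nx, f[1] + ny, f[2] + nz)])
    p1 = expand_to_padded_cell(st1, 0.5).positions
    p2 = expand_to_padded_cell(st2, 0.5).positions
    assert p1.shape == p2.shape
    order = lambda p: p[np.lexsort((p[:, 2], p[:, 1], p[:, 0]))]
    np.testing.assert_allclose(order(p1), order(p2), atol=1e-9)


def test_mmcif_input_equivalent_to_pdb(tmp_path):
    import gemmi
    from xtalchannels import fixtures_oracle as fx

    crystal = fx.make_cubic_lattice(10.0)
    pdb_path = tmp_path / "c.pdb"
    crystal.write_pdb(pdb_path)
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "c.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    from_pdb = parse_structure(pdb_path)
    from_cif = parse_structure(cif_path, fmt="mmcif")
    assert len(from_cif.atoms) == len(from_pdb.atoms)
    assert from_cif.cell.V_a == pytest.approx(from_pdb.cell.V_a)
    np.testing.assert_allclose(from_cif.atoms[0].position,
                               from_pdb.atoms[0].position, atol=1e-3)
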