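"""End-to-end analysis pipeline: structure file in, channel report out.

Stage order: parse -> classify -> hydrogens -> symmetry expansion ->
solvent-accessibility filter -> perturbation -> Delaunay -> Voronoi ->
clip/pair/prune -> per-axis bottleneck sweeps -> optional pocket analysis ->
optional grid export.  Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import crystal_io
from .bottleneck_engine import annotate_bottlenecks
from .channel_graph import build_channel_graph, export_graph_tsv
from .crystal_io import (DEFAULT_ATOM_CAP, Structure, compute_descriptors,
                         expand_to_padded_cell, filter_solvent_exposed,
                         parse_structure, prepare_hydrogens)
from .errors import DegeneratePocketError
from .maps_descriptors import (MODE_ATOM_DISTANCE, MODE_BOTTLENECK,
                               MODE_LOCAL_RADIUS, rasterize, write_ccp4)
from .pocket_analysis import (DEFAULT_SEARCH_DISTANCE, define_pocket,
                              pocket_bottleneck, residues_from_pdb_fragment)
from .voronoi_core import (UnifiedRadiusConfig, delaunay_tetrahedralize,
                           extract_voronoi, perturb_positions)

logger = logging.getLogger(__name__)

GRID_MODES = {"bottleneck": MODE_BOTTLENECK, "local": MODE_LOCAL_RADIUS,
              "distance": MODE_ATOM_DISTANCE}


@dataclass
class RunConfig:
    """All tunables of one analysis run (defaults match the method's)."""

    input_path: str = None
    fmt: str = "auto"
    r_u: float = 1.7                 # unified atom radius, A
    r_min: float = 1.7               # minimum element radius, A
    margin_frac: float = 0.5         # symmetry-expansion padding, fractional
    include_het: tuple = ()          # HET codes kept as obstacles
    exclude_residues: str = None     # file with residues to drop (flexibility)
    pocket_ligand: str = None        # "HET[:CHAIN[:RESSEQ]]"
    pocket_file: str = None          # PDB fragment of binding-site residues
    pocket_search_distance: float = DEFAULT_SEARCH_DISTANCE
    grid_spacing: float = 0.5
    grid_modes: tuple = ()           # subset of GRID_MODES keys
    hydrogen_mode: str = "place"
    sas_filter: bool = True          # burial prefilter; assumes buried space
    sas_probe: float = 1.4           # does not percolate (true for proteins)
    perturbation_eps: float = 1e-6
    seed: int = 0
    atom_cap: int = DEFAULT_ATOM_CAP
    out_dir: str = None
    export_graph: bool = False


@dataclass
class AnalysisResult:
    report: dict
    graph: object = None
    annotation: object = None
    structure: object = None
    atoms: object = None


def _parse_exclusions(path):
    """Residue-exclusion list: a PDB fragment or 'CHAIN RESSEQ [ICODE]' lines."""
    text = Path(path).read_text()
    if "ATOM" in text[:2000] or "HETATM" in text[:2000]:
        return residues_from_pdb_fragment(path)
    out = set()
    for line in text.splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        chain, resseq = parts[0], int(parts[1])
        icode = parts[2] if len(parts) > 2 else ""
        out.add((chain, resseq, icode))
    return out


def run(config: RunConfig, structure: Structure = None) -> AnalysisResult:
    """Execute the full pipeline for one structure."""
    t0 = time.time()
    timings = {}

    if structure is None:
        structure = parse_structure(config.input_path, config.fmt)
    timings["parse"] = time.time() - t0

    if config.exclude_residues:
        excl = _parse_exclusions(config.exclude_residues)
        before = len(structure.atoms)
        structure.atoms = [a for a in structure.atoms
                           if a.residue_id not in excl]
        logger.info("excluded %d atoms in %d listed residues",
                    before - len(structure.atoms), len(excl))

    structure = prepare_hydrogens(structure, config.hydrogen_mode, config.r_u)
    descriptors = compute_descriptors(structure)

    t = time.time()
    atoms = expand_to_padded_cell(structure, config.margin_frac,
                                  include_het=config.include_het,
                                  atom_cap=config.atom_cap)
    n_expanded = len(atoms)
    if config.sas_filter:
        # a burial probe wider than r_min could delete walls of narrow channels
        atoms = filter_solvent_exposed(atoms,
                                       probe_radius=min(config.sas_probe,
                                                        max(config.r_min, 0.5)),
                                       r_u=config.r_u)
    timings["expansion_sas"] = time.time() - t

    t = time.time()
    vconf = UnifiedRadiusConfig(r_u=config.r_u,
                                perturbation_eps=config.perturbation_eps,
                                rng_seed=config.seed)
    atoms = perturb_positions(atoms, vconf.perturbation_eps, vconf.rng_seed)
    tetra = delaunay_tetrahedralize(atoms)
    raw = extract_voronoi(tetra, atoms, vconf)
    timings["voronoi"] = time.time() - t

    t = time.time()
    graph = build_channel_graph(raw, structure.cell, atoms, config.r_min)
    annotation = annotate_bottlenecks(graph)
    timings["bottlenecks"] = time.time() - t

    report = {
        "input": config.input_path,
        "cell": {"a": structure.cell.a, "b": structure.cell.b,
                 "c": structure.cell.c, "alpha": structure.cell.alpha,
                 "beta": structure.cell.beta, "gamma": structure.cell.gamma,
                 "spacegroup": structure.cell.spacegroup,
                 "n_sym": structure.cell.n_sym,
                 "volume_A3": structure.cell.cell_volume},
        "descriptors": {
            "matthews_VM_A3_per_Da": descriptors.matthews_VM,
            "solvent_content_percent": 100.0 * descriptors.solvent_fraction,
            "protein_mass_Da": structure.mass_Da,
        },
        "parameters": {"r_u": config.r_u, "r_min": config.r_min,
                       "margin_frac": config.margin_frac,
                       "hydrogen_mode": config.hydrogen_mode,
                       "seed": config.seed},
        "counts": {"asu_atoms": len(structure.atoms),
                   "padded_atoms": n_expanded,
                   "voronoi_input_atoms": len(atoms),
                   "tetrahedra": raw.n_tetra,
                   "graph_vertices": graph.n_vertices,
                   "graph_edges": graph.n_edges,
                   "surface_pairs": len(graph.pairs)},
        "channels": _channel_block(annotation, config.r_min),
    }

    if config.pocket_ligand or config.pocket_file:
        report["pocket"] = _pocket_block(structure, graph, annotation, config)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(config.input_path).stem if config.input_path else "run"
        for mode_key in config.grid_modes:
            mode = GRID_MODES[mode_key]
            unit_atoms = _unit_cell_atoms(atoms, structure.cell)
            grid = rasterize(graph, annotation, config.grid_spacing, mode,
                             atoms=unit_atoms, r_u=config.r_u)
            write_ccp4(grid, out_dir / f"{stem}_{mode_key}.ccp4")
            report.setdefault("maps", []).append(
                str(out_dir / f"{stem}_{mode_key}.ccp4"))
        if config.export_graph:
            export_graph_tsv(graph, out_dir / f"{stem}_graph.tsv", annotation)
        with open(out_dir / f"{stem}_report.json", "w") as fh:
            json.dump(report, fh, indent=2)

    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    return AnalysisResult(report=report, graph=graph, annotation=annotation,
                          structure=structure, atoms=atoms)


def _unit_cell_atoms(atoms, cell):
    frac = atoms.positions @ cell.frac_matrix.T
    inside = np.all((frac >= 0) & (frac < 1), axis=1)
    return atoms.positions[inside]


def _channel_block(annotation, r_min):
    if not annotation.has_channel:
        return {"status": "no_channels_above_cutoff",
                "main_bottleneck_radius_A": None,
                "note": f"no periodic channel with radius >= {r_min} A"}
    block = {
        "status": "ok",
        "main_bottleneck_radius_A": round(annotation.main_bottleneck_radius, 4),
        "per_axis_bottleneck_A": [round(float(x), 4)
                                  for x in annotation.per_axis_main],
    }
    if annotation.bottleneck_position is not None:
        block["bottleneck_position_A"] = [round(float(x), 3)
                                          for x in annotation.bottleneck_position]
    return block


def _pocket_block(structure, graph, annotation, config):
    try:
        if config.pocket_ligand:
            parts = config.pocket_ligand.split(":")
            lig = (parts[0],
                   parts[1] if len(parts) > 1 else None,
                   int(parts[2]) if len(parts) > 2 else None)
            pocket = define_pocket(structure, ligand=lig)
        else:
            residues = residues_from_pdb_fragment(config.pocket_file)
            pocket = define_pocket(structure, residues=residues)
        result = pocket_bottleneck(graph, annotation, pocket,
                                   config.pocket_search_distance)
    except DegeneratePocketError as exc:
        return {"status": "no_voronoi_elements", "error": str(exc)}
    block = {
        "status": result.status,
        "r_b_poc_A": round(result.r_b_poc, 4),
        "inside_radius_A": round(result.inside_radius, 4),
        "n_shell_vertices": result.n_shell_vertices,
        "n_pocket_residues": len(pocket.residues),
    }
    if result.bottleneck_position is not None:
        block["bottleneck_position_A"] = [round(float(x), 3)
                                          for x in result.bottleneck_position]
    return block
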