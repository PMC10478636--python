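# Methods

## The question and the model

Soaking — diffusing a small molecule into a preformed apo crystal — fails
when the crystal's solvent channels are too narrow or not actually periodic.
This package models a ligand as a rigid sphere and asks: what is the radius
of the largest sphere that can travel an *infinite periodic path* through
the crystal and reach a given position?  Two features distinguish this from
single-protein tunnel finders: the path quality is its *bottleneck* (the
narrowest passage), with no length-dependent cost, and the path must be
periodic — traversing one unit cell is not enough if the exit does not map
onto the entrance of the next cell.

## Geometry stage

Atoms are modelled as spheres of one **unified radius** `r_u` (default
1.7 Å, the carbon van der Waals radius), which reduces the weighted-sphere
problem to a point Voronoi diagram: the clearance of any Voronoi element is
the distance to its generator atoms minus `r_u`.  Hydrogens (vdW 1.1 Å) are
much smaller, so each hydrogen center is displaced `r_u − 1.1` Å toward its
bonded heavy atom; when a structure carries no hydrogens they are generated
from idealized amino-acid templates (bundled topology table, tetrahedral/
trigonal completion, staggered rotors, NE2-H histidine tautomer, charged
termini).  Nucleotide templates are not bundled; such residues are skipped
with a warning.

Waters, free ligands and ions are treated as mobile solvent and excluded
(`--include-het` re-includes selected residues); HET groups covalently
bonded to the polymer (inter-atomic distance below the sum of covalent
radii + 0.4 Å) count as part of the protein, as a glycosylated surface
genuinely narrows a channel.

The asymmetric unit is expanded by the space-group operators (gemmi
symmetry tables) plus lattice translations into a padded block covering
fractional `[-m, 1+m)` per axis.  The default margin `m = 0.5` (≈ 8 cells)
is correct for protein-dense cells, where no Voronoi element of the central
cell can be influenced by atoms more than half a cell away.  Sparse
synthetic cells (e.g. the one-atom cubic lattice) violate that assumption
and are analyzed with `m = 1`.

Atoms with zero solvent-accessible surface (spherical-probe test at the
unified radius, probe `min(1.4 Å, r_min)`) are discarded before
tetrahedralization.  This assumes buried space does not *percolate*: in a
protein crystal the buried cores are isolated blobs, so the voids left by
removing them stay sealed behind sub-probe throats (below the pruning
cutoff).  Solid amorphous walls — as in the synthetic fixtures — break that
assumption, so fixture analyses disable the filter (`sas_filter=False`).

Input points are perturbed uniformly within 1e-6 Å (seeded) to break the
coplanarity/cocircularity that crystal symmetry and ring systems produce.
The perturbation is applied *after* expansion: perturbing the asymmetric
unit alone would leave lattice-translated degeneracies intact.  The
Delaunay tetrahedralization comes from Qhull (`scipy.spatial.Delaunay`);
near-degenerate configurations can leave a few zero-volume sliver
tetrahedra whose dual elements are either clipped away or harmless
near-duplicates.  Circumcenters are solved in batch; hull faces dualize to
rays truncated at the padded boundary (they cannot survive clipping at the
default margin).

## Channel graph

The raw diagram is cut at the central cell (half-open fractional box
`[0,1)³`; all face bookkeeping is fractional, so triclinic cells need no
special casing).  Edges crossing a face are split there into **surface
vertices** whose radius is the generator distance at the crossing minus
`r_u`.  Because the padded atom set is lattice-periodic, every crossing has
a twin on the opposite face produced by the translated image of the same
raw edge; twins are matched primarily by generator provenance (source atom,
symmetry operator, lattice shift) and geometrically by face coordinates
within 1e-4 fractional units as a fallback (Qhull may triangulate
degenerate patches differently on the two faces, changing the generator
triangles but not the crossing position).  Matched twins form a **surface
vertex pair** joined by an *artificial periodic edge* whose radius is the
min of the member radii — passage into the neighboring cell is limited by
the narrower side.  Unmatched crossings are dropped as clipped dead ends.
Elements below `r_min` (default 1.7 Å; lower it to 0.5 Å when screening
ligands with a minimum projection radius below the default) are pruned;
an empty graph is reported as "no channels above cutoff", not an error.

## Bottleneck sweep

Per cell axis, all edges are processed in descending radius order (stable,
edge-id tiebreak) through a union–find forest.  Artificial edges on the two
faces perpendicular to the swept axis are excluded — the checked surface is
non-passable, otherwise a cavity sliced by the boundary would register as a
channel — while artificial edges of the other two face pairs participate,
which is what detects corridors that wind through neighboring cells.  A set
*completes* when it contains both members of a swept-axis pair (the channel
re-enters where its image exits); at that moment every vertex in the set is
annotated with the current edge radius, and vertices merging in later
inherit the (smaller) radius of their joining edge.  The per-vertex local
bottleneck radius `r_b(v)` is the max over the three axis sweeps; never
above the local clearance `r(v)`.  The largest `r_b(v)` is the main-channel
(1D) bottleneck; its location is found by BFS over vertices with
`r_b ≥ target` for the first edge realizing the target radius, reported at
the point of that edge nearest its generator atoms.

**Semantics caveat.** Pair closure is a deliberate approximation of true
periodic reachability.  Every radius it reports corresponds to a real
path (the quotient path lifts to an explicit tiling path), but paths that
only close through a *combination* of distinct pairs — e.g. one pair used
forward and another backward, or channels whose lattice period is a
multiple of the axis vector — are not credited.  The test suite pins this
down: the sweep equals an independent thresholded recomputation of the
same criterion exactly, and is everywhere a lower bound of explicit-tiling
reachability, with equality for the main channel on all fixtures.

## Pockets

A pocket is the convex hull of all atoms of the residues within 6.5 Å
(inclusive, any-atom) of a chosen ligand instance, or of residues given as
a PDB fragment.  Since the binding event itself is outside the model, the
reported quantity is `r_b,poc`: the largest `r_b(v)` among vertices within
a search shell (default 4.0 Å, one hydration shell — the shell width is a
convention of this implementation and a known source of divergence when
comparing against other implementations) of the hull, with vertex-to-hull
distances minimized over the 27 neighboring lattice translates.  Flat
two-residue surface sites give a degenerate hull (`no_voronoi_elements`);
shells whose vertices all have `r_b = 0` are fully enclosed voids.

## Grids and maps

`rasterize` stamps every vertex sphere (center `v`, radius `r(v)`) onto a
unit-cell grid (default spacing 0.5 Å), each grid point keeping the largest
`r_b(v)` among covering spheres (modes: local radius `r(v)`, or plain
distance-to-atom-surface).  Isocontouring the map at level `r'` displays
exactly the space a sphere of radius `r'` can roam on an infinite periodic
path; contour at absolute values, not σ.  Maps are CCP4/MRC mode 2 via
gemmi, one exact unit cell, origin at fractional (0,0,0), P1 map-header
symmetry (crystal symmetry is already baked into the values).

## Descriptors

Solvent content `p_solv = 1 − M/(δ·V_a)` with δ = 0.81 Da Å⁻³ and
`V_a = V_cell/n_sym`; Matthews coefficient `V_M = V_a/M`.  The mass `M`
counts polymer and covalent-modification atoms including placed hydrogens,
each once (the highest-occupancy altloc is kept at parse time; no occupancy
weighting).  Values outside [0,1] are clamped with a warning — synthetic
wall crystals are denser than any protein.

## Ligand size proxy

The minimum projection radius (MPR) of a conformer is the radius of the
smallest circle enclosing all van der Waals disks after projection onto a
plane, minimized over projection directions; for an ensemble, the minimum
over conformers.  Directions are the first `n` terms (default 512) of an R2
low-discrepancy sequence on the hemisphere — prefixes are nested, so a
larger budget can only lower the result — followed by Nelder–Mead
refinement of the best direction (tolerance ~1e-3 Å).  The 2D enclosing
circle minimizes the convex function `max_i(|c−p_i| + r_i)`, using the
farthest inflated pair as certificate and initial guess.  Radii are Bondi
values with the 1.1 Å Rowland–Taylor hydrogen; for monoatomic ions supply a
literature ionic radius (`--ion-radius`).  Note that for flat molecules the
minimizing direction is *edge-on*, not the ring normal: benzene's MPR is
1.39·sin 60° + 1.7 ≈ 2.90 Å.

## Synthetic study crystals and oracles

The fixtures are P1 toy crystals with channel archetypes whose answers are
known from pure geometry: a one-atom cubic lattice (per-axis bottleneck
`a/√2 − r_u`, exact); a straight carved tube; a laterally displaced tube
whose periodic images do not line up (blocked, though a one-cell view shows
a traversing void); a zigzag corridor with lattice period (1,1,0) that only
closes through a y-face crossing (detected only with orthogonal artificial
edges); a dead-end cavity behind a narrow throat; and a fully enclosed
void.  Walls are dense atom grids (1.0 Å spacing); corridor expectations
are computed at generation time as the minimum distance from the corridor
centerline to the placed wall atoms minus `r_u`, i.e. they carry the exact
wall-discretization correction and are *lower* bounds — the optimal Voronoi
path may clear slightly more by weaving between wall atoms.

The independent oracle is the classical distance-map approach: a periodic
distance grid (cKDTree over 27 lattice images), thresholded and
flood-filled with 26-connectivity, periodic wrap on the orthogonal axes
only, and the face-projection condition on the swept axis.  Its systematic
underestimation bound is half the largest point-to-grid distance,
`√3·spacing/2` (+0.05 Å numerical allowance); the Voronoi result is exact,
which is the methodological point of the package.

What the fixtures do *not* emulate: real packing density and contact
topology, symmetry beyond P1 in the channel geometry (symmetry expansion is
exercised separately against operator enumeration), B-factor/occupancy
disorder, and protein flexibility.  Passing fixture tests therefore
validates the geometric and algorithmic machinery, not predictions about
any particular crystal; flexible loops remain the dominant caveat when
interpreting narrow bottlenecks on real structures.

## Problem sizes and determinism

Test and acceptance runs use cells of 10–15 Å with 1 000–2 500 wall atoms
(≈ 7 000–17 000 padded Voronoi input points, 50 000–120 000 tetrahedra),
sizes chosen so the full validation cycle completes in well under a minute
while leaving the corridor widths far above the discretization scales.
Every stochastic element (the 1e-6 Å perturbation; nothing else) is driven
by one seed; identical input and seed give bit-identical annotations, and
different seeds move fixture bottlenecks by < 1e-4 Å.

## Known limitations

- Pair-closure reachability (above): multi-pair and multi-period paths are
  missed; enclosed side regions cut by the checked surface are isolated by
  design.
- Memory heuristic: the padded-atom cap (default 6·10⁶ atoms) aborts runs
  that would exhaust a desktop machine; raise `--memory-cap` for virus
  capsid-scale cells.
- Rigid model: no flexibility, no induced fit; residue exclusion lists
  (`--exclude-residues`, e.g. from electron-density quality screening) are
  the supported workaround.
- Hydrogen templates cover the 20 standard amino acids only.
- A sphere is a crude ligand model; non-globular molecules are better
  described by an ellipsoid, and the MPR underestimates steric demands of
  elongated conformers passing bent channels.
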