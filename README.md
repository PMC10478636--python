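# xtalchannels

Solvent-channel and bottleneck-radius analysis of protein crystals.

Crystallographers obtain most protein–ligand structures by *soaking*: a
small molecule diffuses into a preformed apo crystal through its solvent
channels.  Soaking fails silently when the channels are too narrow for the
ligand — or when a channel that appears to traverse the unit cell is not
actually periodic and dead-ends one cell over.  `xtalchannels` answers,
before the experiment, the question "how large a sphere can travel an
infinite periodic path through this crystal, and can it reach this binding
site?".

## Method in brief

For a structure with a valid CRYST1 record the package:

1. expands crystallographic symmetry into a padded super-cell and models
   all atoms as spheres of a unified radius *r*ᵤ (1.7 Å);
2. builds the Voronoi diagram of the padded atom set (dual of a Delaunay
   tetrahedralization) — its vertices and edges trace the loci of locally
   maximal clearance, with radii *r*(v), *r*(e) = generator distance − *r*ᵤ;
3. clips the diagram to one unit cell and restores periodicity with
   *artificial edges* joining surface vertices that project onto each other
   on opposite cell faces;
4. sweeps the edges once per cell axis in descending radius order through a
   union–find forest: the moment a vertex set connects a surface vertex
   with its own periodic image, the current edge radius is the exact
   widest-path bottleneck for every vertex in the set.  Each vertex v ends
   up with its local bottleneck radius
   *r*_b(v) = max radius of a sphere that reaches v on a periodic path,
   and the largest *r*_b(v) is the bottleneck of the crystal's main
   channel;
5. compares these radii with the ligand's *minimum projection radius*
   (smallest enclosing circle of the projected van der Waals disks,
   minimized over directions), reports the Matthews coefficient
   *V*_M = *V*_a/*M* and solvent content *p*_solv = 1 − *M*/(0.81·*V*_a),
   scores binding pockets (largest *r*_b(v) near the pocket's convex
   hull), and exports CCP4 maps whose isosurface at level *r*′ is exactly
   the space a sphere of radius *r*′ can roam.

Unlike grid-based channel mapping, the Voronoi construction has no
discretization bias — the package ships a grid flood-fill oracle purely as
an independent cross-check of its own results.

## Worked example

Every stage is testable without downloads through synthetic P1 crystals
with analytically known channels.  The simplest is one carbon atom in a
10 Å cubic cell; its widest periodic path runs through the cell face
centers, whose nearest atoms are the four face corners at distance
10/√2 Å, so the bottleneck must be 10/√2 − 1.7 = 5.3711 Å:

```sh
$ xtalchannels fixture cubic demo.pdb --cell 10
$ xtalchannels analyze demo.pdb --hydrogens keep --margin 1.0
```

prints (abridged):

```json
{
  "cell": {"a": 10.0, "spacegroup": "P 1", "n_sym": 1, "volume_A3": 1000.0},
  "counts": {"padded_atoms": 27, "tetrahedra": 95,
             "graph_vertices": 20, "graph_edges": 28, "surface_pairs": 6},
  "channels": {
    "status": "ok",
    "main_bottleneck_radius_A": 5.3711,
    "per_axis_bottleneck_A": [5.3711, 5.3711, 5.3711],
    "bottleneck_position_A": [10.0, 5.0, 5.0]
  }
}
```

The main bottleneck matches the closed form to the printed precision, the
per-axis radii agree by cubic symmetry, and the reported bottleneck
position sits at a cell face center — the narrowest point of the path.

On a real structure you would run e.g.

```sh
xtalchannels analyze 2dqm.pdb --pocket-ligand BES \
    --grid-mode bottleneck --out results/
```

which additionally reports the pocket bottleneck `r_b_poc_A` for the
bestatin site and writes `2dqm_bottleneck.ccp4` for contouring in PyMOL,
Chimera or Coot (contour at absolute radii, not σ).  A ligand's size proxy
comes from `xtalchannels mpr conformers.sdf`; if its ensemble-minimum
projection radius is below 1.7 Å, rerun the analysis with `--r-min 0.5`.

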