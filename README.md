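# pepforge

Tools for building **tangible, measurable peptide models**: segment a peptide
into rigid fragments hinged at its rotatable torsions, emit 3D-printable CAD
scripts for the pieces and for a carved receptor mold, and evaluate any
conformation the user dials in on the physical model back *in silico* —
energies, steric feasibility, and discrete-surface contact scores.

## Who this is for

Structure-based drug design couples shape and charge complementarity between
a ligand and a receptor pocket. Physical space-filling models give an
immediate tactile sense of that complementarity but historically could not be
*measured*; software can measure everything but offers no tactile channel.
pepforge is the computational half of a hybrid workflow: it designs printable
parts whose joints carry angle-measurement ticks, and it reconstructs and
scores whatever conformation was assembled by hand.

## The model

A peptide's conformation is fully described by its torsion angles: each
residue contributes the backbone dihedrals φ (C′₋₁–N–Cα–C′), ψ (N–Cα–C′–N₊₁)
and ω (Cα–C′–N₊₁–Cα₊₁, planar-locked near 180°), plus 0–4 side-chain
dihedrals χ₁…χ₄. Deleting every unlocked torsion's axis bond from the
covalent graph partitions the atoms into **rigid fragments**; each cut bond
becomes a revolute joint realized physically as a keyed male/female port
pair. Two segmentations are supported: *fine* (every rotatable bond is a
joint) and *coarse* (the user keeps only chosen torsions, e.g. splitting a
21-residue chain into three ~7-residue pieces).

Evaluation uses:

* **Nonbonded energy** — Lennard-Jones `ε[(rmin/r)¹² − 2(rmin/r)⁶]` plus
  Coulomb `k·qᵢqⱼ/(D·r)` with `k = 332.0636 kcal·Å/(mol·e²)`; 1-2/1-3 pairs
  excluded, 1-4 pairs divided by 2.0 (LJ) and 1.2 (Coulomb).
* **Hard-sphere feasibility** — a conformation is reachable iff no
  non-excluded pair is closer than `s·(Rᵢ+Rⱼ)` at radius scale `s` (default
  0.7, matching the printed parts, which shrink atom radii to enlarge the
  reachable conformation space).
* **Grid scans** — two torsions stepped over the full circle (20° increments
  give an 18 × 18 Ramachandran-style mesh) recording energy and feasibility
  per cell, as offsets from the native angles.
* **Contact scoring** — approximately equidistant surface marks (Fibonacci
  lattice) on each atom sphere; the receptor surrogate is a *semi-perfect
  template*: a box minus the ligand's atom spheres and their upward sweeps,
  so the native conformation fits it perfectly. A mark scores when it
  touches mold material within a paint-film tolerance (default 0.5 Å).

## Worked example

Build an ideal-geometry tetrapeptide fixture, segment its first 3.5 residues
(side chains locked), scan φ/ψ of residue 2, and emit printable parts:

```
$ pepforge fixture AVSE -o tetra.pdb --torsion 2:phi=-70 --torsion 2:psi=-35
{ "output": "tetra.pdb", "atoms": 27,
  "side_chain_charges": {"ALA1": 0.0, "VAL2": 0.0, "SER3": 0.0, "GLU4": -1.0} }

$ pepforge fragment tetra.pdb --residues 1:3.5 -o frag
{"fragments": 7, "joints": 6, "torsions": 11}

$ pepforge scan tetra.pdb --residues 1:3.5 --torsion-a phi_2 --torsion-b psi_2 --increment 20 -o scan
{"cells": 324, "per_axis": 18, "feasible": 223, "term": "total"}

$ pepforge cad tetra.pdb --residues 1:3.5 -o parts
{"parts": 7, "outdir": "parts"}
```

Reading the output: the 3.5-residue stretch has six rotatable backbone bonds
(ψ₁, φ₂, ψ₂, φ₃, ψ₃, φ₄), so it splits into **7 rigid pieces**; the glutamate
side chain carries net charge −1 e at pH 7, which the CAD export renders as
bar-shaped charge glyphs on its carboxylate spheres; of the 324 cells in the
18 × 18 φ/ψ mesh, 223 are sterically reachable at radius scale 0.7. The
`parts/` directory holds one OpenSCAD-dialect script per piece (keyed joint
pins/holes, measurement tick rings) plus a JSON manifest; render with any
CSG tool, e.g. `openscad -o F1.stl parts/F1.scad`.

The `score` command compares reported conformations against the mold
(`pepforge score … --states states.yaml`), and `build` reconstructs PDB
coordinates from angles read off the physical model's tick marks.

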