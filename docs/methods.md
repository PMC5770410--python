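# Methods

## Molecular model

A peptide is modeled as atoms (position, element, van der Waals radius,
partial charge) grouped into residues and joined by covalent bonds. The
conformational degrees of freedom are named torsions: per residue φ, ψ, ω
and χ₁…χ₄ where the defining atom quad exists. ω is always emitted locked
(peptide-bond planarity); χ torsions are locked unless the residue is
explicitly made mobile (this is also how receptor side-chain mobility is
expressed: pass the receptor system with the chosen residue indices). A
torsion whose axis lies in a ring (proline χ) can never disconnect the bond
graph and is therefore always locked; ring detection uses graph bridges.

Rigid fragments are the connected components left after deleting every
unlocked torsion's axis bond. On the acyclic graphs produced by peptides
this gives exactly (cuts + 1) fragments. Each cut bond becomes a revolute
joint with a gendered port pair: the fragment holding the N-proximal axis
atom (CA-proximal for χ joints) carries the male pin, and the key polygon of
the pin/hole pair is chosen per joint kind (φ/ψ/χ/custom → triangle, square,
pentagon, hexagon), so a φ pin cannot enter a ψ hole and mis-assembly is
blocked by geometry rather than instructions. Finer per-joint keying would
multiply part variety without adding protection against the realistic error
modes (wrong joint kind, flipped gender), so kind-level keying is the
default.

## Ideal-geometry builder

Peptides are constructed ab initio from a bundled internal-coordinate table:
Engh–Huber-style backbone lengths/angles (N–Cα 1.458 Å, Cα–C′ 1.525 Å,
C′–N 1.329 Å, C′–O 1.231 Å) and per-residue side-chain Z-matrix rows with
standard sp³/sp² values; rings close to within normal bond lengths by
construction. Placement uses the natural extension reference frame (NeRF),
so requested torsions are reproduced exactly up to floating point. Defaults
are an extended backbone (φ = −135°, ψ = 135°, ω = 180°) and common rotamer
χ values; the extended default build of every residue type passes the
hard-sphere test at radius scale 0.7. The L-configuration is fixed by the
Cβ improper (Cβ–Cα–N–C′ = −122.5°), validated against an independent
structural library's ideal residue templates.

Partial charges are a bundled united-atom set at pH 7 (GLU/ASP deprotonated,
LYS/ARG protonated, HIS neutral): hydrogen charges are folded into their
parent heavy atoms so that side-chain and residue net charges are exact
(−1, +1, 0) in the default heavy-atom representation. They are
Amber-flavored in spirit but are not a verbatim published charge set; any
calculation needing literature charges should load them from a mol2 file,
whose charge column is passed through verbatim. Van der Waals radii are
Bondi-style per-element values (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å).
Optional hydrogen completion is geometric (tetrahedral/trigonal) and does
not optimize rotatable H orientations.

## Kinematics

`apply_conformation` holds one anchor fragment fixed (default: the
N-terminal piece, matching how the physical model is held) and processes
joints breadth-first outward, rotating each downstream subtree rigidly about
the current joint axis by the angle needed to reach the requested dihedral.
Tie-breaks are by joint id, so reconstruction is deterministic. Because
every move is a rigid rotation of a whole subtree, intra-fragment geometry
and all bond lengths are preserved exactly and locked joints keep their
native angles without special handling. Angles live in degrees on
(−180°, 180°]; measurement-tick quantization is a CLI-level concern, not a
kernel one.

## Energetics

Only nonbonded terms are computed: fragments are rigid, so bonded
stretch/bend terms are constant along every exposed degree of freedom. The
grid scans therefore show a nonbonded potential energy, not a free energy —
no solvation, entropy or minimization. Pair bookkeeping excludes 1-2/1-3
pairs and scales 1-4 pairs by the conventional divisors (2.0 LJ, 1.2
Coulomb). LJ combining is arithmetic in rmin/2 and geometric in ε; the
Coulomb constant is 332.0636 kcal·Å/(mol·e²) with a constant dielectric
(default 1). Coincident atoms report +inf rather than raising.

Feasibility uses the same exclusion list: clashes between 1-4 atoms count,
which is consistent with the printed parts (atoms within one rigid piece are
fused and cannot collide; the closest inter-piece approaches are ≥3 bonds
apart). The 0.7 radius scale deliberately widens the reachable space;
because 0.7·(Rᵢ+Rⱼ) always lies inside the LJ repulsive wall for the bundled
parameters, every hard-sphere violation also has positive pair LJ energy, so
the steric mask is a conservative subset of the energy landscape.

Scans step both torsions over the full circle at a fixed increment (20° →
18 values per axis, 324 cells) and report axes as deviations from the native
angles with the native cell at (0, 0). An electrostatic-only view exposes
the Coulomb term alone, used for charge-complementarity maps of systems like
the glutamate/lysine three-piece demonstration, where the cell minimizing
the distance between the charged groups is also the Coulomb minimum.

## Surface contact scoring

Surface marks are placed per atom on a deterministic Fibonacci spiral with
count `round(density·4πR²)`; marks strictly inside another atom's sphere are
pruned. Marks, printed parts and the mold all use the same radius scale
(default 0.7): if marks sat at full radius while the mold was carved at
0.7×, every native mark would be embedded in mold material and the perfect
native fit would register as a collision, so a single consistent scale is
used throughout.

The semi-perfect template is an implicit CSG solid: an axis-aligned box
minus each atom sphere and its sweep toward the pull direction (+z by
default, extended to the box top — the shape left after pressing the ligand
into a block and withdrawing it straight up). The box footprint is the
bounding box of atom centers across the pull axis padded by the largest
scaled radius; its height is the *lower half* of the centers' vertical
extent. "Half the size of the bounding box" is genuinely ambiguous (half
each axis? half the volume?); the lower-half-height reading keeps every
atom's resting pocket while leaving the upper half open for manipulation,
and it is isolated in `make_template` so alternative readings are one-line
swaps.

A mark scores when it is not inside material and its distance to material is
within the tolerance (default 0.5 Å — a stand-in for the physical paint-film
thickness, which has no single measured value). Distances are evaluated
analytically against box faces, carve-sphere surfaces and sweep-cylinder
walls; every candidate foot point is validated by probing 10⁻⁴ Å past the
surface and re-testing membership, and compound candidates on the rim
circles where carves pierce box faces handle the material slivers there.
Points within 10⁻⁶ Å of a surface are classified as touching (void), so a
mark resting exactly in its pocket counts as contact, not collision. The
residual approximation (distances to higher-order surface intersections can
be slightly overestimated) is far below the 0.5 Å tolerance in practice and
is bounded in tests by a dense-sampling oracle.

Conformation comparison (`match_profile`) holds the anchor fragment at its
native pose — the same rule the physical protocol uses when one piece is
kept seated in the pocket — and reports counts plus a collision flag. An
optional rigid-fit refinement was considered and left out: it changes the
question from "how well does this conformation fit" to "how well can it be
docked", which is a different tool.

## CAD emission

Scripts use a restricted OpenSCAD-dialect vocabulary (sphere, cylinder,
cube, union, difference, intersection, translate, rotate) with fixed
6-decimal formatting, so output is byte-deterministic and renderable by any
CSG engine. The default scale is 4 mm/Å (a carbon sphere at 0.7 radius
scale prints 9.5 mm across — hand-sized); joint pins default to 5 mm
diameter × 6 mm depth with 0.3 mm clearance added to holes only. Female
port rims carry tick notches every `tick_increment_deg` (default 20°, i.e.
18 ticks) with every third notch deepened as an index. Charge glyphs encode
sign by shape (cross = +, bar = −) with population `round(|q|/0.1 e)`.
Large parts can be sliced into equal slabs whose union reproduces the
original solid, for printers with small platforms. STL meshing and slicing
are delegated to external tools (OpenSCAD, any slicer).

## Synthetic fixtures and what the tests show

All test inputs are generated by the ideal-geometry builder (the
tetrapeptide stand-in places valine second, mirroring the backbone-scan
demonstration setup). These fixtures have exact ideal geometry, no
hydrogens, no solvent, single chains and neutral termini; passing tests
demonstrate the correctness of the segmentation, kinematics, energetics and
scoring machinery on such chains, not force-field accuracy on experimental
structures. Real PDB input goes through the same code path (first model,
highest-occupancy altlocs, template-based bond inference with a 1.8 Å
peptide-bond break check), but experimental artifacts (missing atoms,
nonstandard residues, alternate protonation) receive only the documented
fallbacks (specs suppressed, charges zeroed with a warning).

Problem sizes in the default test run and the acceptance script (100
round-trip conformers, 50 fixture draws × 20–50 perturbations at mark
density 0.6 Å⁻², 18 × 18 scans on ≤30-atom systems) were chosen to exercise
the statistical properties while keeping a full run in the minutes range on
one CPU.

## Known limitations

* Peptide chains only; no nucleic acids, no general small-molecule rotatable
  bond perception, one ligand + one receptor at a time.
* No inverse kinematics/loop closure, no energy minimization, no solvation
  or entropy terms.
* mmCIF is not read; PDB CONECT records are honored only when their serials
  match the kept atoms one-to-one.
* The bundled charge/radius/geometry tables are documented stand-ins chosen
  for self-consistency, not fitted parameters.
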