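"""Synthetic demonstration systems built from the ideal-geometry tables.

Everything here is generated, not measured: these are stand-ins that let the
full pipeline (read, segment, print, score) run without any external
structure download.
"""

from __future__ import annotations

import numpy as np

from . import fragmentation, structure_io
from .kinematics import ConformationState


def synthetic_tetrapeptide() -> structure_io.MolecularSystem:
    """Synthetic stand-in for an N-terminal peptide stretch (valine second,
    as in the backbone-scan demonstration), with mixed helical/extended
    backbone angles so the chain is conformationally nontrivial."""
    return structure_io.build_ideal_peptide(
        "AVSE",
        torsions={1: {"psi": 150.0},
                  2: {"phi": -70.0, "psi": -35.0},
                  3: {"phi": -120.0, "psi": 140.0},
                  4: {"phi": -80.0}})


def glu_lys_three_piece():
    """Three-piece chain with one negatively charged (GLU) and one positively
    charged (LYS) side chain at the pH-7 charge set, flexible via two main
    chain angles.  Returns (system, torsions, graph, theta_ids)."""
    system = structure_io.build_ideal_peptide("EGK")
    torsions = fragmentation.identify_torsions(system, mobile_side_chains="none")
    theta = ("psi_1", "phi_3")
    graph = fragmentation.coarse_fragment(system, torsions, keep=theta)
    return system, torsions, graph, theta


def random_state(graph, rng: np.random.Generator,
                 min_offset: float = 0.0) -> ConformationState:
    """Uniform random angles for every unlocked joint; with ``min_offset``
    each angle is pushed at least that many degrees away from native."""
    from .kinematics import extract_conformation
    from .geometry import normalize_angle
    specs = [spec for spec, _, _ in graph.joints.values()]
    native = extract_conformation(graph.system, specs)
    angles = {}
    for spec, _, _ in graph.joints.values():
        if spec.locked:
            continue
        if min_offset > 0:
            sign = rng.choice([-1.0, 1.0])
            off = rng.uniform(min_offset, 180.0)
            angles[spec.id] = normalize_angle(native[spec.id] + sign * off)
        else:
            angles[spec.id] = rng.uniform(-180.0, 180.0)
    return ConformationState(angles)


def to_mol2(system: structure_io.MolecularSystem, path) -> None:
    """Minimal TRIPOS mol2 writer (fixture plumbing for the mol2 reader)."""
    lines = ["@<TRIPOS>MOLECULE", "pepforge-fixture",
             f"{len(system.atoms)} {len(system.bonds)} 0 0 0",
             "SMALL", "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for a in system.atoms:
        res = system.residues[a.residue_index]
        x, y, z = a.position
        lines.append(f"{a.serial:>7} {a.name:<4} {x:>10.4f} {y:>10.4f} "
                     f"{z:>10.4f} {a.element:<5} {a.residue_index + 1} "
                     f"{res.name}{a.residue_index + 1} {a.partial_charge:>8.4f}")
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(sorted(system.bonds), start=1):
        lines.append(f"{k:>6} {i:>5} {j:>5} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
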