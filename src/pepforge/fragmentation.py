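"""Rotatable-torsion identification and rigid-fragment decomposition.

A rigid fragment is a maximal connected set of atoms containing no unlocked
rotatable bond; cutting every unlocked torsion axis yields the "fine"
segmentation, cutting a user-chosen subset the "coarse" one.  Each cut bond
becomes a revolute joint realized physically by a gendered, keyed male/female
port pair so parts can only assemble the intended way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from ._tables import BACKBONE_ATOMS, residue_templates
from .errors import FragmentationError

log = logging.getLogger(__name__)

#: key polygon class per joint kind — distinct keys block wrong assemblies
KEY_INDEX = {"phi": 0, "psi": 1, "chi": 2, "custom": 3, "omega": 4}


@dataclass
class TorsionSpec:
    id: str
    kind: str                      # phi | psi | omega | chi1..chi4 | custom
    residue_index: int
    atom_quad: tuple[int, int, int, int]
    locked: bool = False
    range: tuple[float, float] = (-180.0, 180.0)

    @property
    def axis_bond(self) -> tuple[int, int]:
        b, c = self.atom_quad[1], self.atom_quad[2]
        return (b, c) if b < c else (c, b)

    @property
    def key_class(self) -> int:
        kind = "chi" if self.kind.startswith("chi") else self.kind
        return KEY_INDEX.get(kind, KEY_INDEX["custom"])


@dataclass
class Port:
    gender: str                    # "male" | "female"
    joint_id: str
    anchor_atom: int
    axis_direction: np.ndarray     # unit vector, male anchor -> female anchor
    key_index: int


@dataclass
class RigidFragment:
    id: str
    atom_serials: frozenset[int]
    role: str = "main_chain"       # main_chain | side_chain
    ports: list[Port] = field(default_factory=list)


@dataclass
class FragmentGraph:
    system: object
    fragments: list[RigidFragment]
    #: joint id -> (TorsionSpec, male fragment id, female fragment id)
    joints: dict[str, tuple[TorsionSpec, str, str]]

    def fragment_of(self, serial: int) -> RigidFragment:
        for frag in self.fragments:
            if serial in frag.atom_serials:
                return frag
        raise KeyError(serial)

    def to_json(self) -> str:
        payload = {
            "fragments": [
                {"id": f.id, "atoms": sorted(f.atom_serials), "role": f.role,
                 "ports": [{"gender": p.gender, "joint": p.joint_id,
                            "anchor_atom": p.anchor_atom,
                            "axis_direction": [float(x) for x in p.axis_direction],
                            "key_index": p.key_index} for p in f.ports]}
                for f in self.fragments
            ],
            "joints": {
                jid: {"male": male, "female": female,
                      "torsion": {**asdict(spec),
                                  "atom_quad": list(spec.atom_quad),
                                  "range": list(spec.range)}}
                for jid, (spec, male, female) in self.joints.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Torsion identification
# ---------------------------------------------------------------------------

def _bond_graph(system) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.serial for a in system.atoms)
    g.add_edges_from(system.bonds)
    return g


def identify_torsions(system, mobile_side_chains="none") -> list[TorsionSpec]:
    """Enumerate phi/psi/omega per residue and chi1..chi4 from the bundled
    chi-quad table.

    omega specs are always locked (peptide-bond planarity); chi specs are
    locked unless the residue index is selected via ``mobile_side_chains``
    ("all", "none", or a set of 0-based residue indices — pass a receptor
    system with selected residues for receptor side-chain mobility).  Any
    torsion whose axis lies in a ring (e.g. proline chi) is locked: cutting
    it could not disconnect the graph.  Missing quad atoms suppress a spec
    with a log line.
    """
    templates = residue_templates()
    graph = _bond_graph(system)
    bridges = {tuple(sorted(e)) for e in nx.bridges(graph)} if graph.number_of_edges() else set()

    if mobile_side_chains == "all":
        mobile = {r.index for r in system.residues}
    elif mobile_side_chains in ("none", None):
        mobile = set()
    else:
        mobile = set(mobile_side_chains)

    def serial(ridx: int, name: str):
        atom = system.atom(ridx, name) if 0 <= ridx < len(system.residues) else None
        return atom.serial if atom is not None else None

    specs: list[TorsionSpec] = []

    def emit(kind: str, ridx: int, quad_serials, locked: bool):
        if any(s is None for s in quad_serials):
            log.debug("skipping %s for residue %d: incomplete quad", kind, ridx)
            return
        quad = tuple(int(s) for s in quad_serials)
        axis = tuple(sorted(quad[1:3]))
        if axis not in bridges:
            locked = True  # ring bond: never rotatable
        specs.append(TorsionSpec(id=f"{kind}_{ridx + 1}", kind=kind,
                                 residue_index=ridx, atom_quad=quad, locked=locked))

    for res in system.residues:
        i = res.index
        emit("phi", i, (serial(i - 1, "C"), serial(i, "N"),
                        serial(i, "CA"), serial(i, "C")), locked=False)
        emit("psi", i, (serial(i, "N"), serial(i, "CA"),
                        serial(i, "C"), serial(i + 1, "N")), locked=False)
        emit("omega", i, (serial(i - 1, "CA"), serial(i - 1, "C"),
                          serial(i, "N"), serial(i, "CA")), locked=True)
        tpl = templates.get(res.name)
        if tpl is None:
            continue
        chi_locked = set(tpl.get("chi_locked", ()))
        for chi_name in sorted(tpl["chi"]):
            quad_names = tpl["chi"][chi_name]
            locked = chi_name in chi_locked or i not in mobile
            emit(chi_name, i, tuple(serial(i, n) for n in quad_names), locked=locked)
    return specs


def custom_torsion(system, atom_quad, torsion_id: str,
                   range_deg=(-180.0, 180.0)) -> TorsionSpec:
    """A user-defined rotatable dihedral given four bonded atom serials."""
    quad = tuple(int(s) for s in atom_quad)
    bonds = system.bonds
    for a, b in zip(quad, quad[1:]):
        if tuple(sorted((a, b))) not in bonds:
            raise FragmentationError(f"custom torsion atoms {a}-{b} are not bonded")
    ridx = system.atom_by_serial[quad[1]].residue_index
    return TorsionSpec(id=torsion_id, kind="custom", residue_index=ridx,
                       atom_quad=quad, locked=False, range=tuple(range_deg))


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fine_fragment(system, torsions) -> FragmentGraph:
    """Cut every unlocked torsion's axis bond; connected components become
    rigid fragments, each removed bond a revolute joint."""
    return _fragment(system, torsions, [t.id for t in torsions if not t.locked])


def coarse_fragment(system, torsions, keep) -> FragmentGraph:
    """Cut only the torsions named in ``keep`` (subset of the unlocked ids)."""
    known = {t.id: t for t in torsions}
    keep = list(keep)
    for tid in keep:
        if tid not in known:
            raise FragmentationError(f"unknown torsion id {tid!r}")
        if known[tid].locked:
            raise FragmentationError(f"torsion {tid!r} is locked")
    return _fragment(system, torsions, keep)


def _fragment(system, torsions, cut_ids) -> FragmentGraph:
    graph = _bond_graph(system)
    cut_ids = set(cut_ids)
    cut_specs = [t for t in torsions if t.id in cut_ids]
    bridges = {tuple(sorted(e)) for e in nx.bridges(graph)}
    for spec in cut_specs:
        if spec.axis_bond not in bridges:
            raise FragmentationError(
                f"axis bond of {spec.id!r} lies in a ring; cutting it would "
                "not disconnect the graph")
    work = graph.copy()
    work.remove_edges_from(spec.axis_bond for spec in cut_specs)
    components = sorted(nx.connected_components(work), key=min)
    lookup = system.atom_by_serial
    fragments = []
    for k, comp in enumerate(components, start=1):
        names = {lookup[s].name for s in comp}
        role = "main_chain" if names & BACKBONE_ATOMS else "side_chain"
        fragments.append(RigidFragment(id=f"F{k}", atom_serials=frozenset(comp),
                                       role=role))
    member = {}
    for frag in fragments:
        for s in frag.atom_serials:
            member[s] = frag.id
    joints = {}
    for spec in cut_specs:
        b, c = spec.atom_quad[1], spec.atom_quad[2]
        if member[b] == member[c]:
            raise FragmentationError(f"cut of {spec.id!r} failed to separate its axis")
        joints[spec.id] = (spec, member[b], member[c])
    fg = FragmentGraph(system=system, fragments=fragments, joints=joints)
    return assign_ports(fg)


def assign_ports(graph: FragmentGraph) -> FragmentGraph:
    """Attach one male and one female port per joint.

    Convention: the fragment containing the N-proximal axis atom (the second
    atom of the torsion quad — for chi joints the CA-proximal side) carries
    the male port; the axis direction points from the male anchor to the
    female anchor.  Key index is assigned per joint kind so that, e.g.,
    phi-type pins never fit psi-type holes.
    """
    frag_by_id = {f.id: f for f in graph.fragments}
    for frag in graph.fragments:
        frag.ports = []
    positions = {a.serial: a.position for a in graph.system.atoms}
    for joint_id in sorted(graph.joints):
        spec, male_id, female_id = graph.joints[joint_id]
        b, c = spec.atom_quad[1], spec.atom_quad[2]
        axis = positions[c] - positions[b]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise FragmentationError(f"zero-length joint axis for {joint_id!r}")
        axis = axis / norm
        if b not in frag_by_id[male_id].atom_serials:
            raise FragmentationError(f"joint {joint_id!r}: axis atoms not split "
                                     "between its fragments")
        frag_by_id[male_id].ports.append(Port("male", joint_id, b, axis, spec.key_class))
        frag_by_id[female_id].ports.append(Port("female", joint_id, c, axis, spec.key_class))
    return graph
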