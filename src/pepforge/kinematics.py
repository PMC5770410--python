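"""Torsion measurement and Cartesian reconstruction from conformation states.

A conformation is a flat map ``torsion id -> degrees``.  Reconstruction
holds one anchor fragment fixed and rotates each downstream rigid-fragment
subtree about its joint axis (breadth-first from the anchor, deterministic
tie-break by joint id), so every fragment moves rigidly and bond geometry is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConformationError, GeometryError
from .geometry import dihedral, normalize_angle, rotation_about_axis

measure_torsion = dihedral  # four positions -> signed degrees in (-180, 180]


@dataclass
class ConformationState:
    """Angles (degrees, (-180, 180]) for the unlocked torsions of a graph."""
    angles: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.angles[key]

    def __contains__(self, key: str) -> bool:
        return key in self.angles

    def items(self):
        return self.angles.items()


@dataclass
class RigidTransform:
    rotation: np.ndarray   # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("rotation matrix determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def transform_system(system, transform: RigidTransform) -> np.ndarray:
    """Return new coordinates for every atom under a rigid transform."""
    return transform.apply(system.coords())


def extract_conformation(system, torsions, coords: np.ndarray | None = None) -> ConformationState:
    """Measure the current angle of every unlocked torsion."""
    coords = system.coords() if coords is None else np.asarray(coords, float)
    idx = system.serial_index()
    angles = {}
    for spec in torsions:
        if spec.locked:
            continue
        a, b, c, d = (coords[idx[s]] for s in spec.atom_quad)
        angles[spec.id] = measure_torsion(a, b, c, d)
    return ConformationState(angles)


def apply_conformation(system, graph, state: ConformationState,
                       anchor_fragment: str | None = None,
                       coords: np.ndarray | None = None) -> np.ndarray:
    """Rebuild Cartesian coordinates so each unlocked torsion matches ``state``.

    The anchor fragment (default: the fragment containing the lowest atom
    serial, i.e. the N-terminal piece) keeps its coordinates; joints are
    processed breadth-first outward from it and each joint rotates the whole
    downstream subtree rigidly about the current joint axis.  Locked joints
    keep their native angles automatically (rigid motion preserves internal
    dihedrals of the moved subtree).
    """
    state = state if isinstance(state, ConformationState) else ConformationState(dict(state))
    coords = system.coords().copy() if coords is None else np.asarray(coords, float).copy()
    idx = system.serial_index()

    frag_by_id = {f.id: f for f in graph.fragments}
    if anchor_fragment is None:
        anchor_fragment = min(graph.fragments, key=lambda f: min(f.atom_serials)).id
    if anchor_fragment not in frag_by_id:
        raise ConformationError(f"anchor fragment {anchor_fragment!r} not in graph")

    for joint_id, (spec, _male, _female) in graph.joints.items():
        if not spec.locked and joint_id not in state:
            raise ConformationError(f"no angle supplied for unlocked joint {joint_id!r}")

    # fragment adjacency: joint connects the two fragments holding its axis
    adjacency: dict[str, list[tuple[str, str]]] = {f.id: [] for f in graph.fragments}
    for joint_id, (spec, male_id, female_id) in graph.joints.items():
        adjacency[male_id].append((joint_id, female_id))
        adjacency[female_id].append((joint_id, male_id))

    visited = {anchor_fragment}
    order: list[tuple[str, str, str]] = []  # (joint_id, upstream frag, downstream frag)
    children: dict[str, list[str]] = {f.id: [] for f in graph.fragments}
    queue = [anchor_fragment]
    while queue:
        current = queue.pop(0)
        for joint_id, other in sorted(adjacency[current]):
            if other in visited:
                continue
            visited.add(other)
            children[current].append(other)
            order.append((joint_id, current, other))
            queue.append(other)

    def subtree_atoms(root: str) -> list[int]:
        serials: list[int] = []
        stack = [root]
        while stack:
            fid = stack.pop()
            serials.extend(frag_by_id[fid].atom_serials)
            stack.extend(children[fid])
        return [idx[s] for s in serials]

    for joint_id, upstream, downstream in order:
        spec, _male, _female = graph.joints[joint_id]
        if spec.locked:
            continue
        target = normalize_angle(state[joint_id])
        lo, hi = spec.range
        if not (lo < target <= hi or np.isclose(target, lo) or np.isclose(target, hi)):
            raise ConformationError(
                f"angle {target:.2f} for {joint_id!r} outside range ({lo}, {hi}]")
        a, b, c, d = (coords[idx[s]] for s in spec.atom_quad)
        current = measure_torsion(a, b, c, d)
        delta = normalize_angle(target - current)
        if abs(delta) < 1e-12:
            continue
        # the downstream fragment holds the far axis atom; rotating it about
        # b->c by +delta increases the measured dihedral by delta when the
        # d side is downstream, and decreases it otherwise
        b_pos, c_pos = coords[idx[spec.atom_quad[1]]], coords[idx[spec.atom_quad[2]]]
        d_serial = spec.atom_quad[3]
        d_downstream = d_serial in frag_by_id[downstream].atom_serials or any(
            d_serial in frag_by_id[f].atom_serials for f in _descendants(children, downstream))
        sign = 1.0 if d_downstream else -1.0
        R, t = rotation_about_axis(b_pos, c_pos - b_pos, sign * delta)
        rows = subtree_atoms(downstream)
        coords[rows] = coords[rows] @ R.T + t
    return coords


def _descendants(children: dict[str, list[str]], root: str) -> list[str]:
    out = []
    stack = list(children[root])
    while stack:
        fid = stack.pop()
        out.append(fid)
        stack.extend(children[fid])
    return out
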