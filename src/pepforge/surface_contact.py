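"""Discrete dot-surface contact scoring against a carved mold template.

The receptor surrogate ("semi-perfect template") is a rectangular box minus
every ligand atom sphere and its upward sweep — the shape a mold has after
the ligand is pressed in from above and withdrawn straight up.  Contact area
is counted discretely: approximately equidistant surface marks are placed on
each atom sphere (Fibonacci spiral lattice) and a mark scores when it lies
within a paint-film tolerance of the mold material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError
from .kinematics import apply_conformation

DEFAULT_TOLERANCE = 0.5  # Angstrom, stand-in for the paint film thickness


# ---------------------------------------------------------------------------
# Surface marks
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMarkSet:
    """Per-atom points on (scaled) atom spheres, buried marks pruned."""
    marks: dict[int, np.ndarray]      # atom serial -> (k, 3) model-space A
    density: float                    # marks per square Angstrom target
    radius_scale: float = 1.0

    def all_points(self) -> np.ndarray:
        arrays = [m for m in self.marks.values() if len(m)]
        return np.vstack(arrays) if arrays else np.empty((0, 3))

    def total(self) -> int:
        return sum(len(m) for m in self.marks.values())


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors (golden-spiral lattice)."""
    if n <= 0:
        return np.empty((0, 3))
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_surface_marks(system, density: float = 1.0,
                           coordinates: np.ndarray | None = None,
                           radius_scale: float = 1.0) -> SurfaceMarkSet:
    """Deterministic spiral-lattice marks, count = round(density * 4*pi*R^2)
    per atom; marks strictly inside another atom's sphere are pruned."""
    if density <= 0:
        raise ValueError("mark density must be positive")
    coords = system.coords() if coordinates is None else np.asarray(coordinates, float)
    radii = radius_scale * np.array([a.vdw_radius for a in system.atoms])
    marks: dict[int, np.ndarray] = {}
    for i, atom in enumerate(system.atoms):
        r = radii[i]
        count = max(1, int(round(density * 4.0 * np.pi * r * r)))
        pts = coords[i] + r * fibonacci_sphere(count)
        keep = np.ones(len(pts), dtype=bool)
        for j in range(len(system.atoms)):
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            keep &= d >= radii[j] - 1e-9
        marks[atom.serial] = pts[keep]
    return SurfaceMarkSet(marks=marks, density=density, radius_scale=radius_scale)


# ---------------------------------------------------------------------------
# Semi-perfect template
# ---------------------------------------------------------------------------

@dataclass
class TemplateSolid:
    """Implicit CSG mold: axis-aligned box minus carve spheres minus their
    upward sweep cylinders.  Stored in a frame whose +z is the pull
    direction; ``frame`` rotates molecule space into that frame."""
    box_min: np.ndarray
    box_max: np.ndarray
    centers: np.ndarray          # (n, 3) in mold frame
    radii: np.ndarray            # (n,) scaled radii
    radius_scale: float
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, float)) @ self.frame.T


def _frame_to_z(up_axis) -> np.ndarray:
    u = np.asarray(up_axis, float)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise GeometryError("up_axis must be a nonzero vector")
    u = u / nu
    if np.allclose(u, [0, 0, 1]):
        return np.eye(3)
    if np.allclose(u, [0, 0, -1]):
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(u, [0.0, 0.0, 1.0])
    s = np.linalg.norm(v)
    c = float(np.dot(u, [0, 0, 1]))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def make_template(system, up_axis=(0.0, 0.0, 1.0),
                  radius_scale: float = 0.7,
                  coordinates: np.ndarray | None = None) -> TemplateSolid:
    """Build the mold: box footprint = bounding box of atom centers in the
    two axes perpendicular to the pull direction, padded by the largest
    scaled radius; box height = the lower half of the centers' extent along
    the pull axis.  Carves = every atom sphere at scaled radius plus its
    sweep toward +up_axis (to the box top)."""
    if len(system.atoms) < 2:
        raise GeometryError("template needs at least 2 atoms")
    coords = system.coords() if coordinates is None else np.asarray(coordinates, float)
    R = _frame_to_z(up_axis)
    local = coords @ R.T
    radii = radius_scale * np.array([a.vdw_radius for a in system.atoms])
    lo = local.min(axis=0)
    hi = local.max(axis=0)
    if hi[2] - lo[2] < 1e-9:
        raise GeometryError("degenerate bounding box: no extent along up_axis")
    pad = float(radii.max())
    box_min = np.array([lo[0] - pad, lo[1] - pad, lo[2]])
    box_max = np.array([hi[0] + pad, hi[1] + pad, lo[2] + 0.5 * (hi[2] - lo[2])])
    return TemplateSolid(box_min=box_min, box_max=box_max, centers=local,
                         radii=radii, radius_scale=radius_scale, frame=R)


#: boundary shell half-width — points within this of a surface are "touching",
#: neither material nor void interior
_SURF_EPS = 1e-6
_PROBE = 1e-4


def points_in_material(solid: TemplateSolid, points: np.ndarray) -> np.ndarray:
    """Vectorized CSG membership: strictly inside the box, strictly outside
    every carve sphere and outside every upward sweep cylinder.  Points
    exactly on a surface (within 1e-6 A) are classified as void so a mark
    resting on the mold counts as touching, not colliding."""
    p = solid.to_frame(points)
    inside = np.all((p > solid.box_min + _SURF_EPS)
                    & (p < solid.box_max - _SURF_EPS), axis=1)
    for c, r in zip(solid.centers, solid.radii):
        d = np.linalg.norm(p - c, axis=1)
        inside &= d > r + _SURF_EPS
        radial = np.linalg.norm(p[:, :2] - c[:2], axis=1)
        swept = (radial < r + _SURF_EPS) & (p[:, 2] > c[2])
        inside &= ~swept
    return inside


def point_in_material(solid: TemplateSolid, point) -> bool:
    return bool(points_in_material(solid, np.asarray(point, float))[0])


def _in_material_frame(solid: TemplateSolid, p: np.ndarray) -> np.ndarray:
    """Membership for points already expressed in the mold frame."""
    inside = np.all((p > solid.box_min + _SURF_EPS)
                    & (p < solid.box_max - _SURF_EPS), axis=1)
    for c, r in zip(solid.centers, solid.radii):
        d = np.linalg.norm(p - c, axis=1)
        inside &= d > r + _SURF_EPS
        radial = np.linalg.norm(p[:, :2] - c[:2], axis=1)
        inside &= ~((radial < r + _SURF_EPS) & (p[:, 2] > c[2]))
    return inside


def distances_to_material(solid: TemplateSolid, points) -> np.ndarray:
    """Distance from each point to the mold material (0 when inside it).

    Evaluated analytically against box faces, carve sphere surfaces and
    sweep cylinder walls; each candidate surface is validated by probing
    slightly past it and re-testing membership, so surfaces whose far side
    is also carved are rejected."""
    p = solid.to_frame(points)
    m = len(p)
    if m == 0:
        return np.empty(0)
    n = len(solid.radii)
    faces = [(axis, v) for axis in range(3)
             for v in (solid.box_min[axis] + _PROBE, solid.box_max[axis] - _PROBE)]
    n_cand = 1 + 2 * n + len(faces) * n + n
    dists = np.full((m, n_cand), np.inf)
    probes = np.zeros((m, n_cand, 3))
    inner_lo = solid.box_min + _PROBE
    inner_hi = solid.box_max - _PROBE
    q = np.clip(p, solid.box_min, solid.box_max)
    dists[:, 0] = np.linalg.norm(p - q, axis=1)
    probes[:, 0] = np.clip(p, inner_lo, inner_hi)
    col = 1 + 2 * n
    for fi, (axis, v) in enumerate(faces):
        # where a carve sphere pierces this box face, the material boundary
        # on the face is the rim circle sphere-cap; push the in-plane foot
        # point just outside that circle
        q_face = np.clip(p, inner_lo, inner_hi)
        q_face[:, axis] = v
        other = [a for a in range(3) if a != axis]
        for k, (c, r) in enumerate(zip(solid.centers, solid.radii)):
            h = abs(v - c[axis])
            if h >= r:
                continue
            rf = np.sqrt(r * r - h * h)
            delta = q_face[:, other] - c[other]
            dn = np.linalg.norm(delta, axis=1)
            dirs = delta / np.where(dn > 1e-12, dn, 1.0)[:, None]
            dirs[dn <= 1e-12] = np.array([1.0, 0.0])
            cand = q_face.copy()
            cand[:, other] = c[other] + dirs * (rf + _PROBE)
            cand = np.clip(cand, inner_lo, inner_hi)
            dists[:, col + fi * n + k] = np.linalg.norm(p - cand, axis=1)
            probes[:, col + fi * n + k] = cand
    col = 1 + 2 * n + len(faces) * n
    top = inner_hi[2]
    for k, (c, r) in enumerate(zip(solid.centers, solid.radii)):
        # sweep cylinder rim on the box top face
        delta = np.clip(p, inner_lo, inner_hi)[:, :2] - c[:2]
        dn = np.linalg.norm(delta, axis=1)
        dirs = delta / np.where(dn > 1e-12, dn, 1.0)[:, None]
        dirs[dn <= 1e-12] = np.array([1.0, 0.0])
        cand = np.empty((m, 3))
        cand[:, :2] = c[:2] + dirs * (r + _PROBE)
        cand[:, 2] = top
        cand = np.clip(cand, inner_lo, inner_hi)
        dists[:, col + k] = np.linalg.norm(p - cand, axis=1)
        probes[:, col + k] = cand
    for k, (c, r) in enumerate(zip(solid.centers, solid.radii)):
        delta = p - c
        d = np.linalg.norm(delta, axis=1)
        safe = d > 1e-12
        dists[safe, 1 + k] = np.abs(d[safe] - r)
        probes[:, 1 + k] = c + delta * ((r + _PROBE) / np.where(safe, d, 1.0))[:, None]
        radial = np.linalg.norm(delta[:, :2], axis=1)
        use = (p[:, 2] > c[2]) & (radial > 1e-12)
        dists[use, 1 + n + k] = np.abs(radial[use] - r)
        probes[:, 1 + n + k] = p
        push = c[:2] + delta[:, :2] * ((r + _PROBE) / np.where(use, radial, 1.0))[:, None]
        probes[use, 1 + n + k, :2] = push[use]
    valid = _in_material_frame(solid, probes.reshape(-1, 3)).reshape(m, n_cand)
    dists[~valid] = np.inf
    out = dists.min(axis=1)
    out[_in_material_frame(solid, p)] = 0.0
    return out


def distance_to_material(solid: TemplateSolid, point) -> float:
    return float(distances_to_material(solid, np.asarray(point, float))[0])


# ---------------------------------------------------------------------------
# Contact counting
# ---------------------------------------------------------------------------

@dataclass
class ContactResult:
    count: int
    per_atom: dict[int, int]
    collision: bool


def contact_count(marks: SurfaceMarkSet, solid: TemplateSolid,
                  tolerance: float = DEFAULT_TOLERANCE,
                  atom_centers: np.ndarray | None = None) -> ContactResult:
    """Count marks touching the mold: a mark scores iff it is not inside
    material and its distance to material is <= tolerance.  The collision
    flag reports marks (or atom centers, when given) embedded in material."""
    per_atom: dict[int, int] = {}
    collision = False
    serials = [s for s, pts in marks.marks.items() if len(pts)]
    per_atom.update({s: 0 for s in marks.marks if s not in serials})
    if serials:
        pts = np.vstack([marks.marks[s] for s in serials])
        sizes = [len(marks.marks[s]) for s in serials]
        inmat = points_in_material(solid, pts)
        collision = bool(np.any(inmat))
        touching = ~inmat & (distances_to_material(solid, pts) <= tolerance)
        offset = 0
        for s, k in zip(serials, sizes):
            per_atom[s] = int(np.sum(touching[offset:offset + k]))
            offset += k
    if atom_centers is not None and len(atom_centers):
        collision = collision or bool(np.any(points_in_material(solid, atom_centers)))
    return ContactResult(count=sum(per_atom.values()), per_atom=per_atom,
                         collision=collision)


def match_profile(system, graph, template: TemplateSolid, conformations,
                  anchor_fragment: str | None = None,
                  density: float = 1.0,
                  tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Contact counts for a list of (state id, conformation) pairs.

    Pose rule: the anchor fragment keeps its native pose (the default of
    :func:`apply_conformation`), emulating holding one piece fixed in the
    mold while the others pivot.  Colliding poses are flagged but still
    counted.
    """
    rows = []
    for state_id, state in conformations:
        coords = apply_conformation(system, graph, state,
                                    anchor_fragment=anchor_fragment)
        marks = generate_surface_marks(system, density, coordinates=coords,
                                       radius_scale=template.radius_scale)
        centers = coords
        res = contact_count(marks, template, tolerance, atom_centers=centers)
        rows.append({"state": state_id, "contacts": res.count,
                     "collision": res.collision})
    return pd.DataFrame(rows)
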