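"""Low-level vector geometry: dihedrals, internal-coordinate placement.

Angles are degrees throughout, normalized to (-180, 180] with the IUPAC
sign convention (cis = 0, right-handed positive looking from b to c).
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

_COLLINEAR_EPS = 1e-8


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -np.remainder(-a + 180.0, 360.0) + 180.0
    return float(out) if np.isscalar(angle) or out.ndim == 0 else out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, atan2 formulation."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < _COLLINEAR_EPS:
        raise GeometryError("dihedral axis has zero length")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _COLLINEAR_EPS or np.linalg.norm(w) < _COLLINEAR_EPS:
        raise GeometryError("three consecutive dihedral points are collinear")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(p_bond, p_angle, p_torsion, length: float, angle: float,
               torsion: float) -> np.ndarray:
    """Place a new atom D from internal coordinates (NeRF construction).

    The new point is at distance ``length`` from ``p_bond``, forming the
    given bond ``angle`` D-p_bond-p_angle and dihedral D-p_bond-p_angle-
    p_torsion equal to ``torsion``.
    """
    a = np.asarray(p_torsion, float)
    b = np.asarray(p_angle, float)
    c = np.asarray(p_bond, float)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _COLLINEAR_EPS:
        raise GeometryError("coincident reference points in place_atom")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_EPS:
        raise GeometryError("collinear reference points in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(origin, direction, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation by ``angle_deg`` about the axis through ``origin`` along
    ``direction`` (right-hand rule).  Returns (R, t) with x' = R @ x + t."""
    from scipy.spatial.transform import Rotation

    origin = np.asarray(origin, float)
    u = np.asarray(direction, float)
    nu = np.linalg.norm(u)
    if nu < _COLLINEAR_EPS:
        raise GeometryError("rotation axis has zero length")
    u = u / nu
    R = Rotation.from_rotvec(np.radians(angle_deg) * u).as_matrix()
    t = origin - R @ origin
    return R, t
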