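"""Nonbonded energetics: Lennard-Jones + Coulomb, steric feasibility, and
two-torsion grid scans.

Only nonbonded terms are evaluated — fragments are rigid by construction, so
bonded stretch/bend terms are constant along every degree of freedom this
package exposes.  The exclusion policy is the conventional one for
Amber-style force fields: 1-2 and 1-3 pairs excluded, 1-4 pairs divided by
2.0 (LJ) and 1.2 (Coulomb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._tables import COULOMB_CONSTANT, lj_params
from .errors import PepforgeError
from .geometry import normalize_angle
from .kinematics import apply_conformation, extract_conformation

DEFAULT_RADIUS_SCALE = 0.7  # expands the physically reachable conformation space


@dataclass
class EnergyModel:
    coulomb_constant: float = COULOMB_CONSTANT  # kcal*A/(mol*e^2)
    dielectric: float = 1.0
    scale14_lj: float = 2.0     # divisors applied to 1-4 pairs
    scale14_coul: float = 1.2
    min_separation: int = 3     # pairs closer than this many bonds are excluded

    def __post_init__(self):
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass
class EnergyBreakdown:
    lj: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.lj + self.coulomb


@dataclass
class GridScanResult:
    """Energies/feasibility over a (delta_a, delta_b) torsion mesh; offsets
    are deviations from the native angles, native cell at (0, 0)."""
    torsion_a: str
    torsion_b: str
    axis_a: np.ndarray
    axis_b: np.ndarray
    energy: np.ndarray           # kcal/mol, rows follow axis_a
    coulomb: np.ndarray
    feasible: np.ndarray         # boolean
    radius_scale: float
    native_angles: tuple[float, float] = (0.0, 0.0)

    def native_cell(self) -> tuple[int, int]:
        return (int(np.argmin(np.abs(self.axis_a))),
                int(np.argmin(np.abs(self.axis_b))))

    def energy_frame(self, term: str = "total") -> pd.DataFrame:
        data = {"total": self.energy, "coulomb": self.coulomb,
                "feasible": self.feasible.astype(int)}[term]
        return pd.DataFrame(data, index=pd.Index(self.axis_a, name=f"d_{self.torsion_a}"),
                            columns=pd.Index(self.axis_b, name=f"d_{self.torsion_b}"))


# ---------------------------------------------------------------------------

def _graph_separations(system, cutoff: int) -> dict[tuple[int, int], int]:
    g = nx.Graph()
    g.add_nodes_from(a.serial for a in system.atoms)
    g.add_edges_from(system.bonds)
    sep = {}
    for src, dists in nx.all_pairs_shortest_path_length(g, cutoff=cutoff):
        for dst, d in dists.items():
            if src < dst:
                sep[(src, dst)] = d
    return sep


def nonbonded_pairs(system, model: EnergyModel | None = None):
    """All atom pairs at bonded separation >= ``min_separation``; pairs at
    exactly 3 bonds are flagged as 1-4.  Returns (pairs, is14) as arrays of
    atom-array indices."""
    model = model or EnergyModel()
    sep = _graph_separations(system, cutoff=model.min_separation)
    idx = system.serial_index()
    serials = [a.serial for a in system.atoms]
    pairs, is14 = [], []
    n = len(serials)
    for i in range(n):
        for j in range(i + 1, n):
            key = (min(serials[i], serials[j]), max(serials[i], serials[j]))
            d = sep.get(key)
            if d is not None and d < model.min_separation:
                continue
            pairs.append((idx[serials[i]], idx[serials[j]]))
            is14.append(d == 3)
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(is14, dtype=bool)


def total_energy(system, coordinates: np.ndarray | None = None,
                 model: EnergyModel | None = None,
                 pairs=None) -> EnergyBreakdown:
    """Nonbonded energy in kcal/mol with separate LJ and Coulomb terms.

    LJ uses the rmin/epsilon form E = eps*((rmin/r)^12 - 2*(rmin/r)^6) with
    pairwise rmin the sum of the per-atom rmin/2 values and eps the geometric
    mean; Coulomb is k*qi*qj/(D*r).  Coincident atoms report +inf.
    """
    model = model or EnergyModel()
    coords = system.coords() if coordinates is None else np.asarray(coordinates, float)
    pair_idx, is14 = nonbonded_pairs(system, model) if pairs is None else pairs
    if len(pair_idx) == 0:
        return EnergyBreakdown(0.0, 0.0)
    rmin_half = np.empty(len(system.atoms))
    eps = np.empty(len(system.atoms))
    q = np.empty(len(system.atoms))
    for i, a in enumerate(system.atoms):
        rmin_half[i], eps[i] = lj_params(a.element)
        q[i] = a.partial_charge
    i, j = pair_idx[:, 0], pair_idx[:, 1]
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    if np.any(r == 0.0):
        return EnergyBreakdown(float("inf"), float("inf"))
    rmin = rmin_half[i] + rmin_half[j]
    eps_ij = np.sqrt(eps[i] * eps[j])
    x6 = (rmin / r) ** 6
    lj = eps_ij * (x6 * x6 - 2.0 * x6)
    coul = model.coulomb_constant * q[i] * q[j] / (model.dielectric * r)
    lj_scale = np.where(is14, 1.0 / model.scale14_lj, 1.0)
    coul_scale = np.where(is14, 1.0 / model.scale14_coul, 1.0)
    return EnergyBreakdown(float(np.sum(lj * lj_scale)),
                           float(np.sum(coul * coul_scale)))


def feasible(system, coordinates: np.ndarray | None = None,
             radius_scale: float = DEFAULT_RADIUS_SCALE,
             model: EnergyModel | None = None,
             pairs=None):
    """Hard-sphere test at scaled van der Waals radii.

    Infeasible iff any non-excluded pair is closer than radius_scale *
    (R_i + R_j).  Returns (ok, offending) where offending lists serial pairs.
    """
    coords = system.coords() if coordinates is None else np.asarray(coordinates, float)
    pair_idx, _ = nonbonded_pairs(system, model) if pairs is None else pairs
    if len(pair_idx) == 0:
        return True, []
    radii = np.array([a.vdw_radius for a in system.atoms])
    serials = np.array([a.serial for a in system.atoms])
    i, j = pair_idx[:, 0], pair_idx[:, 1]
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    limit = radius_scale * (radii[i] + radii[j])
    bad = r < limit
    offending = [(int(serials[a]), int(serials[b]))
                 for a, b in pair_idx[bad]]
    return not bool(np.any(bad)), offending


def grid_scan(system, graph, torsion_a: str, torsion_b: str,
              increment: float = 20.0,
              model: EnergyModel | None = None,
              radius_scale: float = DEFAULT_RADIUS_SCALE,
              anchor_fragment: str | None = None) -> GridScanResult:
    """Scan two torsions over the full circle at a fixed increment.

    At 20 degrees this is the 18 x 18 mesh (324 conformers).  Axis values
    are offsets from the native angles; the native cell is (0, 0).
    """
    model = model or EnergyModel()
    if abs(360.0 / increment - round(360.0 / increment)) > 1e-9:
        raise PepforgeError("increment must divide 360")
    n = int(round(360.0 / increment))
    offsets = np.array(sorted(normalize_angle(k * increment) for k in range(n)))

    specs = {spec.id: spec for spec, _, _ in graph.joints.values()}
    for tid in (torsion_a, torsion_b):
        if tid not in specs:
            raise PepforgeError(f"torsion {tid!r} is not a joint of the graph")
        if specs[tid].locked:
            raise PepforgeError(f"torsion {tid!r} is locked")

    all_specs = [spec for spec, _, _ in graph.joints.values()]
    native = extract_conformation(system, all_specs)
    pairs = nonbonded_pairs(system, model)

    energy = np.empty((n, n))
    coulomb = np.empty((n, n))
    ok = np.empty((n, n), dtype=bool)
    for ia, da in enumerate(offsets):
        for ib, db in enumerate(offsets):
            angles = dict(native.angles)
            angles[torsion_a] = normalize_angle(native[torsion_a] + da)
            angles[torsion_b] = normalize_angle(native[torsion_b] + db)
            coords = apply_conformation(system, graph, angles,
                                        anchor_fragment=anchor_fragment)
            e = total_energy(system, coords, model, pairs=pairs)
            energy[ia, ib] = e.total
            coulomb[ia, ib] = e.coulomb
            ok[ia, ib], _ = feasible(system, coords, radius_scale, model, pairs=pairs)
    return GridScanResult(torsion_a=torsion_a, torsion_b=torsion_b,
                          axis_a=offsets, axis_b=offsets,
                          energy=energy, coulomb=coulomb, feasible=ok,
                          radius_scale=radius_scale,
                          native_angles=(native[torsion_a], native[torsion_b]))
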