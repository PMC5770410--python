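"""energetics: pair lists, LJ/Coulomb identities, feasibility, grid scans."""

import numpy as np
import pytest

from pepforge import (EnergyModel, PepforgeError, RigidTransform,
                      apply_conformation, build_ideal_peptide,
                      extract_conformation, feasible, fine_fragment,
                      grid_scan, identify_torsions, nonbonded_pairs,
                      total_energy, transform_system)
from pepforge._tables import lj_params
from pepforge.fixtures import glu_lys_three_piece, random_state
from pepforge.structure_io import Atom, MolecularSystem, Residue
from conftest import random_peptide


def toy_system(positions, charges=None, bonds=(), element="C"):
    charges = charges or [0.0] * len(positions)
    atoms = [Atom(i + 1, f"X{i+1}", element, np.asarray(p, float), 1.7, q)
             for i, (p, q) in enumerate(zip(positions, charges))]
    res = Residue(0, "LIG", [a.serial for a in atoms])
    return MolecularSystem(atoms, [res], set(bonds))


def bfs_separation(serials, bonds):
    adj = {s: set() for s in serials}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    def dist(src, dst):
        frontier, d, seen = {src}, 0, {src}
        while frontier:
            if dst in frontier:
                return d
            frontier = {y for x in frontier for y in adj[x]} - seen
            seen |= frontier
            d += 1
        return None
    return dist


class TestPairList:
    def test_diatomic_has_no_pairs(self):
        system = toy_system([(0, 0, 0), (1.5, 0, 0)], bonds={(1, 2)})
        pairs, _ = nonbonded_pairs(system)
        assert len(pairs) == 0

    def test_linear_four_chain_single_14_pair(self):
        system = toy_system([(0, 0, 0), (1.5, 0, 0), (3, 0, 0), (4.5, 0, 0)],
                            bonds={(1, 2), (2, 3), (3, 4)})
        pairs, is14 = nonbonded_pairs(system)
        assert len(pairs) == 1
        assert is14.tolist() == [True]

    def test_dipeptide_matches_graph_distance_oracle(self):
        system = build_ideal_peptide("AA")
        pairs, is14 = nonbonded_pairs(system)
        serials = [a.serial for a in system.atoms]
        idx = {a.serial: i for i, a in enumerate(system.atoms)}
        dist = bfs_separation(serials, system.bonds)
        expected = set()
        expected14 = set()
        for i, si in enumerate(serials):
            for sj in serials[i + 1:]:
                d = dist(si, sj)
                if d is None or d >= 3:
                    expected.add((idx[si], idx[sj]))
                    if d == 3:
                        expected14.add((idx[si], idx[sj]))
        got = {tuple(sorted(p)) for p in pairs.tolist()}
        got14 = {tuple(sorted(p)) for p, f in zip(pairs.tolist(), is14) if f}
        assert got == expected
        assert got14 == expected14


class TestEnergyIdentities:
    def test_lj_minimum_is_minus_epsilon(self):
        rmin_half, eps = lj_params("C")
        system = toy_system([(0, 0, 0), (2 * rmin_half, 0, 0)])
        e = total_energy(system)
        assert e.lj == pytest.approx(-eps, rel=1e-12)
        assert e.coulomb == 0.0

    def test_unit_charges_at_one_angstrom(self):
        system = toy_system([(0, 0, 0), (1.0, 0, 0)], charges=[1.0, -1.0])
        e = total_energy(system, model=EnergyModel(dielectric=1.0))
        assert e.coulomb == pytest.approx(-332.0636, abs=1e-10)

    def test_lj_decays_at_long_range(self):
        rmin_half, eps = lj_params("C")
        system = toy_system([(0, 0, 0), (20 * rmin_half, 0, 0)])
        assert abs(total_energy(system).lj) < 1e-4 * eps

    def test_coincident_atoms_report_infinite_energy(self):
        system = toy_system([(0, 0, 0), (0, 0, 0)])
        assert np.isinf(total_energy(system).total)

    def test_energy_invariant_under_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation
        system = build_ideal_peptide("GAG")
        e0 = total_energy(system)
        t = RigidTransform(Rotation.random(random_state=3).as_matrix(),
                           rng.normal(size=3) * 10)
        e1 = total_energy(system, transform_system(system, t))
        assert e1.total == pytest.approx(e0.total, abs=1e-9)

    def test_one_four_scaling_applied(self):
        system = toy_system([(0, 0, 0), (1.5, 0, 0), (3, 0, 0), (4.5, 0, 0)],
                            charges=[0.5, 0.0, 0.0, -0.5],
                            bonds={(1, 2), (2, 3), (3, 4)})
        scaled = total_energy(system, model=EnergyModel())
        plain = total_energy(system, model=EnergyModel(scale14_lj=1.0,
                                                       scale14_coul=1.0))
        assert scaled.lj == pytest.approx(plain.lj / 2.0)
        assert scaled.coulomb == pytest.approx(plain.coulomb / 1.2)


class TestFeasibility:
    def test_extended_chain_is_feasible_at_07(self):
        system = build_ideal_peptide("GAGAG")
        ok, offending = feasible(system, radius_scale=0.7)
        assert ok and offending == []

    def test_coincident_pair_reported(self):
        system = toy_system([(0, 0, 0), (0, 0, 0)])
        ok, offending = feasible(system, radius_scale=0.7)
        assert not ok
        assert (1, 2) in offending

    def test_matches_brute_force_oracle_and_monotone(self, rng):
        for _ in range(20):
            system = random_peptide(rng, length=3)
            torsions = identify_torsions(system, mobile_side_chains="all")
            graph = fine_fragment(system, torsions)
            coords = apply_conformation(system, graph, random_state(graph, rng))
            pairs, _ = nonbonded_pairs(system)
            prev_ok = None
            for scale in (1.0, 0.9, 0.7, 0.5):
                ok, offending = feasible(system, coords, radius_scale=scale)
                # O(n^2) oracle over the nonbonded pair list
                radii = np.array([a.vdw_radius for a in system.atoms])
                brute = []
                for i, j in pairs:
                    r = np.linalg.norm(coords[i] - coords[j])
                    if r < scale * (radii[i] + radii[j]):
                        brute.append((system.atoms[i].serial, system.atoms[j].serial))
                assert ok == (not brute)
                assert sorted(offending) == sorted(brute)
                # monotone: feasible at larger scale implies feasible below it
                if prev_ok is True:
                    assert ok
                prev_ok = prev_ok if prev_ok is True else ok

    def test_overlap_at_07_implies_repulsive_lj(self, rng):
        """0.7x summed vdW radii sits inside the LJ repulsive wall for every
        element pair in the table, so each offending pair contributes
        positive LJ energy."""
        hits = 0
        for _ in range(10):
            system = random_peptide(rng, length=3)
            torsions = identify_torsions(system, mobile_side_chains="all")
            graph = fine_fragment(system, torsions)
            coords = apply_conformation(system, graph, random_state(graph, rng))
            _, offending = feasible(system, coords, radius_scale=0.7)
            idx = system.serial_index()
            for si, sj in offending:
                hits += 1
                ai = system.atoms[idx[si]]
                aj = system.atoms[idx[sj]]
                r = np.linalg.norm(coords[idx[si]] - coords[idx[sj]])
                rh_i, e_i = lj_params(ai.element)
                rh_j, e_j = lj_params(aj.element)
                rmin = rh_i + rh_j
                x6 = (rmin / r) ** 6
                assert np.sqrt(e_i * e_j) * (x6 * x6 - 2 * x6) > 0
        assert hits > 0  # random conformers did produce clashes to check


class TestGridScan:
    def test_twenty_degree_mesh_is_18_by_18(self, half_residue_selection):
        system = half_residue_selection
        torsions = identify_torsions(system)
        graph = fine_fragment(system, torsions)
        result = grid_scan(system, graph, "phi_2", "psi_2", increment=20.0)
        assert len(result.axis_a) == 18
        assert len(result.axis_b) == 18
        assert result.energy.size == 324

    def test_coarse_scan_native_cell_feasible(self, gly3):
        system, _, graph = gly3
        result = grid_scan(system, graph, "psi_1", "phi_2", increment=120.0)
        assert result.energy.shape == (3, 3)
        assert result.feasible[result.native_cell()]

    def test_infeasible_cells_have_higher_lj_than_native(self, gly3):
        system, _, graph = gly3
        result = grid_scan(system, graph, "psi_1", "phi_2", increment=60.0)
        lj = result.energy - result.coulomb
        native_lj = lj[result.native_cell()]
        assert np.any(~result.feasible)
        assert np.all(lj[~result.feasible] > native_lj)

    def test_bad_increment_rejected(self, gly3):
        system, _, graph = gly3
        with pytest.raises(PepforgeError):
            grid_scan(system, graph, "psi_1", "phi_2", increment=50.0)

    def test_opposite_charges_attract_across_the_grid(self):
        """The conformer bringing the glutamate carboxylate closest to the
        lysine ammonium has the lowest electrostatic term in the scan."""
        system, _, graph, (t1, t2) = glu_lys_three_piece()
        result = grid_scan(system, graph, t1, t2, increment=30.0)
        specs = [spec for spec, _, _ in graph.joints.values()]
        native = extract_conformation(system, specs)
        idx = system.serial_index()
        neg = [system.atom(0, n).serial for n in ("CD", "OE1", "OE2")]
        pos = system.atom(2, "NZ").serial
        from pepforge.geometry import normalize_angle
        dist = np.zeros_like(result.coulomb)
        for ia, da in enumerate(result.axis_a):
            for ib, db in enumerate(result.axis_b):
                angles = dict(native.angles)
                angles[t1] = normalize_angle(native[t1] + da)
                angles[t2] = normalize_angle(native[t2] + db)
                coords = apply_conformation(system, graph, angles)
                dist[ia, ib] = np.linalg.norm(
                    coords[[idx[s] for s in neg]].mean(axis=0) - coords[idx[pos]])
        closest = np.unravel_index(dist.argmin(), dist.shape)
        assert result.coulomb[closest] == result.coulomb.min()
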