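"""surface_contact: mark lattices, mold CSG, contact counting."""

import numpy as np
import pytest

from pepforge import (GeometryError, apply_conformation, build_ideal_peptide,
                      coarse_fragment, contact_count, extract_conformation,
                      generate_surface_marks, identify_torsions, make_template,
                      match_profile, point_in_material)
from pepforge.geometry import normalize_angle
from pepforge.surface_contact import (distances_to_material, fibonacci_sphere,
                                      points_in_material)
from pepforge.structure_io import Atom, MolecularSystem, Residue


def two_atom_system(separation=3.0, radius=1.5, z_offset=1.0):
    a1 = Atom(1, "X1", "C", np.array([0.0, 0.0, 0.0]), radius)
    a2 = Atom(2, "X2", "C", np.array([separation, 0.0, z_offset]), radius)
    return MolecularSystem([a1, a2], [Residue(0, "LIG", [1, 2])], set())


def voxel_membership_oracle(solid, p):
    """Independent re-statement of the CSG definition."""
    q = solid.to_frame(p)[0]
    if not np.all((q > solid.box_min) & (q < solid.box_max)):
        return False
    for c, r in zip(solid.centers, solid.radii):
        if np.linalg.norm(q - c) < r:
            return False
        if np.linalg.norm(q[:2] - c[:2]) < r and q[2] > c[2]:
            return False
    return True


class TestSurfaceMarks:
    def test_isolated_atom_count_matches_density(self):
        r = 1.6
        system = MolecularSystem([Atom(1, "X", "C", np.zeros(3), r)],
                                 [Residue(0, "LIG", [1])], set())
        for density in (0.5, 1.0, 2.0):
            marks = generate_surface_marks(system, density)
            expected = round(density * 4 * np.pi * r * r)
            assert len(marks.marks[1]) == expected

    def test_density_must_be_positive(self, gly3):
        system, _, _ = gly3
        with pytest.raises(ValueError):
            generate_surface_marks(system, 0.0)

    def test_nearly_coincident_spheres_keep_half_their_marks(self, rng):
        system = two_atom_system(separation=1e-3, z_offset=0.0)
        marks = generate_surface_marks(system, density=4.0)
        total = round(4.0 * 4 * np.pi * 1.5 ** 2)
        for serial in (1, 2):
            frac = len(marks.marks[serial]) / total
            assert abs(frac - 0.5) < 0.05
        # Monte-Carlo oracle for the same geometry
        other = system.atoms[1].position
        pts = system.atoms[0].position + 1.5 * _random_dirs(rng, 20000)
        mc = np.mean(np.linalg.norm(pts - other, axis=1) >= 1.5)
        assert abs(len(marks.marks[1]) / total - mc) < 0.05

    def test_lattice_is_more_even_than_random(self):
        pts = fibonacci_sphere(200)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.25

    def test_marks_lie_on_their_spheres(self, gly3):
        system, _, _ = gly3
        marks = generate_surface_marks(system, 1.0, radius_scale=0.7)
        for atom in system.atoms:
            pts = marks.marks[atom.serial]
            if len(pts) == 0:
                continue
            r = np.linalg.norm(pts - atom.position, axis=1)
            assert np.allclose(r, 0.7 * atom.vdw_radius, atol=1e-9)


def _random_dirs(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestTemplate:
    def test_membership_matches_independent_oracle(self, rng):
        system = two_atom_system()
        solid = make_template(system, radius_scale=0.8)
        lo = solid.box_min - 1.0
        hi = solid.box_max + 1.0
        pts = lo + rng.random((1000, 3)) * (hi - lo)
        ours = points_in_material(solid, pts)
        oracle = np.array([voxel_membership_oracle(solid, p) for p in pts])
        # disagreement only permitted within the 1e-6 boundary band
        disagree = ours != oracle
        assert disagree.mean() < 0.005

    def test_point_outside_box_and_at_carve_center(self):
        system = two_atom_system()
        solid = make_template(system)
        assert not point_in_material(solid, solid.box_max + 10.0)
        assert not point_in_material(solid, system.atoms[0].position)

    def test_native_ligand_fits_its_own_mold(self):
        system = build_ideal_peptide("GAG")
        solid = make_template(system, radius_scale=0.7)
        centers = system.coords()
        assert not np.any(points_in_material(solid, centers))
        marks = generate_surface_marks(system, 1.0, radius_scale=0.7)
        res = contact_count(marks, solid, atom_centers=centers)
        assert not res.collision
        assert res.count > 0

    def test_needs_two_atoms_and_vertical_extent(self):
        single = MolecularSystem([Atom(1, "X", "C", np.zeros(3), 1.5)],
                                 [Residue(0, "LIG", [1])], set())
        with pytest.raises(GeometryError):
            make_template(single)
        flat = two_atom_system(z_offset=0.0)
        with pytest.raises(GeometryError):
            make_template(flat)

    def test_distance_to_material_is_zero_on_the_surface(self):
        system = two_atom_system()
        solid = make_template(system, radius_scale=0.8)
        # a below-center point of the second carve sphere inside the box is
        # genuine material boundary
        c = solid.centers[1]
        r = solid.radii[1]
        surface_point = (c + r * np.array([0.6, 0.0, -0.8])) @ solid.frame
        assert distances_to_material(solid, surface_point)[0] < 1e-9


class TestContactCount:
    def test_far_away_ligand_scores_zero(self):
        system = build_ideal_peptide("GAG")
        solid = make_template(system, radius_scale=0.7)
        far = system.with_coords(system.coords() + np.array([100.0, 0.0, 0.0]))
        marks = generate_surface_marks(far, 1.0, radius_scale=0.7)
        assert contact_count(marks, solid).count == 0

    def test_tolerance_monotonicity(self):
        system = build_ideal_peptide("GAG")
        solid = make_template(system, radius_scale=0.7)
        marks = generate_surface_marks(system, 1.0, radius_scale=0.7)
        counts = [contact_count(marks, solid, tolerance=t).count
                  for t in (0.1, 0.3, 0.5, 1.0, 2.0)]
        assert counts == sorted(counts)

    def test_counts_match_boundary_sampling_oracle(self, rng):
        """Classify each mark by brute-force distance to a dense sample of
        the material region; analytic counts agree within the sampling
        resolution band."""
        system = two_atom_system()
        solid = make_template(system, radius_scale=0.8)
        marks = generate_surface_marks(system, 1.0, radius_scale=0.8)
        lo, hi = solid.box_min, solid.box_max
        grid = np.stack(np.meshgrid(*[np.arange(l, h, 0.1) for l, h in zip(lo, hi)],
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        material = grid[points_in_material(solid, grid @ solid.frame)]
        tol = 0.5
        slack = 0.1 * np.sqrt(3)
        for serial, pts in marks.marks.items():
            if len(pts) == 0:
                continue
            local = solid.to_frame(pts)
            inmat = points_in_material(solid, pts)
            dists = distances_to_material(solid, pts)
            for k in range(len(pts)):
                if inmat[k]:
                    continue
                d_oracle = np.min(np.linalg.norm(material - local[k], axis=1))
                analytic = dists[k] <= tol
                if d_oracle < tol - slack:
                    assert analytic
                if d_oracle > tol + slack:
                    assert not analytic

    def test_rigid_rotation_invariance(self):
        # rotating marks and solid together leaves every count unchanged
        from dataclasses import replace
        from scipy.spatial.transform import Rotation
        system = build_ideal_peptide("GAG")
        solid = make_template(system, radius_scale=0.7)
        marks = generate_surface_marks(system, 1.0, radius_scale=0.7)
        base = contact_count(marks, solid, tolerance=0.5)
        R = Rotation.random(random_state=11).as_matrix()
        solid_moved = replace(solid, frame=solid.frame @ R.T)
        marks_moved = replace(
            marks, marks={s: pts @ R.T for s, pts in marks.marks.items()})
        got = contact_count(marks_moved, solid_moved, tolerance=0.5)
        assert got.count == base.count
        assert got.per_atom == base.per_atom


@pytest.fixture(scope="module")
def three_piece():
    system = build_ideal_peptide("AVA", {2: {"phi": -70.0, "psi": -40.0}})
    torsions = identify_torsions(system)
    graph = coarse_fragment(system, torsions, keep=["phi_2", "psi_2"])
    solid = make_template(system, radius_scale=0.7)
    specs = [spec for spec, _, _ in graph.joints.values()]
    native = extract_conformation(system, specs)
    return system, graph, solid, native


class TestMatchProfile:
    def test_native_beats_the_flipped_conformers(self, three_piece):
        system, graph, solid, native = three_piece
        states = [("native", dict(native.angles))]
        for dphi, dpsi in ((180.0, 0.0), (0.0, 180.0), (180.0, 180.0)):
            angles = dict(native.angles)
            angles["phi_2"] = normalize_angle(angles["phi_2"] + dphi)
            angles["psi_2"] = normalize_angle(angles["psi_2"] + dpsi)
            states.append((f"d{int(dphi)}_{int(dpsi)}", angles))
        report = match_profile(system, graph, solid, states, density=1.0)
        native_count = report.loc[report.state == "native", "contacts"].iloc[0]
        others = report.loc[report.state != "native", "contacts"]
        assert (native_count > others).all()

    def test_single_row_report(self, three_piece):
        system, graph, solid, native = three_piece
        report = match_profile(system, graph, solid, [("native", dict(native.angles))])
        assert len(report) == 1
        assert not report.collision.iloc[0]

    def test_duplicate_states_score_identically(self, three_piece):
        system, graph, solid, native = three_piece
        angles = dict(native.angles)
        angles["phi_2"] = normalize_angle(angles["phi_2"] + 60.0)
        report = match_profile(system, graph, solid,
                               [("a", angles), ("b", dict(angles))])
        assert report.contacts.iloc[0] == report.contacts.iloc[1]
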