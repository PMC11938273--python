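"""Dot-surface SASA against closed-form sphere/cap oracles, and the 3D PSA."""

import numpy as np
import pytest

from bbbperm import molio, surface
from bbbperm.exceptions import ConfigurationError, StateError
from bbbperm.molio import Atom, Molecule3D
from bbbperm.surface import DotSurfaceSettings, PolarRule

R_O = 1.52
PROBE = 1.4


def _atoms(positions, element="O", radius=R_O):
    return Molecule3D(
        id="probe",
        atoms=[Atom(element, np.asarray(p, float), vdw_radius=radius) for p in positions],
        bonds=[],
    )


class TestDotSphere:
    def test_base_icosahedron(self):
        assert len(surface.generate_dot_sphere(0)) == 12

    @pytest.mark.parametrize("level", [1, 2, 3, 4, 5])
    def test_subdivision_count_and_unit_norm(self, level):
        dots = surface.generate_dot_sphere(level)
        assert len(dots) == 10 * 4**level + 2
        assert np.abs(np.linalg.norm(dots, axis=1) - 1).max() < 1e-9

    def test_centroid_near_origin(self):
        dots = surface.generate_dot_sphere(4)
        assert np.abs(dots.mean(axis=0)).max() < 1e-3

    def test_level_out_of_range(self):
        with pytest.raises(ConfigurationError):
            surface.generate_dot_sphere(9)


class TestSasaOracles:
    def test_single_sphere_analytic(self):
        res = surface.compute_sasa(_atoms([[0, 0, 0]]))
        exact = 4 * np.pi * (R_O + PROBE) ** 2
        assert res.total_sasa == pytest.approx(exact, rel=0.005)

    def test_additivity_at_infinite_separation(self):
        res = surface.compute_sasa(_atoms([[0, 0, 0], [100, 0, 0]]))
        exact = 2 * 4 * np.pi * (R_O + PROBE) ** 2
        assert res.total_sasa == pytest.approx(exact, rel=0.005)

    def test_two_sphere_overlap_matches_cap_formula(self):
        d = R_O + PROBE  # equal spheres of radius R separated by d
        res = surface.compute_sasa(_atoms([[0, 0, 0], [d, 0, 0]]))
        R = R_O + PROBE
        exact_per_atom = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        assert res.per_atom_area[0] == pytest.approx(exact_per_atom, rel=0.01)
        assert res.per_atom_area[1] == pytest.approx(exact_per_atom, rel=0.01)

    def test_total_is_sum_of_per_atom(self, fixture_molecules):
        for mol in fixture_molecules.values():
            res = surface.compute_sasa(mol)
            assert res.total_sasa == pytest.approx(res.per_atom_area.sum(), rel=1e-6)
            assert (res.per_atom_area >= 0).all()

    def test_fully_buried_atom_has_zero_area(self):
        # a tiny sphere at the center of a big one
        mol = Molecule3D(
            id="buried",
            atoms=[
                Atom("H", np.zeros(3), vdw_radius=1.2),
                Atom("O", np.array([0.1, 0, 0]), vdw_radius=5.0),
            ],
            bonds=[],
        )
        res = surface.compute_sasa(mol)
        assert res.per_atom_area[0] == 0.0


class TestInvariances:
    def test_rigid_transform_invariance(self, fixture_molecules, rng):
        mol = fixture_molecules["glycine"]
        base = surface.compute_3d_psa(mol)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = rng.uniform(-5, 5, 3)
        moved = mol.copy()
        for atom in moved.atoms:
            atom.position = q @ atom.position + shift
        res = surface.compute_3d_psa(moved)
        assert res.total_sasa == pytest.approx(base.total_sasa, rel=0.005)
        assert res.polar_area == pytest.approx(base.polar_area, rel=0.005)

    def test_atom_order_invariance(self, fixture_molecules):
        mol = fixture_molecules["ethanol"]
        perm = [8, 2, 1, 0, 3, 4, 5, 6, 7]
        inv = {old: new for new, old in enumerate(perm)}
        shuffled = Molecule3D(
            id="ethanol-perm",
            atoms=[mol.atoms[i] for i in perm],
            bonds=[(*sorted((inv[i], inv[j])), o) for i, j, o in mol.bonds],
        )
        assert surface.compute_3d_psa(shuffled).polar_area == pytest.approx(
            surface.compute_3d_psa(mol).polar_area, rel=1e-9
        )

    def test_dot_density_convergence(self, fixture_molecules):
        for mol in fixture_molecules.values():
            s4 = surface.compute_sasa(mol, DotSurfaceSettings(density_level=4)).total_sasa
            s5 = surface.compute_sasa(mol, DotSurfaceSettings(density_level=5)).total_sasa
            assert abs(s5 - s4) / s5 < 0.01

    def test_polar_area_monotone_in_element_set(self, fixture_molecules):
        mol = fixture_molecules["glycine"]
        areas = [
            surface.compute_3d_psa(mol, rule=PolarRule(elements=frozenset(els))).polar_area
            for els in [{"O"}, {"N", "O"}, {"N", "O", "S"}, {"N", "O", "S", "C"}]
        ]
        assert all(b >= a - 1e-12 for a, b in zip(areas, areas[1:]))


class TestPolarSelection:
    def test_methane_empty(self, fixture_molecules):
        assert surface.select_polar_atoms(fixture_molecules["methane"]) == frozenset()

    def test_water_all_atoms(self, fixture_molecules):
        assert surface.select_polar_atoms(fixture_molecules["water"]) == {0, 1, 2}

    def test_ethanol_hydroxyl_only(self, fixture_molecules):
        # atom 2 is the oxygen, atom 8 its hydrogen
        assert surface.select_polar_atoms(fixture_molecules["ethanol"]) == {2, 8}

    def test_charge_filter_requires_charges(self, fixture_molecules):
        with pytest.raises(StateError):
            surface.select_polar_atoms(
                fixture_molecules["water"], PolarRule(use_charge_filter=True)
            )

    def test_charge_filter_thresholds(self, fixture_molecules):
        water = molio.assign_partial_charges(fixture_molecules["water"])
        # Gasteiger charges on water are ~(-0.41, +0.21, +0.21): below 0.6
        strict = surface.select_polar_atoms(water, PolarRule(use_charge_filter=True))
        assert strict == frozenset()
        loose = surface.select_polar_atoms(
            water, PolarRule(use_charge_filter=True, charge_threshold=0.3)
        )
        assert loose == {0, 1, 2}


class TestPsa3d:
    def test_apolar_molecules_zero(self, fixture_molecules):
        for name in ("methane", "benzene"):
            assert surface.compute_3d_psa(fixture_molecules[name]).polar_area == 0.0

    def test_water_entirely_polar(self, fixture_molecules):
        res = surface.compute_3d_psa(fixture_molecules["water"])
        assert res.polar_area == pytest.approx(res.total_sasa, rel=1e-9)

    def test_polar_bounded_by_total(self, fixture_molecules):
        for mol in fixture_molecules.values():
            res = surface.compute_3d_psa(mol)
            assert 0.0 <= res.polar_area <= res.total_sasa + 1e-9

    def test_missing_radius_is_state_error(self):
        bare = Molecule3D(id="bare", atoms=[Atom("O", np.zeros(3))], bonds=[])
        with pytest.raises(StateError):
            surface.compute_sasa(bare)
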