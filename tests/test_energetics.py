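"""MM/PBSA terms: Coulomb, LJ, SASA, nonpolar, Born solvation, ΔE_bind."""

import numpy as np
import pytest

from cleftforce import (GridSpec, IonicMedium, NonpolarModel, Selection,
                        Trajectory, coulomb_energy, fixtures, lj_energy,
                        mmpbsa_binding, nonpolar_energy, polar_solvation,
                        sasa)
from cleftforce.constants import K_COULOMB
from cleftforce.energetics import EnergyBreakdown
from cleftforce.structio import AtomTable, StructureFrame

SRC = Selection("a", chain="A")
TGT = Selection("b", chain="B")


class TestCoulombEnergy:
    def test_unit_charges_vacuum(self):
        fr = fixtures.make_point_charge_pair(1.0, -1.0, 10.0)
        e = coulomb_energy(fr, SRC, TGT, dielectric=1.0)
        assert e == pytest.approx(-33.20637, abs=1e-4)

    def test_dielectric_scaling(self):
        fr = fixtures.make_point_charge_pair(1.0, -1.0, 10.0)
        e = coulomb_energy(fr, SRC, TGT, dielectric=80.0)
        assert e == pytest.approx(-0.41508, abs=1e-4)

    def test_zero_charge_contributes_nothing(self):
        fr = fixtures.make_point_charge_pair(0.0, -1.0, 10.0)
        assert coulomb_energy(fr, SRC, TGT) == 0.0


class TestLJEnergy:
    @staticmethod
    def _lj_pair(r, eps=(0.1, 0.2), rmin_half=(1.8, 1.9)):
        atoms = AtomTable(
            serial=np.array([1, 2]),
            name=np.array(["C1", "C2"], dtype="U6"),
            residue_name=np.array(["DOM", "DOM"], dtype="U5"),
            chain=np.array(["A", "B"], dtype="U4"),
            residue_number=np.array([1, 2]),
            mass=np.array([12.0, 12.0]),
            charge=np.zeros(2), radius=np.array([1.7, 1.7]),
            lj_epsilon=np.array(eps), lj_rmin_half=np.array(rmin_half),
        )
        coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        return StructureFrame(atoms, coords)

    def test_minimum_is_minus_eps(self):
        rmin = 1.8 + 1.9
        fr = self._lj_pair(rmin)
        eps_ij = np.sqrt(0.1 * 0.2)
        assert lj_energy(fr, SRC, TGT) == pytest.approx(-eps_ij, rel=1e-12)

    def test_long_range_vanishes_from_below(self):
        e = lj_energy(self._lj_pair(50.0), SRC, TGT)
        assert -1e-6 < e < 0.0

    def test_three_atom_hand_sum(self):
        """Cross-check against term-by-term enumeration."""
        atoms = AtomTable(
            serial=np.arange(1, 4),
            name=np.array(["C1", "C2", "C3"], dtype="U6"),
            residue_name=np.array(["DOM"] * 3, dtype="U5"),
            chain=np.array(["A", "B", "B"], dtype="U4"),
            residue_number=np.array([1, 2, 2]),
            mass=np.full(3, 12.0), charge=np.zeros(3),
            radius=np.full(3, 1.7),
            lj_epsilon=np.array([0.1, 0.2, 0.05]),
            lj_rmin_half=np.array([1.8, 1.9, 2.0]),
        )
        coords = np.array([[0, 0, 0], [4.0, 0, 0], [0, 4.5, 0.0]])
        fr = StructureFrame(atoms, coords)
        total = 0.0
        for j, (eps_j, rh_j, pos) in enumerate(
                zip([0.2, 0.05], [1.9, 2.0], coords[1:])):
            r = np.linalg.norm(pos - coords[0])
            eps_ij = np.sqrt(0.1 * eps_j)
            s6 = ((1.8 + rh_j) / r) ** 6
            total += eps_ij * (s6 * s6 - 2 * s6)
        assert lj_energy(fr, SRC, TGT) == pytest.approx(total, rel=1e-12)


class TestSasa:
    def test_single_sphere_closed_form(self):
        fr = fixtures.make_born_sphere(1.0, 2.0)
        res = sasa(fr, probe=1.4, n_points=1000)
        exact = 4.0 * np.pi * 3.4 ** 2
        assert abs(res.total - exact) / exact < 0.01

    def test_buried_atom_is_zero(self):
        # central atom caged by 26 overlapping large spheres
        offsets = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) != (0, 0, 0):
                        offsets.append((2.5 * dx, 2.5 * dy, 2.5 * dz))
        n = 1 + len(offsets)
        atoms = AtomTable(
            serial=np.arange(1, n + 1),
            name=np.array(["C1"] * n, dtype="U6"),
            residue_name=np.array(["DOM"] * n, dtype="U5"),
            chain=np.array(["A"] * n, dtype="U4"),
            residue_number=np.arange(1, n + 1),
            mass=np.full(n, 12.0), charge=np.zeros(n),
            radius=np.concatenate([[1.5], np.full(len(offsets), 2.5)]),
            lj_epsilon=np.zeros(n), lj_rmin_half=np.full(n, 2.0),
        )
        coords = np.vstack([[0.0, 0.0, 0.0], np.array(offsets)])
        res = sasa(StructureFrame(atoms, coords), n_points=500)
        assert res.per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_far_apart_atoms_are_additive(self):
        fr = fixtures.make_point_charge_pair(0.0, 0.0, 100.0)
        res = sasa(fr, n_points=1000)
        single = 4.0 * np.pi * (1.5 + 1.4) ** 2
        assert res.total == pytest.approx(2 * single, rel=0.01)

    def test_convergence_toward_closed_form(self):
        fr = fixtures.make_born_sphere(1.0, 2.0)
        exact = 4.0 * np.pi * 3.4 ** 2
        errors = [abs(sasa(fr, n_points=n).total - exact)
                  for n in (100, 1000, 10000)]
        assert errors[0] >= errors[1] >= errors[2]


class TestNonpolar:
    def test_intercept_only_at_zero_area(self):
        assert nonpolar_energy(0.0) == pytest.approx(0.92)

    def test_affine_value(self):
        assert nonpolar_energy(1000.0) == pytest.approx(6.32)

    def test_doubling_adds_slope_times_area(self):
        m = NonpolarModel()
        assert nonpolar_energy(2000.0, m) - nonpolar_energy(1000.0, m) == \
            pytest.approx(0.0054 * 1000.0)


class TestPolarSolvation:
    BORN_EXACT = -(K_COULOMB / (2 * 2.0)) * (1 / 2.0 - 1 / 80.0)

    def test_born_sphere_within_10pct_at_2_grid(self, saltfree_medium):
        fr = fixtures.make_born_sphere(1.0, 2.0)
        e = polar_solvation(fr, saltfree_medium, GridSpec(resolution=2.0))
        assert abs(e - self.BORN_EXACT) / abs(self.BORN_EXACT) < 0.10

    def test_refinement_improves_born_energy(self, saltfree_medium):
        fr = fixtures.make_born_sphere(1.0, 2.0)
        e2 = polar_solvation(fr, saltfree_medium, GridSpec(resolution=2.0))
        e4 = polar_solvation(fr, saltfree_medium, GridSpec(resolution=4.0))
        assert abs(e4 - self.BORN_EXACT) < abs(e2 - self.BORN_EXACT)

    def test_zero_charge_zero_energy(self, saltfree_medium):
        fr = fixtures.make_born_sphere(0.0, 2.0)
        assert polar_solvation(fr, saltfree_medium) == \
            pytest.approx(0.0, abs=1e-12)

    def test_quadratic_charge_scaling(self, saltfree_medium):
        grid = GridSpec(resolution=2.0)
        e1 = polar_solvation(fixtures.make_born_sphere(1.0, 2.0),
                             saltfree_medium, grid)
        e2 = polar_solvation(fixtures.make_born_sphere(2.0, 2.0),
                             saltfree_medium, grid)
        assert e2 / e1 == pytest.approx(4.0, rel=1e-6)

    def test_charge_sign_symmetry(self, saltfree_medium):
        grid = GridSpec(resolution=2.0)
        ep = polar_solvation(fixtures.make_born_sphere(1.0, 2.0),
                             saltfree_medium, grid)
        em = polar_solvation(fixtures.make_born_sphere(-1.0, 2.0),
                             saltfree_medium, grid)
        assert ep == pytest.approx(em, rel=1e-9)


class TestEnergyBreakdown:
    def test_total_is_exact_sum(self):
        b = EnergyBreakdown(coulomb=-3.1, vdw=0.7, polar=12.9, nonpolar=1.4)
        assert b.total == pytest.approx(-3.1 + 0.7 + 12.9 + 1.4, abs=1e-12)


class TestMMPBSA:
    @staticmethod
    def _pair_traj(q1, q2, sep, n_frames=2):
        fr = fixtures.make_point_charge_pair(q1, q2, sep)
        coords = np.repeat(fr.coords[None], n_frames, axis=0)
        times = 0.1 * np.arange(1, n_frames + 1)
        return Trajectory(fr.atoms, coords, times)

    COMPLEX = Selection("complex", intervals=[(1, 2)])

    def test_neutral_far_pair_leaves_only_intercept(self, saltfree_medium):
        """With ΔSASA = 0 and no charges, ΔE reduces to −β = −0.92."""
        traj = self._pair_traj(0.0, 0.0, 100.0)
        rec = mmpbsa_binding(traj, self.COMPLEX, SRC, TGT,
                             medium=saltfree_medium, sasa_points=1000)
        assert rec.delta_nonpolar == pytest.approx(-0.92, abs=0.02)
        assert rec.delta_polar == pytest.approx(0.0, abs=1e-9)
        assert rec.delta_coulomb == 0.0
        assert rec.delta_e == pytest.approx(-0.92, abs=0.03)

    def test_charged_pair_sign_structure(self, saltfree_medium):
        """Attractive Coulomb with a desolvation penalty on binding."""
        traj = self._pair_traj(1.0, -1.0, 6.0)
        rec = mmpbsa_binding(traj, self.COMPLEX, SRC, TGT,
                             medium=saltfree_medium, sasa_points=500)
        assert rec.delta_coulomb < 0
        assert rec.delta_polar > 0

    def test_label_swap_symmetry(self, saltfree_medium):
        traj = self._pair_traj(1.0, -1.0, 6.0)
        a = mmpbsa_binding(traj, self.COMPLEX, SRC, TGT,
                           medium=saltfree_medium, sasa_points=500)
        b = mmpbsa_binding(traj, self.COMPLEX, TGT, SRC,
                           medium=saltfree_medium, sasa_points=500)
        assert a.delta_e == pytest.approx(b.delta_e, abs=1e-12)

    def test_intra_part_mm_terms_cancel(self, saltfree_medium):
        """ΔE_c equals the inter-part Coulomb term alone: the intra-part
        contributions of complex and parts subtract out exactly."""
        traj = self._pair_traj(1.0, -1.0, 6.0)
        rec = mmpbsa_binding(traj, self.COMPLEX, SRC, TGT,
                             medium=saltfree_medium, sasa_points=500)
        fr = traj.frame(0)
        inter = coulomb_energy(fr, SRC, TGT,
                               saltfree_medium.solute_dielectric)
        assert rec.delta_coulomb == pytest.approx(inter, rel=1e-12)

    def test_terms_sum_to_delta_e(self, saltfree_medium):
        traj = self._pair_traj(1.0, -1.0, 6.0)
        rec = mmpbsa_binding(traj, self.COMPLEX, SRC, TGT,
                             medium=saltfree_medium, sasa_points=500)
        assert rec.delta_e == pytest.approx(
            rec.delta_coulomb + rec.delta_vdw + rec.delta_polar
            + rec.delta_nonpolar, abs=1e-9)

    def test_overlapping_parts_rejected(self, saltfree_medium):
        traj = self._pair_traj(1.0, -1.0, 6.0)
        with pytest.raises(ValueError):
            mmpbsa_binding(traj, self.COMPLEX, SRC, SRC,
                           medium=saltfree_medium)

    def test_biopython_sasa_cross_check(self):
        """Independent Shrake–Rupley on the same two-sphere system."""
        Bio = pytest.importorskip("Bio.PDB")
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        fr = fixtures.make_point_charge_pair(0.0, 0.0, 4.0)
        ours = sasa(fr, probe=1.4, n_points=960)

        sb = StructureBuilder()
        sb.init_structure("s")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg("    ")
        for i in range(fr.n_atoms):
            sb.init_residue(f"R{i}", " ", i + 1, " ")
            sb.init_atom(f"C{i}", fr.coords[i], 0.0, 1.0, " ", f"C{i}",
                         i + 1, element="C")
        struct = sb.get_structure()
        # align Biopython's element radius table with the fixture radius
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"C": float(fr.atoms.radius[0])})
        sr.compute(struct, level="S")
        assert ours.total == pytest.approx(struct.sasa, rel=0.02)
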