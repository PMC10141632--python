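"""Mass-center topology: cleft series, window stats, RMSD, separation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cleftforce import (Selection, cleft_series, fixtures, kabsch_rmsd,
                        mass_center, resolve_selection, separate,
                        window_stats)
from cleftforce.structio import AtomTable, StructureFrame


def _frame(coords, masses):
    n = len(masses)
    atoms = AtomTable(
        serial=np.arange(1, n + 1),
        name=np.array([f"C{i}" for i in range(n)], dtype="U6"),
        residue_name=np.array(["DOM"] * n, dtype="U5"),
        chain=np.array(["A"] * n, dtype="U4"),
        residue_number=np.ones(n, dtype=int),
        mass=np.asarray(masses, dtype=float),
    )
    return StructureFrame(atoms, np.asarray(coords, dtype=float))


class TestMassCenter:
    def test_equal_mass_midpoint(self):
        fr = _frame([[0, 0, 0], [2, 0, 0]], [12.0, 12.0])
        assert np.allclose(mass_center(fr, np.array([0, 1])), [1, 0, 0])

    def test_mass_weighting(self):
        fr = _frame([[0, 0, 0], [4, 0, 0]], [1.0, 3.0])
        assert np.allclose(mass_center(fr, np.array([0, 1])), [3, 0, 0])

    def test_single_atom(self):
        fr = _frame([[1.5, -2.0, 3.0]], [12.0])
        assert np.allclose(mass_center(fr, np.array([0])), [1.5, -2.0, 3.0])

    def test_geometric_mode_ignores_masses(self):
        fr = _frame([[0, 0, 0], [4, 0, 0]], [1.0, 3.0])
        assert np.allclose(
            mass_center(fr, np.array([0, 1]), weighted=False), [2, 0, 0])


class TestCleftSeries:
    def test_constant_when_sd_zero(self, chain_a, chain_b):
        traj = fixtures.make_two_domain_trajectory(200, 0.1, 10.0, 0.0)
        series = cleft_series(traj, chain_a, chain_b)
        assert np.allclose(series.distances, 10.0, atol=1e-9)

    def test_matches_generator_draws(self, two_domain_traj, chain_a,
                                     chain_b):
        """Distances recomputed from coordinates equal the internal draws."""
        series = cleft_series(two_domain_traj, chain_a, chain_b)
        # domain B translates along +x only; the draw is the x offset of
        # its mass center relative to domain A's (at the origin)
        ib = resolve_selection(two_domain_traj, chain_b)
        draws = two_domain_traj.coords[:, ib, 0].mean(axis=1)
        assert np.allclose(series.distances, draws, atol=1e-9)

    def test_same_selection_gives_zero(self, two_domain_traj, chain_a):
        series = cleft_series(two_domain_traj, chain_a, chain_a)
        assert np.allclose(series.distances, 0.0)

    def test_invariant_under_global_rigid_motion(self, chain_a, chain_b):
        traj = fixtures.make_two_domain_trajectory(5, 0.1, 10.0, 1.0, seed=2)
        d0 = cleft_series(traj, chain_a, chain_b).distances
        rot = Rotation.from_euler("zyx", [10, 20, 30], degrees=True)
        moved = fixtures.Trajectory(
            traj.atoms,
            rot.apply(traj.coords.reshape(-1, 3)).reshape(traj.coords.shape)
            + np.array([1.0, -2.0, 3.0]),
            traj.times)
        d1 = cleft_series(moved, chain_a, chain_b).distances
        assert np.allclose(d0, d1, atol=1e-9)


class TestWindowStats:
    def test_70_to_100_ns_has_300_frames(self, two_domain_traj, chain_a,
                                         chain_b):
        series = cleft_series(two_domain_traj, chain_a, chain_b)
        stats = window_stats(series, 70.0, 100.0)
        assert stats.n_frames == 300

    def test_constant_series_sd_zero(self, chain_a, chain_b):
        traj = fixtures.make_two_domain_trajectory(1000, 0.1, 10.0, 0.0)
        stats = window_stats(cleft_series(traj, chain_a, chain_b), 70, 100)
        assert stats.mean == pytest.approx(10.0, abs=1e-12)
        assert stats.sd == 0.0

    def test_matches_brute_force_recount(self, two_domain_traj, chain_a,
                                         chain_b):
        series = cleft_series(two_domain_traj, chain_a, chain_b)
        stats = window_stats(series, 70.0, 100.0)
        sel = (series.times > 70.0) & (series.times <= 100.0)
        vals = series.distances[sel]
        assert stats.mean == pytest.approx(vals.mean(), abs=1e-12)
        assert stats.sd == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def test_empty_window_raises(self, two_domain_traj, chain_a, chain_b):
        series = cleft_series(two_domain_traj, chain_a, chain_b)
        with pytest.raises(ValueError):
            window_stats(series, 200.0, 300.0)


def _independent_kabsch_rmsd(p, q):
    """Direct SVD Kabsch on two point sets (oracle path)."""
    p = p - p.mean(0)
    q = q - q.mean(0)
    u, s, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ p.T).T - q
    return float(np.sqrt((diff ** 2).sum() / len(p)))


class TestKabschRMSD:
    def test_identical_frames_zero(self):
        traj = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0)
        fr = traj.frame(0)
        assert kabsch_rmsd(fr, fr) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        traj = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0)
        fr = traj.frame(0)
        moved = fr.copy()
        rot = Rotation.from_euler("xyz", [33, -71, 12], degrees=True)
        moved.coords = rot.apply(moved.coords) + np.array([5, -1, 2.5])
        assert kabsch_rmsd(moved, fr) <= 1e-9

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            p = rng.normal(size=(3, 3)) * 3
            q = p.copy()
            q[0] += rng.normal(size=3)
            ours_fwd = kabsch_rmsd(_frame(p, [1, 1, 1]),
                                   _frame(q, [1, 1, 1]))
            assert ours_fwd == pytest.approx(_independent_kabsch_rmsd(p, q),
                                             abs=1e-9)
            # symmetry in the two arguments
            ours_rev = kabsch_rmsd(_frame(q, [1, 1, 1]),
                                   _frame(p, [1, 1, 1]))
            assert ours_fwd == pytest.approx(ours_rev, abs=1e-9)

    def test_atom_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_rmsd(_frame(np.zeros((3, 3)), [1, 1, 1]),
                        _frame(np.zeros((4, 3)), [1, 1, 1, 1]))


class TestSeparate:
    def test_zero_displacement_is_identity(self, chain_a, chain_b):
        fr = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0).frame(0)
        out = separate(fr, chain_b, chain_a, 0.0)
        assert np.allclose(out.coords, fr.coords, atol=1e-12)

    @pytest.mark.parametrize("displacement", [10.0, 15.0, 20.0])
    def test_new_center_distance_is_additive(self, displacement, chain_a,
                                             chain_b):
        fr = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0).frame(0)
        out = separate(fr, chain_b, chain_a, displacement)
        ca = mass_center(out, resolve_selection(out, chain_a))
        cb = mass_center(out, resolve_selection(out, chain_b))
        assert np.linalg.norm(ca - cb) == pytest.approx(10.0 + displacement,
                                                        abs=1e-9)

    def test_composition_along_axis(self, chain_a, chain_b):
        fr = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0).frame(0)
        once = separate(separate(fr, chain_b, chain_a, 10.0),
                        chain_b, chain_a, 10.0)
        twice = separate(fr, chain_b, chain_a, 20.0)
        assert np.abs(once.coords - twice.coords).max() <= 1e-9

    def test_internal_geometry_preserved(self, chain_a, chain_b):
        fr = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0).frame(0)
        out = separate(fr, chain_b, chain_a, 15.0)
        ib = resolve_selection(fr, chain_b)
        before = fr.coords[ib]
        after = out.coords[ib]
        d_before = np.linalg.norm(before[:, None] - before[None], axis=2)
        d_after = np.linalg.norm(after[:, None] - after[None], axis=2)
        assert np.abs(d_before - d_after).max() <= 1e-9
        # fixed domain untouched
        ia = resolve_selection(fr, chain_a)
        assert np.array_equal(fr.coords[ia], out.coords[ia])

    def test_overlapping_selections_rejected(self, chain_a):
        fr = fixtures.make_two_domain_trajectory(1, 0.1, 10.0, 0.0).frame(0)
        with pytest.raises(ValueError, match="disjoint"):
            separate(fr, chain_a, chain_a, 5.0)
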