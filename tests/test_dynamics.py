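"""Superposition, fluctuation statistics, hydrogen bonds, collective
motion analyses, and clustering."""

import numpy as np
import pytest

from gbind.core import Frame, Selection, Topology, Trajectory
from gbind.dynamics import (
    HBondCriteria,
    dccm,
    hbond_occupancy,
    kmeans_cluster,
    pca,
    rmsd_series,
    rmsf,
    superpose,
)
from gbind.synthetic import EnsembleSpec, generate_ensemble

from conftest import make_atom, topology_from


def rigid_move(coords, theta=0.7, axis=(0.3, -0.5, 0.81),
               shift=(4.0, -2.0, 9.0)):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = (np.eye(3) + np.sin(theta) * k
           + (1 - np.cos(theta)) * (k @ k))
    return coords @ rot.T + np.asarray(shift)


@pytest.fixture()
def blob():
    rng = np.random.default_rng(8)
    return rng.uniform(0, 10, size=(12, 3))


class TestSuperpose:
    def test_identity_fit(self, blob):
        res = superpose(blob, blob)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_copy_recovers_zero_rmsd(self, blob):
        res = superpose(rigid_move(blob), blob)
        assert res.rmsd < 1e-10
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_rotation_is_proper_even_for_reflection_prone_input(self):
        # near-planar configurations tempt an improper (det -1) fit
        coords = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0.01]])
        res = superpose(coords[::-1], coords)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_rotation_grid_oracle(self):
        # exhaustive search over single-axis rotations for a toy pair
        rng = np.random.default_rng(21)
        ref = rng.uniform(0, 5, size=(6, 3))
        mobile = rigid_move(ref, theta=0.4, axis=(0, 0, 1), shift=(1, 2, 3))
        mobile = mobile + rng.normal(0, 0.05, mobile.shape)  # slight noise
        got = superpose(mobile, ref).rmsd
        best = np.inf
        mc = mobile - mobile.mean(axis=0)
        rc = ref - ref.mean(axis=0)
        for theta in np.linspace(-np.pi, np.pi, 20001):
            rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                            [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
            r = np.sqrt(np.mean(np.sum((mc @ rot.T - rc) ** 2, axis=1)))
            best = min(best, r)
        # Kabsch must be at least as good as the best grid rotation and
        # close to it (the noise tilts the true optimum slightly off-axis)
        assert got <= best + 1e-6
        assert got == pytest.approx(best, abs=1e-3)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="3 atoms"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestRmsd:
    def test_copies_give_zero_series(self, blob):
        top, frame = topology_from(blob)
        traj = Trajectory(frames=tuple(
            Frame(rigid_move(blob, theta=0.1 * i)) for i in range(4)))
        sel = Selection(tuple(range(len(blob))), "all")
        series = rmsd_series(traj, frame, sel)
        assert series.shape == (4,)
        np.testing.assert_allclose(series, 0.0, atol=1e-10)

    def test_isotropic_ensemble_matches_gaussian_expectation(self, blob):
        top, frame = topology_from(blob)
        sigma = 0.25
        n_atoms = len(blob)
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=sigma ** 2 * np.eye(3 * n_atoms),
            n_frames=600, seed=13), top)
        sel = Selection(tuple(range(n_atoms)), "all")
        series = rmsd_series(traj, frame, sel)
        # E[RMSD^2] ~ 3 sigma^2 reduced by the 6 fitted rigid dof
        expected = np.sqrt(3 * sigma ** 2 * (1 - 2.0 / n_atoms))
        assert np.mean(series) == pytest.approx(expected, rel=0.05)


class TestRmsf:
    def test_zero_covariance_gives_zero_profile(self, toy_complex):
        top, frame = toy_complex
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=np.zeros((3 * top.n_atoms,) * 2),
            n_frames=5, seed=0), top)
        from gbind.core import select
        prof = rmsf([traj], select(top, "calpha"), topology=top)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-10)

    def test_isotropic_variance_matches_closed_form(self, blob):
        top, frame = topology_from(blob)
        sigma = 0.4
        traj = generate_ensemble(EnsembleSpec(
            reference=frame,
            covariance=sigma ** 2 * np.eye(3 * len(blob)),
            n_frames=3000, seed=5), top)
        sel = Selection(tuple(range(len(blob))), "all")
        prof = rmsf([traj], sel, topology=top, align=False)
        np.testing.assert_allclose(prof.rmsf, np.sqrt(3) * sigma, rtol=0.05)

    def test_identical_replicas_have_zero_standard_error(self, blob):
        top, frame = topology_from(blob)
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=0.04 * np.eye(3 * len(blob)),
            n_frames=50, seed=9), top)
        sel = Selection(tuple(range(len(blob))), "all")
        prof = rmsf([traj, traj], sel, topology=top)
        np.testing.assert_allclose(prof.standard_error, 0.0, atol=1e-12)
        assert prof.per_replica.shape == (2, len(blob))


class TestHbonds:
    def _donor_acceptor_system(self, da=2.8, angle_deg=180.0):
        # receptor: donor O with H; ligand: acceptor O
        d = np.array([0.0, 0, 0])
        h_dir = np.array([1.0, 0, 0])
        h = d + 1.0 * h_dir
        theta = np.deg2rad(180.0 - angle_deg)
        a_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
        a = h + (da - 1.0) * a_dir if angle_deg == 180.0 else None
        if a is None:
            # place acceptor at requested D-H...A angle with D-A = da
            # via rotation of the acceptor direction about H
            a = h + (da - 1.0) * a_dir
        atoms = (
            make_atom(0, name="OG", element="O", residue_index=0),
            make_atom(1, name="HG", element="H", residue_index=0),
            make_atom(2, name="O1", element="O", residue_index=1,
                      segment="ligand"),
        )
        top = Topology(atoms=atoms)
        frame = Frame(np.vstack([d, h, a]))
        return top, frame

    def test_ideal_geometry_detected(self):
        top, frame = self._donor_acceptor_system(da=2.8, angle_deg=180.0)
        bonds = hbond_occupancy(top, Trajectory(frames=(frame,)))
        assert len(bonds) == 1 and bonds[0].occupancy == 1.0

    def test_long_contact_not_detected(self):
        top, frame = self._donor_acceptor_system(da=4.0)
        assert hbond_occupancy(top, Trajectory(frames=(frame,))) == []

    def test_bent_geometry_not_detected(self):
        top, frame = self._donor_acceptor_system(da=2.8, angle_deg=100.0)
        crit = HBondCriteria()
        assert hbond_occupancy(top, Trajectory(frames=(frame,)),
                               criteria=crit) == []

    def test_occupancy_counts_fraction_of_frames(self):
        top, frame = self._donor_acceptor_system()
        far = Frame(frame.coordinates + np.array([[0, 0, 0]] * 2
                                                 + [[10.0, 0, 0]]))
        frames = tuple([frame] * 6 + [far] * 4)
        bonds = hbond_occupancy(top, Trajectory(frames=frames))
        assert bonds[0].occupancy == pytest.approx(0.6)

    def test_explicit_donor_without_hydrogen_warns(self):
        top, frame = self._donor_acceptor_system()
        donors = Selection((0, 2), "donors")  # atom 2 has no hydrogen
        acceptors = Selection((2,), "acceptors")
        with pytest.warns(RuntimeWarning, match="no attached hydrogen"):
            hbond_occupancy(top, Trajectory(frames=(frame,)),
                            donors=Selection((2,), "d"),
                            acceptors=Selection((0,), "a"))


class TestDccm:
    def _correlated_ensemble(self, c, n_frames, seed=3):
        coords = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 8.0, 0]])
        top, frame = topology_from(coords)
        cov = np.eye(9)
        for k in range(3):  # correlate atoms 0 and 1 axis-by-axis
            cov[k, 3 + k] = cov[3 + k, k] = c
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=cov, n_frames=n_frames,
            seed=seed), top)
        sel = Selection((0, 1, 2), "all")
        return dccm(traj, sel, topology=top, align=False)

    def test_diagonal_is_exactly_one(self):
        cm = self._correlated_ensemble(0.5, 200)
        np.testing.assert_array_equal(np.diag(cm.matrix), 1.0)

    def test_identical_streams_fully_correlated(self, blob):
        top, frame = topology_from(blob[:3])
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(100):
            d = rng.normal(0, 1, 3)
            coords = frame.coordinates.copy()
            coords[0] += d
            coords[1] += d  # same displacement stream
            frames.append(Frame(coords))
        cm = dccm(Trajectory(frames=tuple(frames)),
                  Selection((0, 1), "pair"), align=False)
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_planted_correlation_recovered(self):
        n = 5000
        cm = self._correlated_ensemble(0.8, n)
        se = (1 - 0.8 ** 2) / np.sqrt(n)
        assert abs(cm.matrix[0, 1] - 0.8) < 3 * se
        assert abs(cm.matrix[0, 2]) < 4 / np.sqrt(n)

    def test_zero_variance_atom_zeroed_with_warning(self):
        coords = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 8.0, 0]])
        top, frame = topology_from(coords)
        cov = np.zeros((9, 9))
        cov[:3, :3] = np.eye(3)  # only atom 0 moves
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=cov, n_frames=50, seed=1), top)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            cm = dccm(traj, Selection((0, 1, 2), "all"), align=False)
        assert cm.matrix[1, 2] == 0.0 and cm.matrix[1, 1] == 1.0


class TestPca:
    def test_rank_one_motion_loads_on_first_component(self, blob):
        top, frame = topology_from(blob[:4])
        cov = np.zeros((12, 12))
        cov[0, 0] = 2.0  # single Cartesian dof of one atom
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=cov, n_frames=400, seed=2), top)
        res = pca(traj, Selection((0, 1, 2, 3), "all"), n_components=2,
                  align=False)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)

    def test_planted_spectrum_fractions_recovered(self):
        coords = np.array([[0.0, 0, 0], [9.0, 0, 0], [0, 9.0, 0]])
        top, frame = topology_from(coords)
        cov = np.zeros((9, 9))
        cov[0, 0], cov[1, 1], cov[2, 2] = 4.0, 2.0, 1.0
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=cov, n_frames=5000, seed=6), top)
        res = pca(traj, Selection((0, 1, 2), "all"), n_components=3,
                  align=False)
        np.testing.assert_allclose(
            res.variance_fractions[:3], [4 / 7, 2 / 7, 1 / 7], atol=0.02)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert res.projections.shape == (5000, 3)

    def test_fraction_sum_and_shuffle_stability(self, blob):
        top, frame = topology_from(blob[:5])
        rng = np.random.default_rng(4)
        cov = rng.normal(size=(15, 15))
        cov = cov @ cov.T
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=cov, n_frames=300, seed=8), top)
        sel = Selection(tuple(range(5)), "all")
        res = pca(traj, sel, align=False)
        shuffled = Trajectory(frames=tuple(
            traj.frames[i] for i in rng.permutation(300)))
        res2 = pca(shuffled, sel, align=False)
        np.testing.assert_allclose(res.variance_fractions,
                                   res2.variance_fractions, atol=1e-10)

    def test_too_many_components_rejected(self, blob):
        top, frame = topology_from(blob[:3])
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=np.eye(9), n_frames=10, seed=0),
            top)
        with pytest.raises(ValueError, match="exceeds"):
            pca(traj, Selection((0, 1, 2), "all"), n_components=10,
                align=False)


class TestClustering:
    def _two_state_ensemble(self, n_frames=800, frac=0.7, seed=7):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 8, size=(6, 3))
        top, frame = topology_from(base)
        other = base + np.array([6.0, 0, 0]) * np.array([[1, 0, 0]] * 6)
        n_a = int(round(frac * n_frames))
        frames = []
        for i in range(n_frames):
            center = base if i < n_a else other
            frames.append(Frame(center + rng.normal(0, 0.15, base.shape)))
        return top, Trajectory(frames=tuple(frames)), n_a

    def test_degenerate_single_cluster(self, blob):
        top, frame = topology_from(blob[:4])
        traj = Trajectory(frames=tuple([frame] * 10))
        sel = Selection((0, 1, 2, 3), "all")
        res = kmeans_cluster(traj, sel, k=1, seed=0)
        assert res.populations.tolist() == [1.0]
        assert res.representative_frames[0] == 0  # lowest index on ties

    def test_two_state_populations_recovered(self):
        top, traj, n_a = self._two_state_ensemble()
        sel = Selection(tuple(range(6)), "all")
        res = kmeans_cluster(traj, sel, k=2, seed=0, align=False)
        np.testing.assert_allclose(res.populations, [0.7, 0.3], atol=0.02)
        assert res.populations.sum() == pytest.approx(1.0)
        # canonical labels: cluster 0 is the most populated
        assert (res.labels == 0).mean() == pytest.approx(
            res.populations[0])

    def test_representative_matches_linear_scan(self):
        top, traj, _ = self._two_state_ensemble(n_frames=200)
        sel = Selection(tuple(range(6)), "all")
        res = kmeans_cluster(traj, sel, k=2, seed=3, align=False)
        flat = traj.coordinates()[:, sel.indices, :].reshape(200, -1)
        for c in range(2):
            members = np.where(res.labels == c)[0]
            centroid = flat[members].mean(axis=0)
            d = np.linalg.norm(flat[members] - centroid, axis=1)
            assert res.representative_frames[c] == members[np.argmin(d)]
            assert res.labels[res.representative_frames[c]] == c

    def test_seed_determinism(self):
        top, traj, _ = self._two_state_ensemble(n_frames=120)
        sel = Selection(tuple(range(6)), "all")
        a = kmeans_cluster(traj, sel, k=3, seed=11, align=False)
        b = kmeans_cluster(traj, sel, k=3, seed=11, align=False)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.representative_frames,
                                      b.representative_frames)

    def test_k_larger_than_frames_rejected(self, blob):
        top, frame = topology_from(blob[:4])
        traj = Trajectory(frames=(frame, frame))
        with pytest.raises(ValueError, match="k must be"):
            kmeans_cluster(traj, Selection((0, 1, 2, 3), "a"), k=5, seed=0)


class TestRigidInvariance:
    def test_statistics_invariant_under_global_rigid_motion(self, blob):
        top, frame = topology_from(blob)
        n = len(blob)
        rng = np.random.default_rng(10)
        cov = rng.normal(size=(3 * n, 3 * n))
        cov = 0.02 * cov @ cov.T
        traj = generate_ensemble(EnsembleSpec(
            reference=frame, covariance=cov, n_frames=150, seed=3), top)
        moved = Trajectory(frames=tuple(
            Frame(rigid_move(f.coordinates)) for f in traj.frames))
        sel = Selection(tuple(range(n)), "all")
        p1 = rmsf(traj, sel)
        p2 = rmsf(moved, sel)
        np.testing.assert_allclose(p1.rmsf, p2.rmsf, atol=1e-8)
        c1 = dccm(traj, sel)
        c2 = dccm(moved, sel)
        np.testing.assert_allclose(c1.matrix, c2.matrix, atol=1e-8)
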