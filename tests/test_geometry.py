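import numpy as np
import pytest

from discbelt.geometry import (
    RigidTransform, bilayer_normal, reorient, radius_of_gyration,
    kabsch_superpose, backbone_rmsd_series, detect_escaped_lipids,
)
from discbelt.structure_io import Frame, Trajectory, select_atoms
from discbelt.synthetic import DiscSpec, generate_nanodisc, perturb_frames


def rotation_about(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def quaternion_rmsd(P, Q):
    """Brute-force optimal-superposition RMSD via the quaternion
    characteristic polynomial (largest eigenvalue of the 4x4 key matrix)."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K).max()
    msd = (np.sum(P0 ** 2) + np.sum(Q0 ** 2) - 2 * lam) / len(P)
    return np.sqrt(max(msd, 0.0))


class TestBilayerNormal:
    def test_flat_disc_gives_z(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        n = bilayer_normal(f, p)
        assert abs(n @ np.array([0, 0, 1.0])) > 0.9999

    def test_equivariance_under_rotation(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        R = rotation_about([1, 0, 0], np.pi / 2)
        rotated = f.with_positions(f.positions @ R.T)
        n = bilayer_normal(rotated, p)
        true_normal = R @ np.array([0, 0, 1.0])
        assert abs(n @ true_normal) > 0.999

    def test_noisy_disc(self, disc):
        f = disc[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        n = bilayer_normal(f, p)
        assert abs(n[2]) > 0.99

    def test_collinear_atoms_rejected(self):
        f = Frame(["P"] * 5, ["P"] * 5, ["DMPC"] * 5, range(1, 6), ["L"] * 5,
                  [[i, 0.0, 0.0] for i in range(5)], [30.97] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            bilayer_normal(f, np.arange(5))


class TestReorient:
    def test_aligned_frame_keeps_normal(self, disc_noise_free):
        # a circular disc has degenerate in-plane axes, so only the normal
        # mapping (z -> z) is well defined for an already-aligned frame
        f = disc_noise_free[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        out, tf = reorient(f, p)
        assert abs(tf.rotation[2, 2]) > 1.0 - 1e-9

    def test_restores_z_variance_minimal(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        R = rotation_about([1, 2, 3], 1.1)
        rotated = f.with_positions(f.positions @ R.T + np.array([5, -2, 7.0]))
        out, _ = reorient(rotated, p)
        pts = out.positions[p]
        var = pts.var(axis=0)
        assert var[2] == pytest.approx(min(var), rel=1e-9)
        com = out.masses[p] @ out.positions[p] / out.masses[p].sum()
        assert np.allclose(com, 0.0, atol=1e-9)

    def test_idempotent_up_to_axis_sign(self, disc):
        f = disc[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        once, _ = reorient(f, p)
        twice, tf = reorient(once, p)
        assert np.allclose(np.abs(tf.rotation), np.eye(3), atol=1e-6)

    def test_major_axis_to_x(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        p = select_atoms(f, atom_name="P", residue_name="DMPC")
        stretched = f.with_positions(f.positions * np.array([1.0, 1.4, 1.0]))
        R = rotation_about([0, 0, 1], 0.7)
        rotated = stretched.with_positions(stretched.positions @ R.T)
        out, _ = reorient(rotated, p)
        pts = out.positions[p]
        assert np.ptp(pts[:, 0]) >= np.ptp(pts[:, 1])


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        f = Frame(["A", "B"], ["C", "C"], ["UNK"] * 2, [1, 2], ["A"] * 2,
                  [[0, 0, 0], [2.0, 0, 0]], [1.0, 1.0])
        assert radius_of_gyration(f, [0, 1]) == pytest.approx(1.0)

    def test_thin_uniform_disc(self):
        # hex-grid discretization of a uniform disc of radius R: Rg = R/sqrt(2)
        R = 5.0
        xs = np.arange(-R, R, 0.05)
        X, Y = np.meshgrid(xs, xs)
        pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        pts = pts[np.linalg.norm(pts[:, :2], axis=1) <= R]
        n = len(pts)
        f = Frame(["C"] * n, ["C"] * n, ["UNK"] * n, np.arange(n) + 1,
                  ["A"] * n, pts, np.ones(n))
        assert radius_of_gyration(f, np.arange(n)) == pytest.approx(
            R / np.sqrt(2), rel=0.02)

    def test_rigid_invariance(self, random_frame):
        f = random_frame(n=50, seed=8)
        sel = np.arange(50)
        rg = radius_of_gyration(f, sel)
        R = rotation_about([1, 1, 0], 0.9)
        g = f.with_positions(f.positions @ R.T + np.array([3, 4, 5.0]))
        assert radius_of_gyration(g, sel) == pytest.approx(rg, rel=1e-12)

    def test_empty_selection_rejected(self, random_frame):
        with pytest.raises(ValueError):
            radius_of_gyration(random_frame(), [])


class TestKabsch:
    def test_rigid_copy_zero_rmsd(self, random_frame):
        f = random_frame(n=30, seed=1)
        R = rotation_about([0.3, -1, 2], 2.2)
        g = f.with_positions(f.positions @ R.T + np.array([1, 2, 3.0]))
        _, rmsd = kabsch_superpose(f, g, np.arange(30))
        assert rmsd < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_quaternion_oracle(self, random_frame, seed):
        rng = np.random.default_rng(seed)
        f = random_frame(n=25, seed=seed)
        g = f.with_positions(f.positions + rng.normal(0, 0.3, (25, 3)))
        _, rmsd = kabsch_superpose(f, g, np.arange(25))
        oracle = quaternion_rmsd(g.positions, f.positions)
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_rmsd_not_above_unsuperposed(self, random_frame):
        rng = np.random.default_rng(9)
        f = random_frame(n=40, seed=9)
        g = f.with_positions(f.positions @ rotation_about([1, 0, 0], 0.4).T
                             + rng.normal(0, 0.1, (40, 3)))
        _, rmsd = kabsch_superpose(f, g, np.arange(40))
        raw = np.sqrt(np.mean(np.sum((f.positions - g.positions) ** 2, axis=1)))
        assert rmsd <= raw + 1e-12

    def test_reflection_never_returned(self, random_frame):
        f = random_frame(n=20, seed=2)
        mirrored = f.with_positions(f.positions * np.array([-1.0, 1.0, 1.0]))
        tf, rmsd = kabsch_superpose(f, mirrored, np.arange(20))
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_atoms_rejected(self, random_frame):
        f = random_frame(n=10)
        with pytest.raises(ValueError):
            kabsch_superpose(f, f, [0, 1])


class TestRmsdSeries:
    def test_identical_frames_zero(self, random_frame):
        f = random_frame(n=30, seed=3)
        traj = Trajectory([f.copy() for _ in range(4)])
        series = backbone_rmsd_series(traj, f, np.arange(30))
        assert series.mean == pytest.approx(0.0, abs=1e-12)
        assert series.sd == pytest.approx(0.0, abs=1e-12)

    def test_noise_rmsd_magnitude(self, disc_noise_free):
        traj = disc_noise_free[1]
        jittered = perturb_frames(traj, 0.05, 50, seed=3)
        f0 = traj.frames[0]
        backbone = select_atoms(f0, chain=("A", "B", "C", "D"),
                                atom_name=("N", "CA", "C", "O"))
        series = backbone_rmsd_series(jittered, f0, backbone)
        # independent per-atom jitter: rmsd ~ sigma*sqrt(3), minus the
        # 6 fitted rigid-body degrees of freedom (negligible at this N)
        assert series.mean == pytest.approx(0.05 * np.sqrt(3), rel=0.1)

    def test_formatted_like_published_tables(self, random_frame):
        f = random_frame(n=30, seed=3)
        traj = Trajectory([f.copy() for _ in range(3)])
        series = backbone_rmsd_series(traj, f, np.arange(30))
        assert str(series) == "0.00 ± 0.00"


class TestEscapedLipids:
    def test_intact_disc_empty(self, disc):
        assert detect_escaped_lipids(disc[1].frames[0]) == []

    def test_single_displaced_lipid(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        pos = f.positions.copy()
        mask = (f.resids == 5) & (f.resnames == "DMPC")
        pos[mask] += np.array([10.0, 0, 0])
        assert detect_escaped_lipids(f.with_positions(pos)) == [5]

    def test_pair_displaced_together(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        pos = f.positions.copy()
        for rid in (3, 4):
            pos[(f.resids == rid) & (f.resnames == "DMPC")] += \
                np.array([0, 12.0, 0])
        assert detect_escaped_lipids(f.with_positions(pos)) == [3, 4]

    def test_matches_brute_force_single_linkage(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        pos = f.positions.copy()
        rng = np.random.default_rng(5)
        moved = rng.choice(np.unique(f.resids[f.resnames == "DMPC"]), 6,
                           replace=False)
        for k, rid in enumerate(moved):
            pos[(f.resids == rid) & (f.resnames == "DMPC")] += \
                np.array([15.0 + 5 * k, 0, 0])
        g = f.with_positions(pos)
        result = set(detect_escaped_lipids(g, max_gap=1.0))

        # brute force: iterative merge on representative-atom min distances
        lip = select_atoms(g, residue_name="DMPC")
        rep = lip[np.isin(g.names[lip], ("P", "C214", "C314"))]
        rids = sorted(set(g.resids[rep].tolist()))
        clusters = [{r} for r in rids]
        pts = {r: g.positions[rep[g.resids[rep] == r]] for r in rids}

        def dmin(ca, cb):
            return min(np.sqrt(((pts[a][:, None] - pts[b][None]) ** 2)
                               .sum(-1)).min() for a in ca for b in cb)

        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if dmin(clusters[i], clusters[j]) <= 1.0:
                        clusters[i] |= clusters.pop(j)
                        merged = True
                        break
                if merged:
                    break
        largest = max(clusters, key=len)
        expected = set().union(*(c for c in clusters if c is not largest))
        assert result == expected


def test_rigid_transform_validates_rotation():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
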