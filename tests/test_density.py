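import numpy as np
import pytest

from discbelt.density import (
    DensityProfile, mass_density_profile, symmetrize_profile,
    bilayer_thickness, diameter_from_protein, diameter_from_lipid,
    average_diameter, linear_trend, AMU_PER_NM3_TO_KG_PER_M3,
)
from discbelt.structure_io import Frame, Trajectory, select_atoms, subset_mass
from discbelt.synthetic import DiscSpec, generate_nanodisc


def slab_frame(n=1000, z_lo=-1.0, z_hi=1.0, seed=0, mass=10.0):
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.uniform(0, 2, n), rng.uniform(0, 2, n),
                           rng.uniform(z_lo, z_hi, n)])
    return Frame([f"C{i % 9}" for i in range(n)], ["C"] * n, ["UNK"] * n,
                 np.arange(n) + 1, ["A"] * n, pos, [mass] * n)


class TestMassDensityProfile:
    def test_total_mass_recovered(self, disc):
        _, traj, _ = disc
        f = traj.frames[0]
        sel = select_atoms(f, residue_name="DMPC")
        prof = mass_density_profile(traj, sel, "z")
        assert prof.total_mass_amu() == pytest.approx(
            subset_mass(f, sel), rel=1e-9)

    def test_uniform_slab_interior_density(self):
        f = slab_frame(n=20000, seed=1)
        sel = np.arange(f.n_atoms)
        prof = mass_density_profile(
            f, sel, "z", extent=(-1.0, 1.0), cross_section_nm2=4.0)
        expected = 20000 * 10.0 / (2.0 * 4.0) * AMU_PER_NM3_TO_KG_PER_M3
        interior = prof.density[10:-10]
        assert interior.mean() == pytest.approx(expected, rel=0.02)

    def test_two_frame_average(self):
        f1 = slab_frame(n=500, seed=2)
        f2 = f1.with_positions(f1.positions + np.array([0, 0, 0.5]))
        sel = np.arange(f1.n_atoms)
        kw = dict(extent=(-2.0, 3.0), cross_section_nm2=4.0)
        p1 = mass_density_profile(f1, sel, "z", **kw)
        p2 = mass_density_profile(f2, sel, "z", **kw)
        p12 = mass_density_profile(Trajectory([f1, f2]), sel, "z", **kw)
        np.testing.assert_allclose(p12.density, (p1.density + p2.density) / 2,
                                   rtol=1e-12)

    def test_empty_selection_rejected(self, disc):
        with pytest.raises(ValueError):
            mass_density_profile(disc[1], np.array([], dtype=int), "z")


class TestSymmetrize:
    def make(self, density):
        density = np.asarray(density, float)
        edges = np.linspace(0, len(density), len(density) + 1)
        return DensityProfile("z", edges, density, cross_section_nm2=1.0)

    def test_symmetric_fixed_point(self):
        prof = self.make([0, 1, 2, 3, 2, 1, 0])
        out = symmetrize_profile(prof, 3.5)
        np.testing.assert_allclose(out.density, prof.density)

    def test_two_spike_profile_equalized(self):
        prof = self.make([0, 4, 0, 0, 0, 2, 0])
        out = symmetrize_profile(prof, 3.5)
        assert out.density[1] == out.density[5] == 3.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        prof = self.make(rng.uniform(0, 5, 100))
        once = symmetrize_profile(prof, 47.0)
        twice = symmetrize_profile(once, 47.0)
        np.testing.assert_allclose(twice.density, once.density)

    def test_center_outside_extent_rejected(self):
        with pytest.raises(ValueError):
            symmetrize_profile(self.make([1, 2, 3]), 99.0)


class TestBilayerThickness:
    def test_synthetic_planes(self, disc):
        _, traj, gt = disc
        f0 = traj.frames[0]
        p = select_atoms(f0, atom_name="P", residue_name="DMPC")
        prof = mass_density_profile(traj, p, "z")
        assert bilayer_thickness(prof) == pytest.approx(
            gt.thickness, abs=prof.bin_width / 2)

    def test_noisy_planes_with_many_frames(self):
        spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=200,
                        noise_sigma=0.1, seed=7)
        traj, gt = generate_nanodisc(spec)
        f0 = traj.frames[0]
        p = select_atoms(f0, atom_name="P", residue_name="DMPC")
        prof = mass_density_profile(traj, p, "z")
        assert bilayer_thickness(prof) == pytest.approx(3.4, abs=0.1)

    def test_monolayer_rejected(self):
        n = 400
        rng = np.random.default_rng(3)
        pos = np.column_stack([rng.uniform(-3, 3, n), rng.uniform(-3, 3, n),
                               rng.normal(0, 0.05, n)])
        f = Frame(["P"] * n, ["P"] * n, ["DMPC"] * n, np.arange(n) + 1,
                  ["L"] * n, pos, [30.97] * n)
        prof = mass_density_profile(f, np.arange(n), "z")
        with pytest.raises(ValueError, match="bilayer"):
            bilayer_thickness(prof)


class TestDiameters:
    def ring_profile(self, R, n_bins=100, extra_bump=False):
        # two belt rings projected on x: density peaks at +-R
        theta = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        xs = R * np.cos(theta)
        if extra_bump:
            xs = np.concatenate([xs, np.random.default_rng(0).normal(0, 0.5, 500)])
        n = len(xs)
        pos = np.column_stack([xs, np.zeros(n), np.zeros(n)])
        f = Frame(["CA"] * n, ["C"] * n, ["ALA"] * n, np.arange(n) + 1,
                  ["A"] * n, pos, [12.0] * n)
        return mass_density_profile(f, np.arange(n), "x", n_bins=n_bins,
                                    extent=(-R - 1, R + 1),
                                    cross_section_nm2=1.0)

    def test_protein_diameter_ring(self):
        prof = self.ring_profile(5.0)
        assert diameter_from_protein(prof) == pytest.approx(
            10.0, abs=prof.bin_width)

    def test_outermost_maxima_chosen_despite_bumps(self):
        prof = self.ring_profile(5.0, extra_bump=True)
        assert diameter_from_protein(prof) == pytest.approx(
            10.0, abs=prof.bin_width)

    def test_flat_profile_rejected(self):
        edges = np.linspace(-1, 1, 101)
        prof = DensityProfile("x", edges, np.ones(100), cross_section_nm2=1.0)
        with pytest.raises(ValueError):
            diameter_from_protein(prof)

    def test_lipid_threshold_diameter(self, disc):
        _, traj, gt = disc
        sel = select_atoms(traj.frames[0], residue_name="DMPC")
        prof = mass_density_profile(traj, sel, "x")
        d = diameter_from_lipid(prof)
        assert d == pytest.approx(2 * gt.outer_radius,
                                  abs=prof.bin_width + 3 * 0.05)

    def test_threshold_above_max_rejected(self, disc):
        sel = select_atoms(disc[1].frames[0], residue_name="DMPC")
        prof = mass_density_profile(disc[1], sel, "x")
        with pytest.raises(ValueError):
            diameter_from_lipid(prof, threshold=1e9)

    def test_interpolated_crossing_vs_dense_binning(self):
        # smooth-edged analytic profile: linear interpolation of the 1 kg/m^3
        # crossing at 100 bins agrees with a 1000-bin near-oracle
        def profile(n_bins):
            edges = np.linspace(-8, 8, n_bins + 1)
            x = 0.5 * (edges[:-1] + edges[1:])
            density = 800.0 * np.exp(-((np.abs(x) / 4.5) ** 6))
            return DensityProfile("x", edges, density, cross_section_nm2=1.0)

        coarse = diameter_from_lipid(profile(100))
        fine = diameter_from_lipid(profile(1000))
        assert coarse == pytest.approx(fine, abs=0.05)

    def test_average_diameter(self):
        est = average_diameter(16.0, 14.0, method="protein_maxima")
        assert est.mean == 15.0
        assert est.major == 16.0 and est.minor == 14.0
        with pytest.raises(ValueError):
            average_diameter(-1.0, 5.0)

    def test_circular_disc_nearly_isotropic(self, disc):
        _, traj, _ = disc
        sel = select_atoms(traj.frames[0], residue_name="DMPC")
        dx = diameter_from_lipid(mass_density_profile(traj, sel, "x"))
        dy = diameter_from_lipid(mass_density_profile(traj, sel, "y"))
        assert dx == pytest.approx(dy, rel=0.05)

    def test_protein_method_exceeds_lipid_method(self, disc):
        _, traj, _ = disc
        f0 = traj.frames[0]
        lip = select_atoms(f0, residue_name="DMPC")
        prot = select_atoms(f0, residue_name="ALA")
        d_prot = diameter_from_protein(mass_density_profile(traj, prot, "x"))
        d_lip = diameter_from_lipid(mass_density_profile(traj, lip, "x"))
        assert d_prot > d_lip


class TestLinearTrend:
    def test_exact_line(self):
        n = [240, 320, 400]
        y = [2 * v + 1 for v in n]
        slope, intercept, r2 = linear_trend(n, y)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_trend([5, 5, 5], [1, 2, 3])

    def test_diameter_grows_with_lipid_count(self):
        sizes = [60, 100, 140]
        diams = []
        for n in sizes:
            traj, gt = generate_nanodisc(
                DiscSpec(n_lipids_per_leaflet=n, n_frames=2, seed=21))
            sel = select_atoms(traj.frames[0], residue_name="DMPC")
            diams.append(diameter_from_lipid(
                mass_density_profile(traj, sel, "x")))
        slope, _, _ = linear_trend([2 * n for n in sizes], diams)
        assert slope > 0
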