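import numpy as np
import pytest

from discbelt.order import (
    OrderParameterProfile, find_ch_bonds, scd_profile, partition_regions,
    delta_scd,
)
from discbelt.structure_io import Frame, select_atoms
from discbelt.synthetic import (
    DiscSpec, generate_nanodisc, generate_bilayer_patch, TAIL_CARBON_INDICES,
)


def bond_frame(directions, carbon_name="C22", h_name="H2R"):
    """One tail carbon + hydrogen per residue with given C->H directions."""
    rows = []
    for i, d in enumerate(directions):
        base = np.array([i * 1.0, 0.0, 0.0])
        rows.append((carbon_name, "C", i + 1, base))
        rows.append((h_name, "H", i + 1, base + 0.109 * np.asarray(d)))
    return Frame([r[0] for r in rows], [r[1] for r in rows],
                 ["DMPC"] * len(rows), [r[2] for r in rows],
                 ["L"] * len(rows), np.array([r[3] for r in rows]),
                 [12.0] * len(rows))


class TestScdAnalyticFixtures:
    def test_perpendicular_bonds_give_half(self):
        f = bond_frame([[1, 0, 0], [0, 1, 0],
                        [np.cos(1.1), np.sin(1.1), 0]])
        prof = scd_profile(f, np.arange(f.n_atoms))
        assert prof.abs_scd[0] == pytest.approx(0.5, abs=1e-12)

    def test_magic_angle_gives_zero(self):
        c = np.sqrt(1.0 / 3.0)  # cos^2 = 1/3
        s = np.sqrt(2.0 / 3.0)
        f = bond_frame([[s, 0, c], [0, s, c], [-s, 0, c]])
        prof = scd_profile(f, np.arange(f.n_atoms))
        assert prof.abs_scd[0] == pytest.approx(0.0, abs=1e-6)

    def test_parallel_bonds_give_one(self):
        f = bond_frame([[0, 0, 1], [0, 0, -1]])
        prof = scd_profile(f, np.arange(f.n_atoms))
        assert prof.abs_scd[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_monte_carlo_near_zero(self):
        rng = np.random.default_rng(123)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        f = bond_frame(v)
        prof = scd_profile(f, np.arange(f.n_atoms))
        assert prof.abs_scd[0] == pytest.approx(0.0, abs=0.01)


class TestScdOnSyntheticLipids:
    def test_matches_construction_to_1e10(self):
        spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=1,
                        noise_sigma=0.0, tail_tilt=("fixed_angle", 0.3),
                        seed=9)
        traj, gt = generate_nanodisc(spec)
        f = traj.frames[0]
        prof = scd_profile(f, select_atoms(f, residue_name="DMPC"))
        assert list(prof.carbon_index) == list(TAIL_CARBON_INDICES)
        for k, s in zip(prof.carbon_index, prof.abs_scd):
            assert s == pytest.approx(gt.expected_abs_scd[int(k)], abs=1e-10)

    def test_tail_naming_finds_both_chains(self, disc_noise_free):
        f = disc_noise_free[1].frames[0]
        sel = select_atoms(f, residue_name="DMPC")
        bonds = find_ch_bonds(f, sel)
        n_lip = disc_noise_free[2].n_lipids
        # per lipid: 12 methylenes x 2 H + terminal methyl x 3 H, both tails
        assert len(bonds) == n_lip * 2 * (12 * 2 + 3)

    def test_united_atom_input_rejected(self):
        f = bond_frame([[0, 0, 1]])
        mask = f.elements != "H"
        g = Frame(f.names[mask], f.elements[mask], f.resnames[mask],
                  f.resids[mask], f.chains[mask], f.positions[mask],
                  f.masses[mask])
        with pytest.raises(ValueError, match="hydrogens"):
            find_ch_bonds(g, np.arange(g.n_atoms))

    def test_pure_bilayer_more_ordered_than_disordered_disc(self):
        patch, _ = generate_bilayer_patch(
            n_per_leaflet=49, tail_tilt=("fixed_angle", 0.1),
            noise_sigma=0.0, n_frames=1, seed=3)
        spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=1, noise_sigma=0.0,
                        tail_tilt=("fixed_angle", 0.1),
                        rim_extra_tilt_sigma=0.35, seed=3)
        disc, _ = generate_nanodisc(spec)
        fp, fd = patch.frames[0], disc.frames[0]
        sp = scd_profile(fp, select_atoms(fp, residue_name="DMPC"))
        sd = scd_profile(fd, select_atoms(fd, residue_name="DMPC"))
        assert np.all(sp.abs_scd >= sd.abs_scd)


@pytest.fixture(scope="module")
def parts():
    spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=1,
                    noise_sigma=0.0, seed=10)
    traj, gt = generate_nanodisc(spec)
    f = traj.frames[0]
    lip = select_atoms(f, residue_name="DMPC")
    prot = select_atoms(f, residue_name="ALA")
    return f, lip, prot, partition_regions(f, lip, prot), gt


class TestRegions:

    def test_center_lipid_in_core(self, parts):
        f, lip, _, part, _ = parts
        # lipid 1 sits on the innermost hex site by construction
        assert 1 in part.core

    def test_subsets_of_full(self, parts):
        _, _, _, part, gt = parts
        assert part.core <= part.full and part.rim <= part.full
        assert len(part.full) == gt.n_lipids

    def test_rim_lipids_near_belt(self, parts):
        f, lip, prot, part, gt = parts
        assert part.rim  # outermost ring of lipids is within 1.4 nm of belt
        sub = f.positions[lip]
        for rid in sorted(part.rim)[:5]:
            centroid = sub[f.resids[lip] == rid].mean(axis=0)
            d = np.linalg.norm(f.positions[prot] - centroid, axis=1).min()
            assert d <= 1.4 + 1e-9

    def test_matches_brute_force_scan(self, parts):
        f, lip, prot, part, _ = parts
        resids = f.resids[lip]
        masses = f.masses[lip]
        com = masses @ f.positions[lip] / masses.sum()
        core, rim = set(), set()
        for rid in np.unique(resids):
            centroid = f.positions[lip][resids == rid].mean(axis=0)
            if np.linalg.norm(centroid[:2] - com[:2]) <= 3.0:
                core.add(int(rid))
            if np.linalg.norm(f.positions[prot] - centroid,
                              axis=1).min() <= 1.4:
                rim.add(int(rid))
        assert part.core == frozenset(core)
        assert part.rim == frozenset(rim)

    def test_core_more_ordered_than_rim_with_rim_disorder(self):
        spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=2,
                        noise_sigma=0.02, tail_tilt=("fixed_angle", 0.05),
                        rim_extra_tilt_sigma=0.4, seed=13)
        traj, _ = generate_nanodisc(spec)
        f0 = traj.frames[0]
        lip = select_atoms(f0, residue_name="DMPC")
        prot = select_atoms(f0, residue_name="ALA")
        parts = [partition_regions(f, lip, prot) for f in traj.frames]
        core = scd_profile(traj, lip, "core", [p.core for p in parts])
        rim = scd_profile(traj, lip, "rim", [p.rim for p in parts])
        assert np.all(core.abs_scd >= rim.abs_scd)


class TestDeltaScd:
    def make(self, values, region="full"):
        return OrderParameterProfile(np.array(TAIL_CARBON_INDICES),
                                     np.asarray(values, float), region, 100)

    def test_identical_profiles_zero(self):
        p = self.make([0.2] * 13)
        np.testing.assert_allclose(delta_scd(p, p), 0.0)

    def test_constant_offset(self):
        a = self.make([0.25] * 13)
        b = self.make([0.20] * 13)
        np.testing.assert_allclose(delta_scd(a, b), 0.05)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = self.make(rng.uniform(0, 0.5, 13))
        b = self.make(rng.uniform(0, 0.5, 13))
        np.testing.assert_allclose(delta_scd(a, b), -delta_scd(b, a))

    def test_index_mismatch_rejected(self):
        a = self.make([0.2] * 13)
        b = OrderParameterProfile(np.arange(3, 16), np.full(13, 0.2),
                                  "full", 10)
        with pytest.raises(ValueError):
            delta_scd(a, b)

    def test_region_mismatch_rejected(self):
        a = self.make([0.2] * 13)
        b = self.make([0.2] * 13, region="core")
        with pytest.raises(ValueError):
            delta_scd(a, b)
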