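import numpy as np
import pytest

from discbelt import DiscSpec, generate_nanodisc, make_synthetic_helix_bundle
from discbelt.structure_io import Frame


@pytest.fixture(scope="session")
def disc():
    """Noisy nanodisc at realistic proportions (100 lipids/leaflet)."""
    spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=10, noise_sigma=0.05,
                    seed=11)
    traj, gt = generate_nanodisc(spec)
    return spec, traj, gt


@pytest.fixture(scope="session")
def disc_noise_free():
    spec = DiscSpec(n_lipids_per_leaflet=100, n_frames=1, noise_sigma=0.0,
                    seed=12)
    traj, gt = generate_nanodisc(spec)
    return spec, traj, gt


@pytest.fixture(scope="session")
def bundle():
    return make_synthetic_helix_bundle()


@pytest.fixture()
def random_frame():
    """Factory for random carbon-atom frames."""

    def make(n=100, seed=0, chains=None, sigma=1.0):
        rng = np.random.default_rng(seed)
        if chains is None:
            chains = ["A"] * n
        return Frame(
            names=[f"C{i % 9 + 1}" for i in range(n)],
            elements=["C"] * n,
            resnames=["UNK"] * n,
            resids=[i // 5 + 1 for i in range(n)],
            chains=chains,
            positions=rng.normal(0.0, sigma, size=(n, 3)),
            masses=[12.0107] * n,
        )

    return make


def single_atom_frame(element="C", radius_name="X", mass=12.0):
    return Frame([radius_name], [element], ["UNK"], [1], ["A"],
                 [[0.0, 0.0, 0.0]], [mass])


def protein_pair_frame(offset_nm: float, res_j=("GLU",)):
    """Two residues on chains A and C whose nearest side-chain atoms sit
    ``offset_nm`` apart along x (ARG guanidinium vs acidic carboxylate)."""
    rows = []

    def add(chain, resid, resname, names, elements, origin):
        for i, (n, e) in enumerate(zip(names, elements)):
            rows.append((n, e, resname, resid, chain,
                         np.array(origin) + np.array([0.0, 0.05 * i, 0.0])))

    add("A", 1, "ARG",
        ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
        ["N", "C", "C", "O", "C", "C", "C", "N", "C", "N", "N"], [0, 0, 0])
    add("C", 1, res_j[0],
        ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
        ["N", "C", "C", "O", "C", "C", "C", "O", "O"], [offset_nm, 0, 0])
    return Frame([r[0] for r in rows], [r[1] for r in rows],
                 [r[2] for r in rows], [r[3] for r in rows],
                 [r[4] for r in rows], np.array([r[5] for r in rows]),
                 [12.0] * len(rows))
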