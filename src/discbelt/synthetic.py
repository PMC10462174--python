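"""Synthetic nanodisc and bilayer-patch trajectories with known ground truth.

Real scaffold-protein/DMPC nanodisc trajectories come from microsecond MD
runs; none are needed here.  This module builds idealized discoidal
assemblies whose every geometric property (radius, phosphate-plane
separation, acyl-tail orientation statistics, belt radius) is set by
construction, so each analysis stage can be validated against closed forms.

The lipid surrogate is an explicit-hydrogen DMPC (C36H72NO8P, 118 atoms)
with CHARMM36-style atom names (P; Sn2 tail C22..C214 with H2R/H2S..;
Sn1 tail C32..C314 with H2X/H2Y..), so selection and order-parameter code
runs unchanged on real all-atom membrane output.  Head-group geometry is
schematic; only the phosphorus position, the tail carbon/hydrogen geometry
and the atomic masses are meaningful.

Tail C-H bonds are built perpendicular to the tail axis at azimuths chosen
so that, for a tail tilted by theta from the disc normal, the exact
per-carbon order parameter is S = (3 sin^2(theta)/2 - 1)/2 independently of
the azimuth draw.  GroundTruth carries that closed-form expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .structure_io import Frame, Trajectory, SystemLabel, STANDARD_ATOMIC_MASSES

__all__ = [
    "BeltSpec",
    "DiscSpec",
    "GroundTruth",
    "generate_nanodisc",
    "generate_bilayer_patch",
    "perturb_frames",
    "TAIL_CARBON_INDICES",
]

_CC_BOND_NM = 0.127      # projected C-C spacing along an extended acyl tail
_CH_BOND_NM = 0.109
_HELIX_RISE_NM = 0.15    # alpha-helix rise per residue
_HELIX_RADIUS_NM = 0.23  # C-alpha helix radius
_HELIX_TURN_DEG = 100.0

#: Tail carbon positions present in a myristoyl (14:0) chain surrogate:
#: carbons 2..14; carbon 1 is the ester carbonyl and carries no hydrogens.
TAIL_CARBON_INDICES = tuple(range(2, 15))


@dataclass(frozen=True)
class BeltSpec:
    """Geometry of the four-chain double belt around the lipid disc."""

    n_chains: int = 4
    ring_radius_offset: float = 1.0       # nm added to the lipid disc radius
    inter_ring_separation: float = 3.0    # nm between the two ring planes
    mode: str = "antiparallel"            # N->C angular sense of lower ring

    def __post_init__(self):
        if self.n_chains != 4:
            raise ValueError("the double-belt model uses exactly 4 chains")
        if self.mode not in ("parallel", "antiparallel"):
            raise ValueError(f"mode must be parallel/antiparallel, got {self.mode!r}")


@dataclass(frozen=True)
class DiscSpec:
    """Parameters of a synthetic nanodisc trajectory.

    Defaults emulate the all-atom study conditions: 0.60 nm^2 per DMPC,
    3.4 nm phosphate peak-to-peak thickness, 200 analysis snapshots, and a
    thermal positional jitter of 0.05 nm.
    """

    n_lipids_per_leaflet: int = 120
    area_per_lipid: float = 0.60              # nm^2
    phosphate_plane_separation: float = 3.4   # nm
    #: ("fixed_angle", theta0_rad) | ("isotropic",) | ("gaussian", mu, sigma)
    tail_tilt: tuple = ("fixed_angle", 0.0)
    belt: BeltSpec = field(default_factory=BeltSpec)
    noise_sigma: float = 0.05                 # nm, per-frame Gaussian jitter
    n_frames: int = 200
    seed: int = 0
    #: extra Gaussian tilt (rad) applied to lipids in the outer rim band,
    #: emulating belt-induced disorder at the disc edge
    rim_extra_tilt_sigma: float = 0.0
    rim_band_nm: float = 1.4

    def __post_init__(self):
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("n_lipids_per_leaflet must be >= 1")
        if self.phosphate_plane_separation <= 0:
            raise ValueError("phosphate_plane_separation must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def disc_radius(self) -> float:
        """Lipid disc radius from the area budget: sqrt(n*APL/pi), nm."""
        return float(np.sqrt(self.n_lipids_per_leaflet * self.area_per_lipid / np.pi))

    @property
    def label(self) -> SystemLabel:
        return SystemLabel(2 * self.n_lipids_per_leaflet, self.belt.mode)


@dataclass
class GroundTruth:
    """Construction parameters a generated trajectory is guaranteed to obey."""

    disc_radius: float            # nm, packing radius sqrt(n*APL/pi); 0 for patches
    thickness: float              # nm, phosphate plane separation
    expected_abs_scd: dict        # carbon index -> |S_CD| of the construction
    belt_radius: float | None     # nm; None for bilayer patches
    label: str | None
    seed: int
    n_lipids: int
    #: physical lipid-atom envelope radius (nm) of the noise-free build:
    #: what a density-threshold diameter measures (atoms overhang the
    #: packing sites by the head-group lateral extent)
    outer_radius: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Lipid template
# ---------------------------------------------------------------------------

def _head_template() -> list[tuple[str, str, np.ndarray]]:
    """Schematic head-group atoms (name, element, offset from P in nm).

    Offsets are in the lipid's local frame with +z pointing away from the
    bilayer midplane.  Chemically plausible spacing, not a refined geometry.
    """
    a = []

    def add(name, element, x, y, z):
        a.append((name, element, np.array([x, y, z])))

    # choline, stacked above the phosphate
    add("N", "N", 0.00, 0.05, 0.45)
    for i, (nm, dx) in enumerate((("C13", -0.12), ("C14", 0.12), ("C15", 0.0))):
        add(nm, "C", dx, 0.12, 0.55)
        for j, h in enumerate("ABC"):
            add(f"H{nm[1:]}{h}", "H", dx + 0.05 * (j - 1), 0.20, 0.60)
    add("C12", "C", 0.00, 0.00, 0.35)
    add("H12A", "H", 0.08, 0.05, 0.37)
    add("H12B", "H", -0.08, 0.05, 0.37)
    add("C11", "C", 0.00, -0.05, 0.22)
    add("H11A", "H", 0.08, -0.10, 0.24)
    add("H11B", "H", -0.08, -0.10, 0.24)
    add("O12", "O", 0.00, -0.08, 0.10)
    # phosphate
    add("P", "P", 0.0, 0.0, 0.0)
    add("O13", "O", 0.10, 0.08, 0.02)
    add("O14", "O", -0.10, 0.08, 0.02)
    add("O11", "O", 0.00, -0.05, -0.12)
    # glycerol
    add("C1", "C", 0.00, 0.00, -0.22)
    add("HA", "H", 0.08, 0.04, -0.22)
    add("HB", "H", -0.08, 0.04, -0.22)
    add("C2", "C", 0.05, 0.00, -0.32)
    add("HS", "H", 0.13, 0.04, -0.32)
    add("C3", "C", -0.05, 0.00, -0.32)
    add("HX", "H", -0.13, 0.04, -0.30)
    add("HY", "H", -0.13, -0.04, -0.34)
    # esters feeding the two tails (Sn2 on C2, Sn1 on C3)
    add("O21", "O", 0.09, 0.00, -0.40)
    add("C21", "C", 0.09, 0.00, -0.50)
    add("O22", "O", 0.17, 0.00, -0.54)
    add("O31", "O", -0.09, 0.00, -0.40)
    add("C31", "C", -0.09, 0.00, -0.50)
    add("O32", "O", -0.17, 0.00, -0.54)
    return a


_HEAD = _head_template()
# formula audit happens in tests: head + 2 tails must sum to C36H72NO8P


def _tail_atoms(sn: int, origin: np.ndarray, direction: np.ndarray,
                e1: np.ndarray, e2: np.ndarray, phi: float):
    """Atoms of one 14-carbon tail along ``direction`` (unit vector).

    C-H bonds are perpendicular to the tail axis; the two methylene H sit at
    azimuths phi and phi+90 deg, the three terminal-methyl H at 120 deg
    spacing, so each carbon's azimuth-averaged cos^2 to any fixed lab axis
    depends on the tilt alone.
    """
    suffix = {2: ("R", "S", "T"), 3: ("X", "Y", "Z")}[sn]
    atoms = []
    for k in TAIL_CARBON_INDICES:
        c_pos = origin + (k - 2) * _CC_BOND_NM * direction
        atoms.append((f"C{sn}{k}", "C", c_pos))
        angles = (phi, phi + np.pi / 2)
        if k == 14:
            angles = (phi, phi + 2 * np.pi / 3, phi + 4 * np.pi / 3)
        for ang, tag in zip(angles, suffix):
            u = np.cos(ang) * e1 + np.sin(ang) * e2
            atoms.append((f"H{k}{tag}", "H", c_pos + _CH_BOND_NM * u))
    return atoms


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal pair spanning the plane perpendicular to unit vector d,
    with e1 chosen in the plane containing d and z (so e2 has zero z)."""
    z = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(z, d)
    n = np.linalg.norm(e2)
    if n < 1e-12:                      # d parallel to z: any in-plane pair
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    e2 = e2 / n
    e1 = np.cross(e2, d)
    return e1, e2


def _build_lipid(site_xy: np.ndarray, leaflet: int, sep: float,
                 theta: float, alpha: float, phi: float):
    """Full atom list for one lipid.

    leaflet: +1 (upper, head at +sep/2) or -1 (lower).
    theta: tail tilt from the disc normal; alpha: tilt azimuth;
    phi: C-H azimuth about the tail axis.
    """
    s = float(leaflet)
    p_pos = np.array([site_xy[0], site_xy[1], s * sep / 2.0])
    atoms = []
    for name, element, off in _HEAD:
        atoms.append((name, element, p_pos + off * np.array([1.0, 1.0, s])))
    # tail direction: tilted away from the inward normal (-s z) by theta
    d = np.array([np.sin(theta) * np.cos(alpha),
                  np.sin(theta) * np.sin(alpha),
                  -s * np.cos(theta)])
    e1, e2 = _perp_basis(d)
    lat = np.cross(d, np.array([0.0, 0.0, 1.0]))
    lat = (lat / np.linalg.norm(lat)) if np.linalg.norm(lat) > 1e-12 else np.array([1.0, 0.0, 0.0])
    tail_origin = p_pos + np.array([0.0, 0.0, -s * 0.62])
    atoms += _tail_atoms(2, tail_origin + 0.045 * lat, d, e1, e2, phi)
    atoms += _tail_atoms(3, tail_origin - 0.045 * lat, d, e1, e2, phi + np.pi / 3)
    return atoms


def expected_abs_scd_from_tilt(thetas: np.ndarray) -> float:
    """|S_CD| implied by the construction for tails tilted by ``thetas``.

    For C-H bonds perpendicular to a tail tilted by theta, placed at
    azimuths averaging cos^2 to 1/2, <cos^2(theta_CH)> = sin^2(theta)/2 and
    hence S = (3 sin^2(theta)/2 - 1)/2 per carbon.
    """
    sin2 = np.sin(np.asarray(thetas)) ** 2
    return abs(float(np.mean((1.5 * sin2 - 1.0) / 2.0)))


def _sample_tilts(rng: np.random.Generator, n: int, tail_tilt: tuple) -> np.ndarray:
    kind = tail_tilt[0]
    if kind == "fixed_angle":
        return np.full(n, float(tail_tilt[1]))
    if kind == "gaussian":
        _, mu, sigma = tail_tilt
        return np.abs(rng.normal(mu, sigma, size=n))
    if kind == "isotropic":
        # uniform over the hemisphere: cos(theta) ~ U(0,1)
        return np.arccos(rng.uniform(0.0, 1.0, size=n))
    raise ValueError(f"unknown tail_tilt kind {kind!r}")


def _hex_sites(n: int, area_per_lipid: float) -> np.ndarray:
    """n hexagonal-lattice sites closest to the origin at the density 1/APL."""
    a = np.sqrt(2.0 * area_per_lipid / np.sqrt(3.0))
    m = int(np.ceil(np.sqrt(n))) + 3
    ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    x = (ii + 0.5 * (jj % 2)) * a
    y = jj * a * np.sqrt(3.0) / 2.0
    pts = np.column_stack([x.ravel(), y.ravel()])
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    return pts[order[:n]]


# ---------------------------------------------------------------------------
# Belt chains
# ---------------------------------------------------------------------------

_BB_OFFSETS = {  # local backbone offsets from C-alpha, nm (schematic)
    "N": np.array([-0.10, 0.05, 0.00]),
    "C": np.array([0.10, 0.05, 0.00]),
    "O": np.array([0.14, 0.14, 0.02]),
    "CB": np.array([0.00, -0.12, 0.08]),
}


def _belt_chain(ring_radius: float, z0: float, theta0: float, theta1: float,
                n_res: int, sense: int):
    """One poly-alanine helical chain wound along the ring arc.

    ``sense`` +1/-1 sets the N->C angular direction.  Returns
    (names, elements, resids, positions).
    """
    names, elements, resids, pos = [], [], [], []
    thetas = theta0 + sense * np.linspace(0.0, abs(theta1 - theta0), n_res)
    psi = np.deg2rad(_HELIX_TURN_DEG) * np.arange(n_res)
    for r in range(n_res):
        th = thetas[r]
        radial = np.array([np.cos(th), np.sin(th), 0.0])
        tangent = sense * np.array([-np.sin(th), np.cos(th), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        ca = (ring_radius + _HELIX_RADIUS_NM * np.cos(psi[r])) * radial \
            + (z0 + _HELIX_RADIUS_NM * np.sin(psi[r])) * zhat
        frame_mat = np.column_stack([tangent, radial, zhat])
        for name in ("N", "CA", "C", "O", "CB"):
            off = _BB_OFFSETS.get(name, np.zeros(3))
            names.append(name)
            elements.append(name[0])
            resids.append(r + 1)
            pos.append(ca + frame_mat @ off)
    return names, elements, resids, np.array(pos)


def _build_belt(ring_radius: float, belt: BeltSpec, arc_gap_nm: float = 0.5):
    """Four belt chains: A,B in the upper ring, C,D in the lower.

    Each chain spans just under half the circle, leaving ``arc_gap_nm``
    between chain termini.  Antiparallel mode reverses the angular sense of
    the lower ring.
    """
    circumference = 2.0 * np.pi * ring_radius
    arc_per_chain = circumference / 2.0 - arc_gap_nm
    n_res = max(4, int(arc_per_chain / _HELIX_RISE_NM))
    gap_angle = arc_gap_nm / ring_radius
    span = np.pi - gap_angle
    z_up = belt.inter_ring_separation / 2.0
    z_dn = -z_up
    lower_sense = 1 if belt.mode == "parallel" else -1

    uppers = [("A", z_up, gap_angle / 2.0, 1), ("B", z_up, np.pi + gap_angle / 2.0, 1)]
    if lower_sense == 1:
        lowers = [("C", z_dn, gap_angle / 2.0, 1), ("D", z_dn, np.pi + gap_angle / 2.0, 1)]
    else:
        lowers = [("C", z_dn, gap_angle / 2.0 + span, -1),
                  ("D", z_dn, np.pi + gap_angle / 2.0 + span, -1)]

    chains = []
    for cid, z0, th0, sense in uppers + lowers:
        names, elements, resids, pos = _belt_chain(
            ring_radius, z0, th0, th0 + sense * span, n_res, sense)
        chains.append((cid, names, elements, resids, pos))
    return chains


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def _assemble_frame(lipid_atoms, belt_chains, box=None) -> Frame:
    names, elements, resnames, resids, chains, positions = [], [], [], [], [], []
    for resid, atoms in enumerate(lipid_atoms, start=1):
        for name, element, p in atoms:
            names.append(name)
            elements.append(element)
            resnames.append("DMPC")
            resids.append(resid)
            chains.append("L")
            positions.append(p)
    for cid, cnames, celements, cresids, cpos in belt_chains:
        names += list(cnames)
        elements += list(celements)
        resnames += ["ALA"] * len(cnames)
        resids += list(cresids)
        chains += [cid] * len(cnames)
        positions += list(cpos)
    masses = [STANDARD_ATOMIC_MASSES[e] for e in elements]
    return Frame(names, elements, resnames, resids, chains,
                 np.array(positions), masses, box=box)


def _jitter_trajectory(base: Frame, n_frames: int, sigma: float,
                       rng: np.random.Generator) -> Trajectory:
    """Gaussian positional noise applied as one rigid translation per
    molecule (residue), so intramolecular geometry — in particular C-H bond
    directions — is exactly preserved under jitter."""
    keys = np.char.add(base.chains.astype("U8"), base.resids.astype("U12"))
    _, group = np.unique(keys, return_inverse=True)
    n_groups = group.max() + 1
    frames = []
    for _ in range(max(1, n_frames)):
        if sigma > 0:
            shifts = rng.normal(0.0, sigma, size=(n_groups, 3))
            frames.append(base.with_positions(base.positions + shifts[group]))
        else:
            frames.append(base.with_positions(base.positions.copy()))
    return Trajectory(frames, np.arange(len(frames), dtype=float))


def generate_nanodisc(spec: DiscSpec) -> tuple[Trajectory, GroundTruth]:
    """Build a synthetic double-belt nanodisc trajectory.

    Two hex-packed leaflets of the DMPC surrogate inside four poly-alanine
    belt chains (A/B upper ring, C/D lower); Gaussian positional noise per
    frame; deterministic under the spec's seed.

    Raises
    ------
    ValueError
        If the belt ring radius would fall inside the lipid disc.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lipids_per_leaflet
    r_disc = spec.disc_radius
    r_belt = r_disc + spec.belt.ring_radius_offset
    if r_belt <= r_disc:
        raise ValueError(
            f"belt radius {r_belt:.2f} nm must exceed the lipid disc radius "
            f"{r_disc:.2f} nm; increase ring_radius_offset")

    sites = _hex_sites(n, spec.area_per_lipid)
    lipid_atoms = []
    all_thetas = []
    for leaflet in (+1, -1):
        thetas = _sample_tilts(rng, n, spec.tail_tilt)
        if spec.rim_extra_tilt_sigma > 0:
            r_site = np.linalg.norm(sites, axis=1)
            rim = r_site > max(r_disc - spec.rim_band_nm, 0.0)
            thetas = thetas + rim * np.abs(
                rng.normal(0.0, spec.rim_extra_tilt_sigma, size=n))
        alphas = rng.uniform(0.0, 2 * np.pi, size=n)
        phis = rng.uniform(0.0, 2 * np.pi, size=n)
        for i in range(n):
            lipid_atoms.append(_build_lipid(
                sites[i], leaflet, spec.phosphate_plane_separation,
                thetas[i], alphas[i], phis[i]))
        all_thetas.append(thetas)

    belt_chains = _build_belt(r_belt, spec.belt)
    base = _assemble_frame(lipid_atoms, belt_chains)
    traj = _jitter_trajectory(base, spec.n_frames, spec.noise_sigma, rng)

    lipid_mask = base.resnames == "DMPC"
    outer = float(np.linalg.norm(base.positions[lipid_mask, :2], axis=1).max())
    scd = expected_abs_scd_from_tilt(np.concatenate(all_thetas))
    gt = GroundTruth(
        disc_radius=r_disc,
        thickness=spec.phosphate_plane_separation,
        expected_abs_scd={int(k): scd for k in TAIL_CARBON_INDICES},
        belt_radius=r_belt,
        label=str(spec.label),
        seed=spec.seed,
        n_lipids=2 * n,
        outer_radius=outer,
    )
    return traj, gt


def generate_bilayer_patch(n_per_leaflet: int = 75, *,
                           area_per_lipid: float = 0.60,
                           phosphate_plane_separation: float = 3.4,
                           tail_tilt: tuple = ("fixed_angle", 0.0),
                           noise_sigma: float = 0.05,
                           n_frames: int = 200,
                           seed: int = 0) -> tuple[Trajectory, GroundTruth]:
    """Rectangular periodic bilayer patch (default 75 lipids per leaflet,
    i.e. the 150-DMPC reference membrane), same lipid template as the disc.
    """
    if n_per_leaflet < 1:
        raise ValueError("n_per_leaflet must be >= 1")
    rng = np.random.default_rng(seed)
    s = np.sqrt(area_per_lipid)
    nx = int(np.ceil(np.sqrt(n_per_leaflet)))
    ny = int(np.ceil(n_per_leaflet / nx))
    sites = np.array([[ (i - (nx - 1) / 2) * s, (j - (ny - 1) / 2) * s ]
                      for j in range(ny) for i in range(nx)])[:n_per_leaflet]
    lipid_atoms = []
    all_thetas = []
    for leaflet in (+1, -1):
        thetas = _sample_tilts(rng, n_per_leaflet, tail_tilt)
        alphas = rng.uniform(0.0, 2 * np.pi, size=n_per_leaflet)
        phis = rng.uniform(0.0, 2 * np.pi, size=n_per_leaflet)
        for i in range(n_per_leaflet):
            lipid_atoms.append(_build_lipid(
                sites[i], leaflet, phosphate_plane_separation,
                thetas[i], alphas[i], phis[i]))
        all_thetas.append(thetas)
    box = np.array([nx * s, ny * s, phosphate_plane_separation + 3.0])
    base = _assemble_frame(lipid_atoms, [], box=box)
    traj = _jitter_trajectory(base, n_frames, noise_sigma, rng)
    scd = expected_abs_scd_from_tilt(np.concatenate(all_thetas))
    gt = GroundTruth(
        disc_radius=0.0,
        thickness=phosphate_plane_separation,
        expected_abs_scd={int(k): scd for k in TAIL_CARBON_INDICES},
        belt_radius=None,
        label=None,
        seed=seed,
        n_lipids=2 * n_per_leaflet,
    )
    return traj, gt


def perturb_frames(traj: Trajectory, sigma: float, n_frames: int,
                   seed: int) -> Trajectory:
    """n_frames independent Gaussian-jittered copies of frame 0.

    Emulates snapshot averaging over a fluctuating but stationary structure;
    sigma=0 reproduces frame 0 exactly in every output frame.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return _jitter_trajectory(traj.frames[0], n_frames, sigma, rng)
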