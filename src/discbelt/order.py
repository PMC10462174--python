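"""C-H bond (deuterium) order parameters of the lipid acyl chains.

For the i-th tail carbon, S_i = <(3 cos^2(theta_i) - 1)/2> with theta_i the
angle between a C-H bond and the bilayer normal (z after reorientation),
averaged over both Sn1 and Sn2 tails, all lipids in the selection, both
hydrogens (three on the terminal methyl) and all frames; the magnitude
|S_CD| is reported per carbon.  Lipids can further be partitioned into the
full disc, a central core (in-plane distance from the lipid center of mass
below a radius, default 3 nm) and a rim shell near the protein belt
(centroid within a distance of any protein atom, default 1.4 nm).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Frame, Trajectory

__all__ = [
    "OrderParameterProfile",
    "RegionPartition",
    "find_ch_bonds",
    "scd_profile",
    "partition_regions",
    "delta_scd",
]

_TAIL_CARBON = re.compile(r"^C[23](\d+)$")


@dataclass(frozen=True)
class OrderParameterProfile:
    """|S_CD| per tail carbon index for one lipid region.

    ``carbon_index`` holds the chemical tail positions (2..14 for a
    myristoyl chain; position 1 is the carbonyl and has no hydrogens).
    """

    carbon_index: np.ndarray
    abs_scd: np.ndarray
    region: str = "full"
    n_lipids_used: int = 0

    def __post_init__(self):
        if len(self.carbon_index) != len(self.abs_scd):
            raise ValueError("carbon_index and abs_scd must align")
        if np.any(self.abs_scd > 1.0 + 1e-9):
            raise ValueError("|S_CD| cannot exceed 1")

    def as_dict(self) -> dict:
        return {int(k): float(v)
                for k, v in zip(self.carbon_index, self.abs_scd)}

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"region": self.region,
                      "carbon_index": self.carbon_index,
                      "abs_scd": self.abs_scd,
                      "n_lipids": self.n_lipids_used}).to_csv(path, index=False)


@dataclass(frozen=True)
class RegionPartition:
    """Disjointly labelled lipid residue-id sets (core/rim are subsets of full)."""

    full: frozenset
    core: frozenset
    rim: frozenset
    core_radius: float = 3.0
    rim_distance: float = 1.4

    def __post_init__(self):
        if not (self.core <= self.full and self.rim <= self.full):
            raise ValueError("core and rim must be subsets of full")


def find_ch_bonds(frame: Frame, lipid_selection: np.ndarray
                  ) -> list[tuple[int, int, int, int]]:
    """(carbon_atom, hydrogen_atom, tail_carbon_index, lipid_resid) tuples.

    Tail carbons are recognised by force-field names C2k/C3k (k >= 2, the
    Sn2/Sn1 chains); their hydrogens are the H atoms immediately following
    the carbon in the residue's atom order — the layout both the synthetic
    lipid template and CHARMM-style all-atom lipids use.

    Raises ValueError if tail carbons are found but no hydrogens follow
    them (e.g. a united-atom model).
    """
    idx = np.asarray(lipid_selection, dtype=np.int64)
    bonds = []
    order = idx[np.argsort(idx, kind="stable")]
    names = frame.names
    elements = frame.elements
    resids = frame.resids
    n_carbons = 0
    for pos, i in enumerate(order):
        m = _TAIL_CARBON.match(names[i])
        if not m:
            continue
        k = int(m.group(1))
        if k < 2:
            continue
        n_carbons += 1
        j = pos + 1
        while j < len(order):
            a = order[j]
            if elements[a] != "H" or resids[a] != resids[i]:
                break
            bonds.append((int(i), int(a), k, int(resids[i])))
            j += 1
    if n_carbons and not bonds:
        raise ValueError(
            "tail carbons carry no explicit hydrogens; provide an all-atom "
            "model or reconstruct C-H directions upstream")
    return bonds


def scd_profile(traj: Trajectory | Frame, lipid_selection: np.ndarray,
                region: str = "full",
                resid_filter=None) -> OrderParameterProfile:
    """|S_CD| per tail carbon over lipids, tails, bonds and frames.

    Frames must already be reoriented (bilayer normal along z).
    ``resid_filter`` restricts the averaged lipids: a set of residue ids, or
    a sequence of per-frame sets (a lipid contributes to whichever region
    it occupies in each frame).
    """
    if isinstance(traj, Trajectory):
        frames = traj.frames
    else:
        frames = [traj]
    bonds = find_ch_bonds(frames[0], lipid_selection)
    if not bonds:
        raise ValueError("no C-H bonds found in the lipid selection")
    carbons = np.array([b[0] for b in bonds])
    hydros = np.array([b[1] for b in bonds])
    kindex = np.array([b[2] for b in bonds])
    bresid = np.array([b[3] for b in bonds])

    per_frame_filter = None
    if resid_filter is not None:
        if isinstance(resid_filter, (set, frozenset)):
            per_frame_filter = [resid_filter] * len(frames)
        else:
            per_frame_filter = list(resid_filter)
            if len(per_frame_filter) != len(frames):
                raise ValueError("per-frame resid_filter length mismatch")

    ks = np.unique(kindex)
    sums = np.zeros(len(ks))
    counts = np.zeros(len(ks), dtype=np.int64)
    used_resids: set[int] = set()
    kslot = np.searchsorted(ks, kindex)
    for fi, frame in enumerate(frames):
        if per_frame_filter is not None:
            keep = np.isin(bresid, sorted(per_frame_filter[fi]))
            if not keep.any():
                continue
        else:
            keep = np.ones(len(bonds), dtype=bool)
        vec = frame.positions[hydros[keep]] - frame.positions[carbons[keep]]
        cos2 = (vec[:, 2] ** 2) / np.einsum("ij,ij->i", vec, vec)
        s = 0.5 * (3.0 * cos2 - 1.0)
        np.add.at(sums, kslot[keep], s)
        np.add.at(counts, kslot[keep], 1)
        used_resids.update(bresid[keep].tolist())
    if counts.sum() == 0:
        raise ValueError("no lipids matched the region filter in any frame")
    scd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return OrderParameterProfile(
        carbon_index=ks, abs_scd=np.abs(scd), region=region,
        n_lipids_used=len(used_resids))


def partition_regions(frame: Frame, lipid_selection: np.ndarray,
                      protein_selection: np.ndarray,
                      core_radius: float = 3.0,
                      rim_distance: float = 1.4) -> RegionPartition:
    """Classify lipids of a reoriented frame into full / core / rim.

    core: lipid centroid's in-plane (xy) distance from the lipid center of
    mass <= ``core_radius``.  rim: centroid within ``rim_distance`` of any
    protein atom.  A lipid may satisfy both; the sets are labels, not a
    partition of convenience.
    """
    lsel = np.asarray(lipid_selection, dtype=np.int64)
    resids = frame.resids[lsel]
    unique, inverse = np.unique(resids, return_inverse=True)
    counts = np.bincount(inverse)
    centroids = np.zeros((len(unique), 3))
    for d in range(3):
        centroids[:, d] = np.bincount(
            inverse, weights=frame.positions[lsel, d]) / counts
    masses = frame.masses[lsel]
    com = masses @ frame.positions[lsel] / masses.sum()
    in_plane = np.linalg.norm(centroids[:, :2] - com[:2], axis=1)
    core = unique[in_plane <= core_radius]

    psel = np.asarray(protein_selection, dtype=np.int64)
    if psel.size:
        tree = cKDTree(frame.positions[psel])
        d_near, _ = tree.query(centroids, k=1)
        rim = unique[d_near <= rim_distance]
    else:
        rim = np.array([], dtype=unique.dtype)
    return RegionPartition(
        full=frozenset(int(r) for r in unique),
        core=frozenset(int(r) for r in core),
        rim=frozenset(int(r) for r in rim),
        core_radius=core_radius, rim_distance=rim_distance)


def delta_scd(profile_parallel: OrderParameterProfile,
              profile_antiparallel: OrderParameterProfile) -> np.ndarray:
    """Per-carbon |S_CD|(parallel) - |S_CD|(antiparallel).

    Raises ValueError on mismatched carbon indexing or regions.
    """
    if not np.array_equal(profile_parallel.carbon_index,
                          profile_antiparallel.carbon_index):
        raise ValueError("carbon indices do not match")
    if profile_parallel.region != profile_antiparallel.region:
        raise ValueError("profiles come from different regions")
    return profile_parallel.abs_scd - profile_antiparallel.abs_scd
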