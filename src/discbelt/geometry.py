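"""Frame reorientation, superposition and rigid-body geometry.

Snapshot frames are reoriented so that the bilayer normal lies along +z
(the convention all density, diameter and order-parameter analyses assume).
The normal is taken as the smallest-variance principal axis of the
phosphate positions; the in-plane axes are ordered so the major axis of the
disc lies along x, which fixes the x/y convention for diameter reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import Frame, Trajectory, select_atoms

__all__ = [
    "RigidTransform",
    "RmsdSeries",
    "bilayer_normal",
    "reorient",
    "radius_of_gyration",
    "kabsch_superpose",
    "backbone_rmsd_series",
    "detect_escaped_lipids",
    "BACKBONE_NAMES",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body map x -> rotation @ x + translation (nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        R1, t1 = np.asarray(self.rotation), np.asarray(self.translation)
        R2, t2 = np.asarray(other.rotation), np.asarray(other.translation)
        return RigidTransform(R1 @ R2, R1 @ t2 + t1)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD (nm) with its mean and standard deviation."""

    rmsd: np.ndarray
    times: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.rmsd))

    @property
    def sd(self) -> float:
        return float(np.std(self.rmsd))

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f}"

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"frame": np.arange(len(self.rmsd)),
                      "time_ns": self.times,
                      "rmsd_nm": self.rmsd}).to_csv(path, index=False)


def bilayer_normal(frame: Frame, lipid_selection: np.ndarray) -> np.ndarray:
    """Unit bilayer normal: smallest-variance eigenvector of the selected
    (typically phosphate) positions' covariance; sign fixed so n_z >= 0."""
    pts = frame.positions[np.asarray(lipid_selection, dtype=np.int64)]
    if len(pts) < 3:
        raise ValueError("need at least 3 atoms to define a bilayer normal")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12:  # two near-zero variances: atoms collinear
        raise ValueError("degenerate atom arrangement: cannot define a plane")
    normal = evecs[:, 0]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or
                                             (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return normal


def reorient(frame: Frame, lipid_selection: np.ndarray
             ) -> tuple[Frame, RigidTransform]:
    """Rigidly map the frame so the lipid COM is at the origin, the bilayer
    normal is +z, and the larger in-plane variance lies along x."""
    idx = np.asarray(lipid_selection, dtype=np.int64)
    pts = frame.positions[idx]
    masses = frame.masses[idx]
    com = masses @ pts / masses.sum()
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12:
        raise ValueError("degenerate atom arrangement: cannot define a plane")
    # eigh returns ascending eigenvalues: [normal, minor, major]
    zax, yax, xax = evecs[:, 0], evecs[:, 1], evecs[:, 2]
    if zax[2] < 0:
        zax = -zax
    if xax[0] < 0:  # deterministic sign convention for the in-plane axes
        xax = -xax
    yax = np.cross(zax, xax)
    R = np.vstack([xax, yax, zax])  # rows: new axes -> R maps lab to disc frame
    t = -R @ com
    out = frame.with_positions(frame.positions @ R.T + t)
    return out, RigidTransform(R, t)


def radius_of_gyration(frame: Frame, selection: np.ndarray) -> float:
    """Mass-weighted rms distance (nm) of the selection from its COM."""
    idx = np.asarray(selection, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("radius_of_gyration needs a non-empty selection")
    pts = frame.positions[idx]
    m = frame.masses[idx]
    if m.sum() <= 0:
        raise ValueError("selection has non-positive total mass")
    com = m @ pts / m.sum()
    return float(np.sqrt(np.sum(m * np.sum((pts - com) ** 2, axis=1)) / m.sum()))


def kabsch_superpose(reference: Frame, mobile: Frame,
                     selection: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation+translation minimizing the RMSD over the
    selected atoms, and the minimized RMSD (nm).  Reflections are never
    returned; near-degenerate cases take the best proper rotation.
    """
    idx = np.asarray(selection, dtype=np.int64)
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    P = mobile.positions[idx]
    Q = reference.positions[idx]
    if P.shape != Q.shape:
        raise ValueError("selected atom counts differ between frames")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def backbone_rmsd_series(traj: Trajectory, reference_frame: Frame,
                         backbone_selection: np.ndarray | None = None
                         ) -> RmsdSeries:
    """Per-frame backbone RMSD vs a reference after per-frame superposition.

    The default selection is the protein backbone (N, CA, C, O) of chains
    A-D; pass an explicit selection for anything else.
    """
    if backbone_selection is None:
        f = reference_frame
        backbone_selection = select_atoms(
            f, chain=("A", "B", "C", "D"), atom_name=BACKBONE_NAMES)
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        _, values[k] = kabsch_superpose(reference_frame, frame, backbone_selection)
    return RmsdSeries(values, np.asarray(traj.times))


_ESCAPE_MARKER_NAMES = ("P", "C214", "C314")


def detect_escaped_lipids(frame: Frame, max_gap: float = 1.0,
                          lipid_resnames=("DMPC",)) -> list[int]:
    """Residue ids of lipids outside the main nanodisc cluster.

    Lipids are single-linkage clustered at ``max_gap`` (nm) on
    representative atoms — the phosphate and the two terminal tail carbons
    — so that leaflets join through their facing tail ends as well as
    laterally (molecule centroids alone sit more than a bilayer half-
    thickness apart and would split an intact disc).  Everything outside
    the largest cluster is reported as escaped.
    """
    sel = select_atoms(frame, residue_name=lipid_resnames)
    if sel.size == 0:
        return []
    markers = sel[np.isin(frame.names[sel], _ESCAPE_MARKER_NAMES)]
    if markers.size == 0:
        markers = sel  # unknown naming dialect: fall back to all lipid atoms
    resids = frame.resids[markers]
    unique, inverse = np.unique(resids, return_inverse=True)
    if len(unique) == 1:
        return []
    pts = frame.positions[markers]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(max_gap, output_type="ndarray")
    n = len(unique)
    if len(pairs) == 0:
        adj = coo_matrix((n, n))
    else:
        ri = inverse[pairs[:, 0]]
        rj = inverse[pairs[:, 1]]
        adj = coo_matrix((np.ones(len(ri)), (ri, rj)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    largest = np.argmax(np.bincount(labels))
    return [int(r) for r in unique[labels != largest]]
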