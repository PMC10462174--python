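"""Domain containers and coordinate I/O for nanodisc structures and trajectories.

The in-memory model is deliberately small: a :class:`Frame` is a set of
parallel numpy arrays (names, elements, residues, chains, positions, masses)
and a :class:`Trajectory` is an ordered list of frames sharing one atom
table.  All lengths are nanometres internally; formats that use Ångström
(PDB, and MDAnalysis' internal convention) are converted on read/write.

Reading and writing of PDB/GRO/XTC/DCD is delegated to MDAnalysis; this
module only adds unit conversion, element inference and mass assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SystemLabel",
    "STANDARD_ATOMIC_MASSES",
    "read_structure",
    "write_structure",
    "select_atoms",
    "subset_mass",
    "system_mass",
    "guess_element",
    "DMPC_MASS_DA",
    "APOE3_NT_CHAIN_MASS_DA",
]

# Standard atomic masses (amu).  The 2005 IUPAC values are used throughout:
# with them the C36H72NO8P formula of DMPC sums to 677.93 amu, the per-lipid
# mass that the published apoE3-NT/DMPC system-mass range is built from.
STANDARD_ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00794,
    "D": 2.014102,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "NA": 22.98977,
    "MG": 24.3050,
    "P": 30.973762,
    "S": 32.065,
    "CL": 35.453,
    "K": 39.0983,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.409,
    "SE": 78.96,
}

#: Molecular mass of DMPC (C36H72NO8P) rounded to the 2-decimal figure the
#: published system masses are consistent with.
DMPC_MASS_DA = 677.93

#: Default per-chain mass for apoE3-NT scaffold systems.  The published
#: system-mass range (298,703 - 420,730 Da for 240-420 DMPC) is reproduced
#: exactly by 4 x 34,000 Da + n x 677.93 Da, i.e. the ~34 kDa full-length
#: apoE figure, although only residues 1-183 were simulated.
APOE3_NT_CHAIN_MASS_DA = 34_000.0

_ANGSTROM_PER_NM = 10.0

_TWO_LETTER_ELEMENTS = {"NA", "MG", "CL", "CA", "FE", "ZN", "SE", "BR"}


def guess_element(atom_name: str) -> str:
    """Infer an element symbol from an atom name (PDB/force-field style).

    Handles the common biomolecular cases: leading digits ("1HB"), Greek
    position suffixes ("CA" the carbon vs "CA" the ion is disambiguated by
    residue context upstream; here a bare two-letter match is only taken for
    genuine two-letter elements when the full name equals the symbol).
    """
    name = atom_name.strip().upper()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if name in _TWO_LETTER_ELEMENTS:
        return name
    return stripped[0]


def _mass_for(element: str, mass_table: Mapping[str, float] | None) -> float:
    key = element.strip().upper()
    table = mass_table if mass_table is not None else STANDARD_ATOMIC_MASSES
    if key not in table:
        raise KeyError(f"no standard atomic mass tabulated for element {key!r}")
    return float(table[key])


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus position (nm) and mass (amu)."""

    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: tuple[float, float, float]
    mass: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


class Frame:
    """One snapshot: parallel arrays over atoms, positions in nm.

    Atom order is the identity key across frames of a trajectory; no
    name-based matching is ever performed.
    """

    __slots__ = ("names", "elements", "resnames", "resids", "chains",
                 "positions", "masses", "box")

    def __init__(self, names, elements, resnames, resids, chains, positions,
                 masses, box=None):
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.resnames = np.asarray(resnames, dtype="U4")
        self.resids = np.asarray(resids, dtype=np.int64)
        self.chains = np.asarray(chains, dtype="U1")
        self.positions = np.ascontiguousarray(positions, dtype=np.float64)
        self.masses = np.asarray(masses, dtype=np.float64)
        self.box = None if box is None else np.asarray(box, dtype=np.float64)
        n = len(self.names)
        for arr, label in ((self.elements, "elements"), (self.resnames, "resnames"),
                           (self.resids, "resids"), (self.chains, "chains"),
                           (self.masses, "masses")):
            if len(arr) != n:
                raise ValueError(f"frame field {label} has length {len(arr)} != {n}")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.resnames[i]),
            residue_seq=int(self.resids[i]),
            chain_id=str(self.chains[i]),
            position=tuple(self.positions[i]),
            mass=float(self.masses[i]),
        )

    @classmethod
    def from_atoms(cls, atoms: Sequence[AtomRecord], box=None) -> "Frame":
        return cls(
            names=[a.atom_name for a in atoms],
            elements=[a.element for a in atoms],
            resnames=[a.residue_name for a in atoms],
            resids=[a.residue_seq for a in atoms],
            chains=[a.chain_id for a in atoms],
            positions=[a.position for a in atoms],
            masses=[a.mass for a in atoms],
            box=box,
        )

    def with_positions(self, positions: np.ndarray, box=None) -> "Frame":
        """A new frame sharing this frame's atom table with new coordinates."""
        f = Frame.__new__(Frame)
        f.names = self.names
        f.elements = self.elements
        f.resnames = self.resnames
        f.resids = self.resids
        f.chains = self.chains
        f.positions = np.ascontiguousarray(positions, dtype=np.float64)
        f.masses = self.masses
        f.box = self.box if box is None else np.asarray(box, dtype=np.float64)
        if f.positions.shape != (self.n_atoms, 3):
            raise ValueError("positions shape mismatch")
        return f

    def copy(self) -> "Frame":
        return self.with_positions(self.positions.copy())


class Trajectory:
    """Frames with identical atom tables plus per-frame times (ns)."""

    def __init__(self, frames: Sequence[Frame], times: Sequence[float] | None = None):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].n_atoms
        for k, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValueError(f"frame {k} has {f.n_atoms} atoms, expected {n}")
        if times is None:
            times = np.arange(len(frames), dtype=float)
        times = np.asarray(times, dtype=float)
        if len(times) != len(frames):
            raise ValueError("times length must match frame count")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i], self.times[i])
        return self.frames[i]


@dataclass(frozen=True)
class SystemLabel:
    """Nanodisc naming: total DMPC count + belt arrangement, e.g. '360-A'."""

    n_lipids: int
    mode: str  # "parallel" | "antiparallel"

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "antiparallel"):
            raise ValueError(f"mode must be parallel/antiparallel, got {self.mode!r}")

    def __str__(self) -> str:
        return f"{self.n_lipids}-{'P' if self.mode == 'parallel' else 'A'}"

    @classmethod
    def parse(cls, label: str) -> "SystemLabel":
        n, _, suffix = label.partition("-")
        mode = {"P": "parallel", "A": "antiparallel"}.get(suffix.upper())
        if mode is None:
            raise ValueError(f"bad system label {label!r}; expected e.g. '240-A'")
        return cls(n_lipids=int(n), mode=mode)


# ---------------------------------------------------------------------------
# Reading / writing via MDAnalysis
# ---------------------------------------------------------------------------

def _import_mda():
    import MDAnalysis as mda  # deferred: import cost and noisy warnings
    return mda


def _frame_from_universe(u, mass_table=None) -> tuple[np.ndarray, ...]:
    atoms = u.atoms
    names = atoms.names.astype("U6")
    try:
        elements = np.array([e if e else guess_element(n)
                             for e, n in zip(atoms.elements, names)], dtype="U2")
    except Exception:
        elements = np.array([guess_element(n) for n in names], dtype="U2")
    resnames = atoms.resnames.astype("U4")
    resids = atoms.resids.astype(np.int64)
    try:
        chains = np.array([c[:1] if c else "A" for c in atoms.chainIDs], dtype="U1")
    except Exception:
        try:
            chains = np.array([s[:1] if s else "A" for s in atoms.segids], dtype="U1")
        except Exception:
            chains = np.full(len(names), "A", dtype="U1")
    masses = np.array([_mass_for(e, mass_table) for e in elements])
    return names, elements, resnames, resids, chains, masses


def read_structure(path, format: str | None = None, topology=None,
                   mass_table: Mapping[str, float] | None = None) -> Trajectory:
    """Read a structure or trajectory into a :class:`Trajectory` (nm units).

    Parameters
    ----------
    path:
        Coordinate file: PDB or GRO (single- or multi-frame), or an XTC/DCD
        trajectory, in which case ``topology`` (PDB/GRO) must be given.
    format:
        Override the extension-based format detection (``"PDB"``, ``"GRO"``,
        ``"XTC"``, ``"DCD"``).
    mass_table:
        Optional element/bead-name -> mass (amu) mapping for coarse-grained
        inputs without elemental atoms.  Defaults to standard atomic masses.

    Raises
    ------
    ValueError
        If the file cannot be parsed under the named format.
    KeyError
        If an element has no tabulated mass.
    """
    mda = _import_mda()
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO", "XTC", "DCD"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt in ("XTC", "DCD"):
                if topology is None:
                    raise ValueError(f"{fmt} trajectories need a topology= PDB/GRO file")
                u = mda.Universe(str(topology), str(path))
            else:
                u = mda.Universe(str(path))
    except (OSError, EOFError) as exc:  # pragma: no cover - passthrough
        raise
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc

    names, elements, resnames, resids, chains, masses = _frame_from_universe(
        u, mass_table)
    frames: list[Frame] = []
    times: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = ts.dimensions[:3] / _ANGSTROM_PER_NM
            frames.append(Frame(names, elements, resnames, resids, chains,
                                u.atoms.positions / _ANGSTROM_PER_NM, masses,
                                box=box))
            times.append(float(ts.time) / 1000.0)  # MDAnalysis ps -> ns
    t = np.asarray(times)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        t = np.arange(len(frames), dtype=float)
    return Trajectory(frames, t)


def write_structure(traj: Trajectory | Frame, path, format: str | None = None) -> None:
    """Write frames to PDB/GRO (multi-model for PDB) or XTC/DCD.

    Positions are converted from nm to the format's native unit.  PDB
    preserves chain identifiers; GRO has no chain field (format limitation)
    so chains are not round-tripped through GRO.
    """
    mda = _import_mda()
    if isinstance(traj, Frame):
        traj = Trajectory([traj])
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    f0 = traj.frames[0]
    n = f0.n_atoms
    n_res_ids = {}
    res_index = np.empty(n, dtype=np.int64)
    for i, key in enumerate(zip(f0.chains, f0.resids, f0.resnames)):
        res_index[i] = n_res_ids.setdefault(key, len(n_res_ids))
    n_res = len(n_res_ids)
    res_keys = list(n_res_ids)

    seg_names = sorted({str(c) for c in f0.chains})
    seg_idx = {s: k for k, s in enumerate(seg_names)}
    res_seg = np.array([seg_idx[str(k[0])] for k in res_keys])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n_res, n_segments=len(seg_names),
                               atom_resindex=res_index,
                               residue_segindex=res_seg, trajectory=True)
        u.add_TopologyAttr("names", f0.names)
        u.add_TopologyAttr("elements", f0.elements)
        u.add_TopologyAttr("masses", f0.masses)
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("chainIDs", f0.chains)
        u.add_TopologyAttr("segids", seg_names)

        box = f0.box
        dims = None
        if box is not None:
            dims = np.array([*(box * _ANGSTROM_PER_NM), 90.0, 90.0, 90.0])

        with mda.Writer(str(path), n_atoms=n, format=fmt, multiframe=(len(traj) > 1)) as w:
            for frame, t_ns in zip(traj.frames, traj.times):
                u.atoms.positions = frame.positions * _ANGSTROM_PER_NM
                if dims is not None:
                    u.dimensions = dims
                u.trajectory.ts.time = t_ns * 1000.0
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selection and mass accounting
# ---------------------------------------------------------------------------

def _as_set(value) -> set[str] | None:
    if value is None:
        return None
    if isinstance(value, str):
        return {value}
    return {str(v) for v in value}


def select_atoms(frame: Frame, chain=None, residue_name=None, atom_name=None,
                 element=None, residue_seq=None) -> np.ndarray:
    """Indices of atoms matching every given predicate (AND semantics).

    Each predicate is a value or an iterable of values; ``None`` means
    "any".  An empty result is a value, not an error.
    """
    mask = np.ones(frame.n_atoms, dtype=bool)
    for values, arr in ((_as_set(chain), frame.chains),
                        (_as_set(residue_name), frame.resnames),
                        (_as_set(atom_name), frame.names),
                        (_as_set(element), frame.elements)):
        if values is not None:
            mask &= np.isin(arr, sorted(values))
    if residue_seq is not None:
        seqs = {int(residue_seq)} if np.isscalar(residue_seq) else {int(v) for v in residue_seq}
        mask &= np.isin(frame.resids, sorted(seqs))
    return np.flatnonzero(mask)


def subset_mass(frame: Frame, selection: np.ndarray | Iterable[int]) -> float:
    """Total mass (amu) of the selected atoms; 0 for an empty selection."""
    idx = np.asarray(list(selection) if not isinstance(selection, np.ndarray)
                     else selection, dtype=np.int64)
    if idx.size == 0:
        return 0.0
    return float(frame.masses[idx].sum())


def system_mass(n_chains: int, chain_mass: float, n_lipids: int,
                lipid_mass: float = DMPC_MASS_DA) -> int:
    """Total nanodisc mass in integer Da: n_chains*chain_mass + n_lipids*lipid_mass.

    The fractional remainder is discarded, matching how published totals for
    scaffold-protein/DMPC systems are reported.

    >>> system_mass(4, 34000, 240)
    298703
    >>> system_mass(4, 34000, 420)
    420730
    """
    if min(n_chains, chain_mass, n_lipids, lipid_mass) < 0:
        raise ValueError("all mass-accounting arguments must be non-negative")
    return int(n_chains * chain_mass + n_lipids * lipid_mass)
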