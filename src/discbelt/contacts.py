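"""Inter-chain residue contacts: extraction, classification, summaries.

A contact is a pair of residues on different scaffold chains whose
side-chain heavy atoms come closer than a cutoff (0.4 nm by default, after
a 1 nm prefilter).  Contacts are classified as polar, nonpolar or
nonspecific (one polar + one nonpolar partner), with an ionic flag for
basic-acidic pairs (R/K/H with D/E) — the salt bridges that dominate the
stability difference between parallel and antiparallel double belts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Frame, Trajectory

__all__ = [
    "ContactClass",
    "ContactRecord",
    "ContactSummary",
    "POLAR_RESIDUES",
    "NONPOLAR_RESIDUES",
    "residue_min_distance",
    "classify_contact",
    "interchain_contacts",
    "summarize_contacts",
    "configuration_comparison",
]

# The polarity decision table.  One residue from each class => "nonspecific".
POLAR_RESIDUES = frozenset(
    {"ASP", "GLU", "LYS", "ARG", "HIS", "ASN", "GLN", "SER", "THR", "TYR",
     "CYS", "TRP"})
NONPOLAR_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY"})

_BASIC = frozenset({"ARG", "LYS", "HIS"})
_ACIDIC = frozenset({"ASP", "GLU"})

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class ContactClass:
    category: str          # "polar" | "nonpolar" | "nonspecific"
    ionic: bool

    def __post_init__(self):
        if self.ionic and self.category != "polar":
            raise ValueError("ionic contacts are by definition polar")


@dataclass(frozen=True)
class ContactRecord:
    """One inter-chain residue pair observed in contact."""

    chain_i: str
    resname_i: str
    resseq_i: int
    chain_j: str
    resname_j: str
    resseq_j: int
    min_sidechain_distance: float  # nm, minimum over frames
    mean_distance: float           # nm, mean over frames where in contact
    occupancy: float               # fraction of frames in contact


@dataclass(frozen=True)
class ContactSummary:
    """Per-system category counts (the published table layout)."""

    polar_total: int
    ionic: int
    nonspecific: int
    nonpolar: int

    @property
    def total(self) -> int:
        return self.polar_total + self.nonspecific + self.nonpolar

    def as_dict(self) -> dict:
        return {"polar_total": self.polar_total, "ionic": self.ionic,
                "nonspecific": self.nonspecific, "nonpolar": self.nonpolar,
                "total": self.total}


def _sidechain_mask(frame: Frame, idx: np.ndarray) -> np.ndarray:
    """Side-chain heavy atoms; glycine keeps CA as its side-chain surrogate."""
    names = frame.names[idx]
    elements = frame.elements[idx]
    resnames = frame.resnames[idx]
    heavy = elements != "H"
    sidechain = ~np.isin(names, sorted(_BACKBONE))
    gly_ca = (resnames == "GLY") & (names == "CA")
    return heavy & (sidechain | gly_ca)


def residue_min_distance(frame: Frame, res_i: tuple[str, int],
                         res_j: tuple[str, int]) -> float:
    """Minimum side-chain heavy-atom distance (nm) between two residues,
    each given as (chain_id, residue_seq)."""
    out = []
    for chain, seq in (res_i, res_j):
        idx = np.flatnonzero((frame.chains == chain) & (frame.resids == seq))
        if idx.size == 0:
            raise ValueError(f"residue {chain}{seq} not present in frame")
        idx = idx[_sidechain_mask(frame, idx)]
        if idx.size == 0:
            raise ValueError(
                f"residue {chain}{seq} has no side-chain heavy atoms")
        out.append(frame.positions[idx])
    a, b = out
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def classify_contact(resname_i: str, resname_j: str,
                     polar=POLAR_RESIDUES, nonpolar=NONPOLAR_RESIDUES
                     ) -> ContactClass:
    """Polarity class of a residue pair plus the salt-bridge (ionic) flag.

    Raises ValueError for residues absent from both class tables (pass
    extended ``polar``/``nonpolar`` sets for nonstandard residues).
    """
    names = (resname_i.upper(), resname_j.upper())
    for nm in names:
        if nm not in polar and nm not in nonpolar:
            raise ValueError(f"residue {nm!r} is in neither polarity class")
    both_polar = all(nm in polar for nm in names)
    both_nonpolar = all(nm in nonpolar for nm in names)
    category = "polar" if both_polar else "nonpolar" if both_nonpolar else "nonspecific"
    ionic = category == "polar" and (
        (names[0] in _BASIC and names[1] in _ACIDIC)
        or (names[1] in _BASIC and names[0] in _ACIDIC))
    return ContactClass(category=category, ionic=ionic)


def _residue_table(frame: Frame, chain: str):
    """[(resid, resname, sidechain atom indices), ...] for one chain."""
    idx = np.flatnonzero(frame.chains == chain)
    if idx.size == 0:
        raise ValueError(f"unknown chain id {chain!r}")
    idx = idx[_sidechain_mask(frame, idx)]
    table = []
    for resid in np.unique(frame.resids[idx]):
        sub = idx[frame.resids[idx] == resid]
        table.append((int(resid), str(frame.resnames[sub[0]]), sub))
    return table


def interchain_contacts(traj: Trajectory | Frame,
                        chain_pairs=(("A", "C"), ("B", "D")),
                        prefilter: float = 1.0, cutoff: float = 0.4,
                        occupancy_min: float = 0.5
                        ) -> list[tuple[ContactRecord, ContactClass]]:
    """Residue contacts between chains, classified, with frame occupancy.

    Residue pairs within ``prefilter`` (nm) in any frame are tracked; a pair
    is *in contact* in a frame when its minimum side-chain heavy-atom
    distance is below ``cutoff``, and reported when its occupancy reaches
    ``occupancy_min``.
    """
    if isinstance(traj, Frame):
        traj = Trajectory([traj])
    # distance bookkeeping per (pair key) -> list of per-frame min distances
    per_pair: dict[tuple, list[float]] = defaultdict(
        lambda: [np.inf] * traj.n_frames)
    meta: dict[tuple, tuple] = {}

    for fk, frame in enumerate(traj.frames):
        for ca, cb in chain_pairs:
            ta = _residue_table(frame, ca)
            tb = _residue_table(frame, cb)
            pos_a = np.vstack([frame.positions[s] for _, _, s in ta])
            pos_b = np.vstack([frame.positions[s] for _, _, s in tb])
            owner_a = np.concatenate([np.full(len(s), k)
                                      for k, (_, _, s) in enumerate(ta)])
            owner_b = np.concatenate([np.full(len(s), k)
                                      for k, (_, _, s) in enumerate(tb)])
            pairs = cKDTree(pos_a).query_ball_tree(cKDTree(pos_b), prefilter)
            best: dict[tuple[int, int], float] = {}
            for ia, js in enumerate(pairs):
                if not js:
                    continue
                d = np.sqrt(((pos_a[ia] - pos_b[js]) ** 2).sum(axis=1))
                ra = owner_a[ia]
                for j, dist in zip(js, d):
                    key = (ra, owner_b[j])
                    if dist < best.get(key, np.inf):
                        best[key] = float(dist)
            for (ka, kb), dist in best.items():
                rid_a, rnm_a, _ = ta[ka]
                rid_b, rnm_b, _ = tb[kb]
                key = (ca, rid_a, cb, rid_b)
                per_pair[key][fk] = dist
                meta[key] = (rnm_a, rnm_b)

    out = []
    for key, dists in per_pair.items():
        dists = np.asarray(dists)
        in_contact = dists < cutoff
        occupancy = in_contact.mean()
        if occupancy <= 0 or occupancy < occupancy_min:
            continue
        ca, rid_a, cb, rid_b = key
        rnm_a, rnm_b = meta[key]
        rec = ContactRecord(
            chain_i=ca, resname_i=rnm_a, resseq_i=rid_a,
            chain_j=cb, resname_j=rnm_b, resseq_j=rid_b,
            min_sidechain_distance=float(dists[in_contact].min()),
            mean_distance=float(dists[in_contact].mean()),
            occupancy=float(occupancy))
        out.append((rec, classify_contact(rnm_a, rnm_b)))
    out.sort(key=lambda rc: (rc[0].chain_i, rc[0].resseq_i,
                             rc[0].chain_j, rc[0].resseq_j))
    return out


def summarize_contacts(records) -> ContactSummary:
    """Category counts over classified contact records."""
    polar = ionic = nonspecific = nonpolar = 0
    for _, cls in records:
        if cls.category == "polar":
            polar += 1
            ionic += cls.ionic
        elif cls.category == "nonpolar":
            nonpolar += 1
        else:
            nonspecific += 1
    return ContactSummary(polar_total=polar, ionic=int(ionic),
                          nonspecific=nonspecific, nonpolar=nonpolar)


def contacts_to_dataframe(records) -> pd.DataFrame:
    rows = [{**rec.__dict__, "category": cls.category, "ionic": cls.ionic}
            for rec, cls in records]
    return pd.DataFrame(rows)


def configuration_comparison(summaries_parallel: pd.DataFrame,
                             summaries_antiparallel: pd.DataFrame,
                             common_only: bool = True) -> dict:
    """Antiparallel-to-parallel contact-count ratios by category.

    Inputs are per-system summary tables indexed by total lipid count with
    columns polar_total / ionic / nonspecific / nonpolar / total (NaN where
    a system is missing).  For every category the ratio of the mean
    antiparallel count to the mean parallel count is computed over the
    lipid counts present in both configurations, rounded to one decimal;
    min-max ranges per configuration are reported alongside.
    """
    p = summaries_parallel.dropna()
    a = summaries_antiparallel.dropna()
    common = sorted(set(p.index) & set(a.index)) if common_only \
        else sorted(set(p.index) | set(a.index))
    if not common:
        raise ValueError("no lipid count present in both configurations")
    categories = ["polar_total", "ionic", "nonspecific", "nonpolar", "total"]
    ratios = {}
    for cat in categories:
        mp = float(p.loc[common, cat].mean())
        ma = float(a.loc[common, cat].mean())
        ratios[cat] = round(ma / mp, 1) if mp != 0 else float("inf")
    return {
        "common_n_lipids": [int(n) for n in common],
        "ratio_antiparallel_over_parallel": ratios,
        "range_parallel": {cat: (int(p[cat].min()), int(p[cat].max()))
                           for cat in categories},
        "range_antiparallel": {cat: (int(a[cat].min()), int(a[cat].max()))
                               for cat in categories},
    }
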