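"""Published summary tables for apoE3-NT/DMPC nanodisc simulations.

These are the reported per-system statistics for the ten parallel ("-P")
and ten antiparallel ("-A") double-belt systems with 240-420 DMPC
molecules: backbone RMSD of the scaffold chains, and inter-chain contact
counts (A-C and B-D stacking contacts at the 0.4 nm side-chain cutoff,
classified as polar / nonspecific / nonpolar with the ionic sub-count).
The 240-P system was unstable and 420-P could not be converted to an
all-atom model, so those rows carry NaN.

They serve as reference inputs for the configuration-comparison
statistics, which are thereby testable without any trajectory data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["apoe3_dmpc_contact_table", "apoe3_dmpc_rmsd_table"]

_NA = float("nan")

# n_lipids: (polar_total, ionic, nonspecific, nonpolar) per configuration
_CONTACTS_PARALLEL = {
    240: (_NA, _NA, _NA, _NA),
    260: (30, 5, 38, 33),
    280: (8, 1, 27, 16),
    300: (19, 1, 37, 19),
    320: (27, 6, 47, 16),
    340: (38, 1, 66, 39),
    360: (32, 9, 59, 33),
    380: (27, 5, 64, 27),
    400: (28, 5, 57, 16),
    420: (_NA, _NA, _NA, _NA),
}
_CONTACTS_ANTIPARALLEL = {
    240: (51, 13, 93, 61),
    260: (32, 18, 61, 47),
    280: (41, 14, 73, 56),
    300: (61, 16, 65, 63),
    320: (44, 10, 70, 71),
    340: (40, 9, 85, 66),
    360: (57, 11, 78, 57),
    380: (58, 18, 89, 55),
    400: (53, 10, 67, 50),
    420: (43, 8, 63, 59),
}

# n_lipids: (mean_nm, sd_nm); NaN where no stable all-atom system exists
_RMSD_PARALLEL = {
    240: (_NA, _NA), 260: (0.43, 0.13), 280: (0.61, 0.12), 300: (0.49, 0.13),
    320: (0.66, 0.21), 340: (0.52, 0.13), 360: (0.77, 0.24), 380: (0.58, 0.17),
    400: (0.65, 0.13), 420: (_NA, _NA),
}
_RMSD_ANTIPARALLEL = {
    240: (0.48, 0.10), 260: (0.58, 0.12), 280: (0.55, 0.16), 300: (0.55, 0.12),
    320: (0.46, 0.10), 340: (0.43, 0.09), 360: (0.57, 0.17), 380: (0.57, 0.13),
    400: (0.46, 0.11), 420: (0.71, 0.25),
}


def _contacts_frame(data: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(
        data, orient="index",
        columns=["polar_total", "ionic", "nonspecific", "nonpolar"])
    df.index.name = "n_lipids"
    df["total"] = df["polar_total"] + df["nonspecific"] + df["nonpolar"]
    return df


def apoe3_dmpc_contact_table(mode: str) -> pd.DataFrame:
    """Reported inter-chain contact counts, indexed by total DMPC count.

    Columns: polar_total, ionic, nonspecific, nonpolar, total.
    ``mode`` is "parallel" or "antiparallel".
    """
    if mode == "parallel":
        return _contacts_frame(_CONTACTS_PARALLEL)
    if mode == "antiparallel":
        return _contacts_frame(_CONTACTS_ANTIPARALLEL)
    raise ValueError(f"mode must be parallel/antiparallel, got {mode!r}")


def apoe3_dmpc_rmsd_table() -> pd.DataFrame:
    """Reported backbone RMSD (mean ± sd, nm) per system and configuration."""
    rows = []
    for n in sorted(_RMSD_PARALLEL):
        rows.append({
            "n_lipids": n,
            "parallel_mean": _RMSD_PARALLEL[n][0],
            "parallel_sd": _RMSD_PARALLEL[n][1],
            "antiparallel_mean": _RMSD_ANTIPARALLEL[n][0],
            "antiparallel_sd": _RMSD_ANTIPARALLEL[n][1],
        })
    return pd.DataFrame(rows).set_index("n_lipids")
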