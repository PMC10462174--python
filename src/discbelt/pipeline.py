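"""End-to-end per-system nanodisc analysis and configuration comparison.

``run_analysis`` composes the full workflow on one trajectory — snapshot
window selection, reorientation, density profiles and size metrics, radius
of gyration, SASA, backbone RMSD, inter-chain contacts, order parameters,
escaped-lipid detection — into one machine-readable report.  Stages fail
independently: a metric that cannot be computed (e.g. diameters on a
bilayer patch with no belt) is recorded under ``errors`` without aborting
the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .structure_io import Frame, Trajectory, SystemLabel, select_atoms
from .geometry import (reorient, radius_of_gyration, backbone_rmsd_series,
                       detect_escaped_lipids)
from .density import (mass_density_profile, bilayer_thickness,
                      diameter_from_protein, diameter_from_lipid,
                      average_diameter, linear_trend)
from .sasa import nanodisc_sasa_series
from .contacts import (interchain_contacts, summarize_contacts,
                       configuration_comparison)
from .order import scd_profile, partition_regions, delta_scd

__all__ = [
    "AnalysisConfig",
    "select_analysis_window",
    "run_analysis",
    "compare_configurations",
    "PROTEIN_CHAINS",
]

PROTEIN_CHAINS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-system analysis workflow.

    The defaults mirror the published analysis conditions: the terminal 20%
    of the trajectory sampled at 200 equally spaced snapshots, 100 density
    bins, all-atom water probe (0.14 nm, 48 sphere points), 1 nm contact
    prefilter with 0.4 nm cutoff, 3 nm core radius and 1.4 nm rim distance.
    """

    last_fraction: float = 0.2
    last_n_frames: int | None = None
    n_snapshots: int = 200
    n_bins: int = 100
    probe_profile: str = "AA"
    sasa_sphere_points: int = 48
    contact_prefilter: float = 1.0
    contact_cutoff: float = 0.4
    occupancy_min: float = 0.5
    core_radius: float = 3.0
    rim_distance: float = 1.4
    escape_gap: float = 1.0
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def select_analysis_window(traj: Trajectory, config: AnalysisConfig
                           ) -> Trajectory:
    """n_snapshots frames at equal index spacing from the terminal window.

    The window is the last ``last_n_frames`` frames if set, otherwise the
    last ``last_fraction`` of the trajectory.  Raises ValueError when the
    window holds fewer frames than requested snapshots.
    """
    n = traj.n_frames
    if config.last_n_frames is not None:
        w = config.last_n_frames
    else:
        w = max(1, int(round(config.last_fraction * n)))
    if w > n:
        raise ValueError(f"window of {w} frames exceeds trajectory length {n}")
    n_snap = config.n_snapshots
    if n_snap > w:
        raise ValueError(
            f"{n_snap} snapshots requested from a {w}-frame window")
    start = n - w
    idx = np.unique(np.round(np.linspace(start, n - 1, n_snap)).astype(int))
    frames = [traj.frames[i] for i in idx]
    return Trajectory(frames, traj.times[idx])


def _reorient_all(traj: Trajectory, lipid_sel) -> Trajectory:
    frames = [reorient(f, lipid_sel)[0] for f in traj.frames]
    return Trajectory(frames, traj.times)


def run_analysis(traj: Trajectory, config: AnalysisConfig | None = None,
                 label: SystemLabel | str | None = None) -> dict:
    """Complete analysis report for one nanodisc (or bilayer) trajectory.

    Every stage's numbers carry explicit units in their key names; stages
    that fail are recorded under ``errors`` and the report is flagged
    partial.  Identical trajectory + config yield an identical report.
    """
    config = config or AnalysisConfig()
    report: dict = {
        "label": str(label) if label is not None else None,
        "software_version": __version__,
        "config": config.as_dict(),
        "errors": {},
    }

    def stage(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    window = select_analysis_window(traj, config)
    f0 = window.frames[0]
    phosphates = select_atoms(f0, atom_name="P", residue_name="DMPC")
    if phosphates.size == 0:
        phosphates = select_atoms(f0, atom_name="P")
    lipids = select_atoms(f0, residue_name="DMPC")
    protein = select_atoms(f0, chain=PROTEIN_CHAINS, residue_name="ALA")
    if protein.size == 0:
        protein = np.setdiff1d(np.arange(f0.n_atoms), lipids)

    window = _reorient_all(window, phosphates)
    f0 = window.frames[0]

    def densities():
        out = {}
        prof_z = mass_density_profile(window, phosphates, "z",
                                      n_bins=config.n_bins, label="phosphate")
        out["thickness_nm"] = bilayer_thickness(prof_z)
        return out

    stage("bilayer", densities)

    def diameters():
        out = {}
        if protein.size:
            dx = diameter_from_protein(mass_density_profile(
                window, protein, "x", n_bins=config.n_bins, label="protein"))
            dy = diameter_from_protein(mass_density_profile(
                window, protein, "y", n_bins=config.n_bins, label="protein"))
            est = average_diameter(dx, dy, method="protein_maxima")
            out["protein_maxima"] = {"d_x_nm": est.d_x, "d_y_nm": est.d_y,
                                     "mean_nm": est.mean}
        dx = diameter_from_lipid(mass_density_profile(
            window, lipids, "x", n_bins=config.n_bins, label="lipid"))
        dy = diameter_from_lipid(mass_density_profile(
            window, lipids, "y", n_bins=config.n_bins, label="lipid"))
        est = average_diameter(dx, dy, method="lipid_threshold")
        out["lipid_threshold"] = {"d_x_nm": est.d_x, "d_y_nm": est.d_y,
                                  "mean_nm": est.mean}
        return out

    stage("diameters", diameters)

    stage("radius_of_gyration_nm", lambda: float(np.mean(
        [radius_of_gyration(f, np.arange(f.n_atoms)) for f in window.frames])))

    def sasa_stage():
        mean, _ = nanodisc_sasa_series(
            window, probe_profile=config.probe_profile,
            n_sphere_points=config.sasa_sphere_points)
        return {"mean_nm2": mean, "probe_profile": config.probe_profile}

    stage("sasa", sasa_stage)

    def rmsd_stage():
        if protein.size == 0:
            raise ValueError("no protein chains present")
        backbone = select_atoms(f0, chain=PROTEIN_CHAINS,
                                atom_name=("N", "CA", "C", "O"))
        series = backbone_rmsd_series(window, f0, backbone)
        return {"mean_nm": series.mean, "sd_nm": series.sd,
                "formatted": str(series)}

    stage("rmsd", rmsd_stage)

    def contacts_stage():
        if protein.size == 0:
            raise ValueError("no protein chains present")
        records = interchain_contacts(
            window, prefilter=config.contact_prefilter,
            cutoff=config.contact_cutoff,
            occupancy_min=config.occupancy_min)
        return {"summary": summarize_contacts(records).as_dict(),
                "n_records": len(records)}

    stage("contacts", contacts_stage)

    def order_stage():
        out = {}
        full = scd_profile(window, lipids, region="full")
        out["full"] = full.as_dict()
        if protein.size:
            parts = [partition_regions(f, lipids, protein,
                                       config.core_radius, config.rim_distance)
                     for f in window.frames]
            core = scd_profile(window, lipids, region="core",
                               resid_filter=[p.core for p in parts])
            rim = scd_profile(window, lipids, region="rim",
                              resid_filter=[p.rim for p in parts])
            out["core"] = core.as_dict()
            out["rim"] = rim.as_dict()
        return out

    stage("order_parameters", order_stage)

    stage("escaped_lipids", lambda: detect_escaped_lipids(
        window.frames[-1], max_gap=config.escape_gap))

    report["partial"] = bool(report["errors"])
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _summary_frame(reports: dict[int, dict]) -> pd.DataFrame:
    rows = {}
    for n, rep in reports.items():
        summary = rep.get("contacts", {}).get("summary")
        if summary:
            rows[n] = summary
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "n_lipids"
    return df


def compare_configurations(reports_parallel: dict[int, dict],
                           reports_antiparallel: dict[int, dict],
                           contact_summaries: tuple[pd.DataFrame, pd.DataFrame]
                           | None = None) -> dict:
    """Parallel-vs-antiparallel comparison across matched lipid counts.

    Builds the contact-count ratio table, per-carbon order-parameter
    differences (Delta S_CD = |S(parallel)| - |S(antiparallel)|), a
    side-by-side RMSD table, and linear trends of diameter/SASA/Rg versus
    lipid count.  ``contact_summaries`` may supply pre-computed per-system
    count tables (e.g. published ones) in place of the reports' own.
    """
    common = sorted(set(reports_parallel) & set(reports_antiparallel))
    if not common and contact_summaries is None:
        raise ValueError("no common lipid counts between configurations")
    out: dict = {"common_n_lipids": common}

    if contact_summaries is not None:
        par_df, anti_df = contact_summaries
    else:
        par_df = _summary_frame(reports_parallel)
        anti_df = _summary_frame(reports_antiparallel)
    if len(par_df) and len(anti_df):
        out["contact_comparison"] = configuration_comparison(par_df, anti_df)

    dscd = {}
    for n in common:
        p = reports_parallel[n].get("order_parameters", {}).get("full")
        a = reports_antiparallel[n].get("order_parameters", {}).get("full")
        if p and a and set(p) == set(a):
            dscd[n] = {k: p[k] - a[k] for k in sorted(p)}
    if dscd:
        out["delta_scd_full"] = dscd

    rmsd_rows = []
    for n in sorted(set(reports_parallel) | set(reports_antiparallel)):
        row = {"n_lipids": n}
        for tag, reports in (("parallel", reports_parallel),
                             ("antiparallel", reports_antiparallel)):
            r = reports.get(n, {}).get("rmsd")
            row[tag] = r["formatted"] if r else "-"
        rmsd_rows.append(row)
    if rmsd_rows:
        out["rmsd_table"] = rmsd_rows

    trends = {}
    for metric, getter in (
        ("diameter_protein_mean_nm",
         lambda r: r.get("diameters", {}).get("protein_maxima", {}).get("mean_nm")),
        ("sasa_mean_nm2", lambda r: r.get("sasa", {}).get("mean_nm2")),
        ("radius_of_gyration_nm", lambda r: r.get("radius_of_gyration_nm")),
    ):
        for tag, reports in (("parallel", reports_parallel),
                             ("antiparallel", reports_antiparallel)):
            xs, ys = [], []
            for n, rep in sorted(reports.items()):
                v = getter(rep)
                if v is not None:
                    xs.append(n)
                    ys.append(v)
            if len(xs) >= 2 and len(set(xs)) > 1:
                slope, intercept, r2 = linear_trend(xs, ys)
                trends[f"{metric}_{tag}"] = {
                    "slope": slope, "intercept": intercept, "r2": r2}
    if trends:
        out["linear_trends"] = trends
    return out
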