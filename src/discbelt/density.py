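"""Binned mass-density profiles and density-derived size metrics.

All profiles follow the same recipe: frames (already reoriented so the
bilayer normal is z) are histogrammed along one axis into 100 uniform bins,
masses are converted to kg/m^3 with a fixed per-trajectory slab volume, and
the time average over the supplied frames is taken.  Sizes come from the
profiles: bilayer thickness from the phosphate peak-to-peak distance,
disc diameters either from the outermost protein-density maxima or from
where the lipid density decays to 1 kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .structure_io import Frame, Trajectory

__all__ = [
    "DensityProfile",
    "DiameterEstimate",
    "mass_density_profile",
    "symmetrize_profile",
    "bilayer_thickness",
    "diameter_from_protein",
    "diameter_from_lipid",
    "average_diameter",
    "linear_trend",
    "AMU_PER_NM3_TO_KG_PER_M3",
]

# 1 amu/nm^3 = 1.66053906660e-27 kg / 1e-27 m^3
AMU_PER_NM3_TO_KG_PER_M3 = 1.66053906660

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class DensityProfile:
    """Mass density (kg/m^3) in uniform bins along one axis (nm)."""

    axis: str
    bin_edges: np.ndarray         # n_bins + 1 edges, nm
    density: np.ndarray           # kg/m^3 per bin
    source_selection: str = ""
    cross_section_nm2: float = float("nan")  # slab cross-section used

    def __post_init__(self):
        if len(self.bin_edges) != len(self.density) + 1:
            raise ValueError("bin_edges must have len(density)+1 entries")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_mass_amu(self) -> float:
        """Integral of the profile times slab volume, back in amu."""
        vol = self.bin_width * self.cross_section_nm2
        return float(self.density.sum() * vol / AMU_PER_NM3_TO_KG_PER_M3)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"bin_center_nm": self.bin_centers,
                      "density_kg_m3": self.density}).to_csv(path, index=False)


@dataclass(frozen=True)
class DiameterEstimate:
    """Disc diameter along x and y plus their mean (nm).

    By the major-axis-along-x reorientation convention, d_x is the major
    and d_y the minor axis (the errorbar convention for elliptical discs).
    """

    d_x: float
    d_y: float
    method: str  # "protein_maxima" | "lipid_threshold"

    @property
    def mean(self) -> float:
        return 0.5 * (self.d_x + self.d_y)

    @property
    def major(self) -> float:
        return max(self.d_x, self.d_y)

    @property
    def minor(self) -> float:
        return min(self.d_x, self.d_y)


def mass_density_profile(traj: Trajectory | Frame, selection: np.ndarray,
                         axis: str, n_bins: int = 100,
                         extent: tuple[float, float] | None = None,
                         cross_section_nm2: float | None = None,
                         label: str = "") -> DensityProfile:
    """Time-averaged mass density (kg/m^3) of a selection along one axis.

    The slab volume for the unit conversion is bin width times a fixed
    cross-section: by default the bounding-box area of the *full* system in
    the orthogonal plane (frame 0), held constant over the trajectory.
    ``extent`` defaults to the full-system bounding box +-1 nm margin.
    """
    if isinstance(traj, Frame):
        traj = Trajectory([traj])
    idx = np.asarray(selection, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("mass_density_profile needs a non-empty selection")
    ax = _AXIS[axis]
    others = [d for d in range(3) if d != ax]

    all_pos0 = traj.frames[0].positions
    if extent is None:
        lo = float(all_pos0[:, ax].min() - 1.0)
        hi = float(all_pos0[:, ax].max() + 1.0)
    else:
        lo, hi = map(float, extent)
    if cross_section_nm2 is None:
        spans = all_pos0[:, others].max(axis=0) - all_pos0[:, others].min(axis=0)
        cross_section_nm2 = float(np.prod(np.maximum(spans, 1e-9)))

    edges = np.linspace(lo, hi, n_bins + 1)
    masses = traj.frames[0].masses[idx]
    acc = np.zeros(n_bins)
    for frame in traj.frames:
        coords = frame.positions[idx, ax]
        hist, _ = np.histogram(coords, bins=edges, weights=masses)
        acc += hist
    mass_per_bin = acc / traj.n_frames  # amu
    bin_vol = (edges[1] - edges[0]) * cross_section_nm2
    density = mass_per_bin / bin_vol * AMU_PER_NM3_TO_KG_PER_M3
    return DensityProfile(axis=axis, bin_edges=edges, density=density,
                          source_selection=label,
                          cross_section_nm2=cross_section_nm2)


def symmetrize_profile(profile: DensityProfile, center: float) -> DensityProfile:
    """Mirror-average the profile about ``center``.

    Bins are paired index-wise around the bin nearest the requested center
    (so the operation is exactly idempotent on the grid); the effective
    center therefore snaps by at most half a bin width.  Bins whose mirror
    falls outside the profile are left unchanged.
    """
    centers = profile.bin_centers
    if not (profile.bin_edges[0] <= center <= profile.bin_edges[-1]):
        raise ValueError("center must lie within the profile extent")
    kc = int(np.argmin(np.abs(centers - center)))
    d = profile.density.copy()
    n = len(d)
    for m in range(1, n):
        i, j = kc - m, kc + m
        if i < 0 or j >= n:
            break
        avg = 0.5 * (d[i] + d[j])
        d[i] = d[j] = avg
    return replace(profile, density=d)


def _local_maxima(y: np.ndarray, min_rel_height: float = 0.0) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of y (interior bins).

    ``min_rel_height`` discards maxima below that fraction of the global
    maximum — shot-noise bins in sparse profile tails would otherwise
    register as peaks.
    """
    idx = []
    n = len(y)
    floor = min_rel_height * y.max() if n else 0.0
    for k in range(1, n - 1):
        if y[k] < floor:
            continue
        left = y[k] - y[k - 1]
        right = y[k] - y[k + 1]
        if left > 0 and right > 0:
            idx.append(k)
        elif left > 0 and right == 0:
            # plateau: accept the left edge of a plateau that later drops
            j = k + 1
            while j < n - 1 and y[j + 1] == y[k]:
                j += 1
            if j < n - 1 and y[j + 1] < y[k]:
                idx.append(k)
    return np.array(idx, dtype=int)


def _parabolic_peak(centers: np.ndarray, y: np.ndarray, k: int) -> float:
    """Refine the peak-bin position by a 3-point parabola vertex."""
    if k == 0 or k == len(y) - 1:
        return float(centers[k])
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    if denom >= 0:  # flat or non-concave: keep the bin center
        return float(centers[k])
    h = centers[1] - centers[0]
    return float(centers[k] + 0.5 * h * (y[k - 1] - y[k + 1]) / denom)


def bilayer_thickness(phosphate_profile_z: DensityProfile,
                      center: float | None = None) -> float:
    """Peak-to-peak distance (nm) of the symmetrized phosphate z-profile.

    Raises ValueError if the profile does not show one peak on each side of
    the center ("not a bilayer").
    """
    prof = phosphate_profile_z
    centers = prof.bin_centers
    if center is None:
        total = prof.density.sum()
        if total <= 0:
            raise ValueError("empty phosphate profile")
        center = float(centers @ prof.density / total)
    prof = symmetrize_profile(prof, center)
    y = prof.density
    # a real phosphate peak is comparable to the profile maximum; the 20%
    # floor keeps noise wiggles of a monolayer from mimicking a second peak
    maxima = _local_maxima(y, min_rel_height=0.2)
    left = [k for k in maxima if centers[k] < center]
    right = [k for k in maxima if centers[k] > center]
    if not left or not right:
        raise ValueError("not a bilayer: need phosphate peaks on both sides of center")
    kl = max(left, key=lambda k: y[k])
    kr = max(right, key=lambda k: y[k])
    # two genuine leaflet peaks are separated by a phosphate-free valley at
    # the membrane center; a monolayer's noise maxima are not
    valley = y[kl:kr + 1].min()
    if valley > 0.5 * min(y[kl], y[kr]):
        raise ValueError("not a bilayer: no density valley between the peaks")
    return _parabolic_peak(centers, y, kr) - _parabolic_peak(centers, y, kl)


def diameter_from_protein(protein_profile: DensityProfile) -> float:
    """Distance (nm) between the outermost maxima of the protein profile."""
    y = protein_profile.density
    centers = protein_profile.bin_centers
    maxima = _local_maxima(y, min_rel_height=0.05)
    if len(maxima) < 2:
        raise ValueError("protein profile needs at least two local maxima")
    return (_parabolic_peak(centers, y, maxima[-1])
            - _parabolic_peak(centers, y, maxima[0]))


def diameter_from_lipid(lipid_profile: DensityProfile,
                        threshold: float = 1.0) -> float:
    """Extent (nm) between the outermost crossings of a density threshold.

    The default 1 kg/m^3 threshold marks where the lipid density has
    effectively decayed to zero.  Crossing positions are linearly
    interpolated between bin centers.
    """
    y = lipid_profile.density
    centers = lipid_profile.bin_centers
    above = np.flatnonzero(y > threshold)
    if above.size == 0:
        raise ValueError(f"profile never exceeds the {threshold} kg/m^3 threshold")
    i0, i1 = above[0], above[-1]

    def cross(k_in, k_out):
        if k_out < 0 or k_out >= len(y):
            return float(centers[k_in])
        y_in, y_out = y[k_in], y[k_out]
        if y_in == y_out:
            return float(centers[k_in])
        f = (y_in - threshold) / (y_in - y_out)
        return float(centers[k_in] + f * (centers[k_out] - centers[k_in]))

    left = cross(i0, i0 - 1)
    right = cross(i1, i1 + 1)
    return right - left


def average_diameter(d_x: float, d_y: float, method: str = "") -> DiameterEstimate:
    """Combine per-axis diameters into a DiameterEstimate (mean of x and y)."""
    if d_x <= 0 or d_y <= 0:
        raise ValueError("diameters must be positive")
    return DiameterEstimate(d_x=float(d_x), d_y=float(d_y), method=method)


def linear_trend(n_lipids, metric) -> tuple[float, float, float]:
    """Ordinary least-squares fit metric ~ n_lipids: (slope, intercept, r^2)."""
    x = np.asarray(n_lipids, dtype=float)
    y = np.asarray(metric, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all n_lipids identical")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
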