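"""Arc-length mapping, digital straightening and damage-cluster detection.

Tissue cross-sections bend during processing; every nucleus is therefore
mapped to (arc length ``s`` along a fitted centerline, signed normal offset
``d``).  The centerline is a low-order polynomial fitted through the
nucleus point cloud after a principal-axis rotation, anchored at the left
end of the section.  Clusters of heavily damaged (pan-γ-H2AX) cells are
located by a 1D Gaussian kernel density over ``s`` and peak picking, which
recovers the beam center-to-center spacing for narrow minibeams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic_tissue import SectionDataset

__all__ = [
    "Centerline",
    "DamagePeakSet",
    "fit_centerline",
    "straighten",
    "detect_damage_peaks",
    "region_profile",
    "plot_damage_map",
]


@dataclass
class Centerline:
    """Smooth centerline of a (possibly bent) tissue section.

    The curve lives in a rotated frame: ``rotation`` maps original (x, y)
    to (u, v) about ``center``, and ``coeffs`` are polynomial coefficients
    of v(u).  A dense arc-length lookup table supports projection.
    """

    center: np.ndarray  # (2,)
    rotation: np.ndarray  # (2, 2), rows are the new basis vectors
    coeffs: np.ndarray  # polynomial v(u), numpy polyval convention
    u_range: tuple[float, float]
    u_grid: np.ndarray = field(repr=False)
    s_grid: np.ndarray = field(repr=False)  # arc length from the left anchor

    @property
    def arc_length(self) -> float:
        return float(self.s_grid[-1])

    def curve_uv(self, u: np.ndarray) -> np.ndarray:
        return np.polyval(self.coeffs, u)

    def to_xy(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        pts = np.stack([u, v], axis=-1) @ self.rotation + self.center
        return pts


def fit_centerline(
    points: np.ndarray,
    degree: int = 5,
    n_grid: int = 4000,
    min_points: int = 50,
) -> Centerline:
    """Fit a smooth centerline through a nucleus point cloud.

    The cloud is rotated onto its principal axis, a polynomial of the given
    degree is least-squares fitted to the transverse coordinate, and arc
    length is accumulated on a dense grid.  The arc-length origin (anchor)
    is the left end of the section, matching the convention of annotating
    the left end of each cross-section.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < min_points:
        raise ValueError(f"need at least {min_points} nuclei to fit a centerline")
    center = pts.mean(axis=0)
    q = pts - center
    _, svals, vt = np.linalg.svd(q, full_matrices=False)
    if svals[0] < 1e-9:
        raise ValueError("degenerate point cloud: all nuclei in a single clump")
    axis = vt[0]
    # orient u to increase with original x so the anchor is the left end
    if axis[0] < 0:
        axis = -axis
    normal = np.array([-axis[1], axis[0]])
    rotation = np.stack([axis, normal])  # rows: principal axis, left normal
    uv = q @ rotation.T
    u, v = uv[:, 0], uv[:, 1]
    if u.max() - u.min() < 1e-9:
        raise ValueError("degenerate point cloud: all nuclei in a single clump")
    deg = min(degree, max(len(pts) // 20, 1))
    coeffs = np.polyfit(u, v, deg)
    u_grid = np.linspace(u.min(), u.max(), n_grid)
    v_grid = np.polyval(coeffs, u_grid)
    seg = np.hypot(np.diff(u_grid), np.diff(v_grid))
    s_grid = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(
        center=center,
        rotation=rotation,
        coeffs=coeffs,
        u_range=(float(u.min()), float(u.max())),
        u_grid=u_grid,
        s_grid=s_grid,
    )


def _project(centerline: Centerline, pts_xy: np.ndarray):
    """Project points onto the centerline: arc length s and signed offset d."""
    q = (pts_xy - centerline.center) @ centerline.rotation.T
    u_grid = centerline.u_grid
    v_grid = centerline.curve_uv(u_grid)
    # derivative for tangent/normal
    dcoeffs = np.polyder(centerline.coeffs)
    clamped = np.zeros(len(q), dtype=bool)
    s_out = np.empty(len(q))
    d_out = np.empty(len(q))
    for i, (pu, pv) in enumerate(q):
        d2 = (u_grid - pu) ** 2 + (v_grid - pv) ** 2
        j = int(np.argmin(d2))
        # local quadratic refinement of the foot point in u
        if 0 < j < len(u_grid) - 1:
            y0, y1, y2 = d2[j - 1], d2[j], d2[j + 1]
            denom = y0 - 2 * y1 + y2
            du = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
            u_star = u_grid[j] + du * (u_grid[1] - u_grid[0])
        else:
            u_star = u_grid[j]
            clamped[i] = True
        u_star = min(max(u_star, u_grid[0]), u_grid[-1])
        v_star = np.polyval(centerline.coeffs, u_star)
        slope = np.polyval(dcoeffs, u_star) if len(dcoeffs) else 0.0
        tnorm = math.hypot(1.0, slope)
        # left-handed normal of tangent (1, slope)
        nx, ny = -slope / tnorm, 1.0 / tnorm
        d_out[i] = (pu - u_star) * nx + (pv - v_star) * ny
        s_out[i] = float(np.interp(u_star, u_grid, centerline.s_grid))
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} nuclei projected beyond the centerline ends were clamped"
        )
    return s_out, d_out


def straighten(
    section: SectionDataset,
    centerline: Centerline | None = None,
    degree: int = 5,
) -> SectionDataset:
    """Map every nucleus to (arc length ``s_um``, normal offset ``d_um``).

    A geometry-only transform: nucleus count and all damage attributes are
    preserved exactly; focus coordinates are projected with the same
    centerline.  On an already-straight section the mapping reduces to a
    shift of the x origin to the left anchor.
    """
    nuclei = section.nuclei.copy()
    pts = nuclei[["x_um", "y_um"]].to_numpy()
    if centerline is None:
        centerline = fit_centerline(pts, degree=degree)
    s, d = _project(centerline, pts)
    nuclei["s_um"] = s
    nuclei["d_um"] = d
    foci = section.foci.copy()
    if len(foci):
        fs, fd = _project(centerline, foci[["x_um", "y_um"]].to_numpy())
        foci["s_um"] = fs
        foci["d_um"] = fd
    meta = dict(section.meta)
    meta["straightened"] = True
    meta["centerline_arc_length_um"] = centerline.arc_length
    return replace(section, nuclei=nuclei, foci=foci, meta=meta)


@dataclass
class DamagePeakSet:
    """Detected clusters of pan-γ-H2AX cells along the straightened section."""

    positions: np.ndarray  # µm, sorted
    heights: np.ndarray  # KDE density at each peak, cells/µm
    spacings: np.ndarray  # adjacent inter-peak distances, µm
    bandwidth: float

    @property
    def n_peaks(self) -> int:
        return len(self.positions)

    @property
    def mean_spacing(self) -> float:
        return float(self.spacings.mean()) if len(self.spacings) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        spac = np.concatenate([[np.nan], self.spacings]) if len(self.positions) else np.array([])
        return pd.DataFrame(
            {"s_um": self.positions, "height": self.heights, "spacing_um": spac}
        )


def detect_damage_peaks(
    section: SectionDataset,
    bandwidth: float = 150.0,
    prominence_factor: float = 3.0,
    grid_step: float | None = None,
) -> DamagePeakSet:
    """Locate clusters of pan-positive cells by 1D kernel density.

    A Gaussian kernel of width ``bandwidth`` µm is summed over pan-positive
    positions (count-scaled, units cells/µm); local maxima whose density
    exceeds ``prominence_factor`` × the section-wide mean pan density are
    reported as damage peaks.  The factor suppresses the scattered
    pan-γ-H2AX cells of late repair times while keeping true beam-track
    clusters, whose local density is many-fold the mean.
    """
    nuclei = section.nuclei
    if "pan_gh2ax" not in nuclei.columns:
        raise ValueError("section has no pan_gh2ax flags")
    s_col = "s_um" if "s_um" in nuclei.columns else "x_um"
    pos = nuclei.loc[nuclei["pan_gh2ax"].astype(bool), s_col].to_numpy(float)
    if len(pos) == 0:
        return DamagePeakSet(
            positions=np.array([]), heights=np.array([]), spacings=np.array([]), bandwidth=bandwidth
        )
    extent = section.spec.section_length if section.spec is not None else float(
        nuclei[s_col].max() - nuclei[s_col].min()
    )
    if grid_step is None:
        grid_step = bandwidth / 10.0
    lo = float(nuclei[s_col].min())
    hi = float(nuclei[s_col].max())
    grid = np.arange(lo - 2 * bandwidth, hi + 2 * bandwidth, grid_step)
    density = np.zeros_like(grid)
    norm = 1.0 / (bandwidth * math.sqrt(2 * math.pi))
    for p in pos:
        density += norm * np.exp(-((grid - p) ** 2) / (2 * bandwidth**2))
    mean_density = len(pos) / extent
    floor = prominence_factor * mean_density
    idx, _ = find_peaks(density, height=floor)
    positions = grid[idx]
    heights = density[idx]
    order = np.argsort(positions)
    positions, heights = positions[order], heights[order]
    return DamagePeakSet(
        positions=positions,
        heights=heights,
        spacings=np.diff(positions),
        bandwidth=bandwidth,
    )


def region_profile(
    section: SectionDataset,
    bin_width: float = 250.0,
    peaks: DamagePeakSet | None = None,
    streak_sigma: float | None = None,
    valley_margin: float = 300.0,
) -> tuple[pd.DataFrame, dict]:
    """Binned damage profile along the straightened section.

    Returns a per-bin table (n cells, % cells with foci, mean foci per
    cell, pan count) and a valley-region summary computed over bins farther
    than ``3·streak_sigma + valley_margin`` µm from every detected peak —
    the statistic used to assess sparing of the inter-beam tissue.
    """
    nuclei = section.nuclei
    s_col = "s_um" if "s_um" in nuclei.columns else "x_um"
    length = section.spec.section_length if section.spec is not None else float(
        nuclei[s_col].max()
    )
    if bin_width > length:
        raise ValueError("bin wider than the section")
    edges = np.arange(0.0, length + bin_width, bin_width)
    s = nuclei[s_col].to_numpy(float)
    which = np.clip(np.digitize(s, edges) - 1, 0, len(edges) - 2)
    any_focus = (nuclei["foci_53bp1"].to_numpy() + nuclei["foci_gh2ax"].to_numpy()) > 0
    total_foci = nuclei["foci_53bp1"].to_numpy() + nuclei["foci_gh2ax"].to_numpy()
    pan = nuclei["pan_gh2ax"].to_numpy(bool)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = which == b
        n = int(in_bin.sum())
        rows.append(
            {
                "bin_start_um": edges[b],
                "bin_end_um": edges[b + 1],
                "n_cells": n,
                "pct_cwf": 100.0 * float(any_focus[in_bin].mean()) if n else np.nan,
                "mean_foci_per_cell": float(total_foci[in_bin].mean()) if n else np.nan,
                "n_pan": int(pan[in_bin].sum()),
            }
        )
    profile = pd.DataFrame(rows)

    if peaks is None:
        peaks = detect_damage_peaks(section)
    if streak_sigma is None:
        try:
            streak_sigma = float(section.geometry_label)
        except (TypeError, ValueError):
            streak_sigma = peaks.bandwidth
    exclusion = 3.0 * streak_sigma + valley_margin
    centers = (edges[:-1] + edges[1:]) / 2.0
    if peaks.n_peaks:
        dist = np.min(np.abs(centers[:, None] - peaks.positions[None, :]), axis=1)
        valley_bins = dist > exclusion
    else:
        valley_bins = np.ones(len(centers), dtype=bool)
    profile["valley"] = valley_bins
    in_valley = valley_bins[which]
    n_valley = int(in_valley.sum())
    valley_summary = {
        "n_cells": n_valley,
        "pct_cwf": 100.0 * float(any_focus[in_valley].mean()) if n_valley else float("nan"),
        "mean_foci_per_cell": float(total_foci[in_valley].mean()) if n_valley else float("nan"),
        "n_pan": int(pan[in_valley].sum()),
        "exclusion_um": exclusion,
    }
    return profile, valley_summary


def plot_damage_map(section: SectionDataset, path=None, peaks: DamagePeakSet | None = None):
    """Bar map of per-cell focus counts and pan cells along the section."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nuclei = section.nuclei
    s_col = "s_um" if "s_um" in nuclei.columns else "x_um"
    fig, ax = plt.subplots(figsize=(10, 3))
    foci = nuclei["foci_53bp1"] + nuclei["foci_gh2ax"]
    ax.vlines(nuclei[s_col], 0, foci, color="firebrick", lw=0.6, label="DSB foci per cell")
    pan = nuclei[nuclei["pan_gh2ax"].astype(bool)]
    if len(pan):
        ax.vlines(pan[s_col], 0, foci.max() if foci.max() > 0 else 1, color="steelblue",
                  lw=0.6, alpha=0.6, label="pan-γH2AX cell")
    if peaks is not None and peaks.n_peaks:
        for p in peaks.positions:
            ax.axvline(p, color="k", ls="--", lw=0.8)
    ax.set_xlabel("arc-length position s (µm)")
    ax.set_ylabel("foci per cell")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig, ax
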