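"""Pseudotime reconstruction and pseudo-temporal particle averages.

Static snapshots are ordered by closing angle: since θ increases
monotonically during endocytosis, the rank of a site among all sites
is its relative (pseudo) time point.  Flat sites (θ set to 0) share
rank 0.  Rolling medians, equal-count binning, per-bin alignment /
rescaling / 72-fold rotational averaging and a sliding-window movie
reproduce the trajectory and average-structure outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .sites import SiteRecord

__all__ = [
    "assign_pseudotime",
    "rolling_median",
    "bin_equal_counts",
    "AverageBin",
    "align_rescale_average",
    "sliding_window_movie",
]


def assign_pseudotime(records: list[SiteRecord]) -> pd.DataFrame:
    """Rank-normalized pseudotime table from fitted sites.

    Excluded (disconnected) sites must be removed upstream.  Sites are
    stably sorted by θ with ties broken by ``site_id``; every flat
    site receives rank 0, curved sites count upward from there, and
    ``t = rank / max_rank`` maps ranks to [0, 1].
    """
    rows = [(r.site_id, r.theta, r.flat) for r in records if not r.excluded]
    if not rows:
        return pd.DataFrame(columns=["site_id", "theta", "rank", "t"])
    df = pd.DataFrame(rows, columns=["site_id", "theta", "flat"])
    df = df.sort_values(["theta", "site_id"], kind="stable").reset_index(drop=True)
    n_flat = int(df["flat"].sum())
    ranks = np.zeros(len(df), dtype=int)
    curved = ~df["flat"].to_numpy()
    start = 1 if n_flat else 0
    ranks[curved] = np.arange(start, start + curved.sum())
    df["rank"] = ranks
    max_rank = ranks.max()
    df["t"] = ranks / max_rank if max_rank > 0 else 0.0
    return df.drop(columns="flat")


def rolling_median(values, window: int | None = None, frac: float = 0.05) -> np.ndarray:
    """Centered rolling median with truncated boundary windows.

    ``window`` is an absolute site count; if omitted it defaults to
    ``frac`` of the series length (at least 1).  A window larger than
    the series collapses to the global median with a warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if window is None:
        window = max(int(round(frac * n)), 1)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        warnings.warn(f"window {window} exceeds series length {n}; using global median")
        return np.full(n, np.median(values)) if n else values
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def bin_equal_counts(table: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Partition the pseudotime table into equal-count contiguous bins.

    Each bin holds ``floor(N / n_bins)`` sites in t-order; the trailing
    remainder (highest t) is dropped with a warning and marked with
    bin index −1.
    """
    n = len(table)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"cannot form {n_bins} bins from {n} sites")
    per_bin = n // n_bins
    out = table.sort_values(["t", "site_id"], kind="stable").reset_index(drop=True)
    idx = np.arange(n) // per_bin
    idx[idx >= n_bins] = -1
    dropped = int(np.sum(idx == -1))
    if dropped:
        warnings.warn(f"dropping {dropped} trailing sites to equalize {n_bins} bins")
    out["bin"] = idx
    return out


@dataclass
class AverageBin:
    """Rotationally averaged 3D rendering of one pseudotime bin."""

    volume: np.ndarray
    voxel_nm: float
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    median_radius: float
    median_t: float
    n_sites: int
    rotations: int
    step_deg: float
    meta: dict = field(default_factory=dict)


def _site_aligned_points(rec: SiteRecord, locs: pd.DataFrame, scale: float) -> np.ndarray:
    """Localizations in the site's model frame: sphere center at the
    origin, symmetry axis along +z, coordinates scaled by ``scale``."""
    f = rec.fit
    X = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    X = X - np.asarray(f.sphere_center)
    axis = f.axis
    # rotation taking axis -> +z (inverse of the axis rotation)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(v) < 1e-14:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return scale * (X @ rot.T)


def align_rescale_average(
    records: list[SiteRecord],
    loc_tables: dict[int, pd.DataFrame],
    rotations: int = 72,
    step_deg: float = 5.0,
    render_sigma_nm: float = 3.0,
    voxel_nm: float = 5.0,
    box_nm: float | None = None,
    median_t: float = float("nan"),
) -> AverageBin:
    """Aligned, rescaled, rotationally averaged rendering of a site bin.

    Every converged site is translated so its fitted sphere center is
    at the origin, rotated so its fitted axis points along +z and
    isotropically rescaled to the bin's median radius.  The pooled
    localizations are duplicated at ``rotations`` azimuthal steps of
    ``step_deg`` and rendered into a voxel volume smoothed with a
    Gaussian of ``render_sigma_nm``.
    """
    usable = [r for r in records if r.fit.converged]
    skipped = len(records) - len(usable)
    if skipped:
        warnings.warn(f"skipping {skipped} non-converged sites in average")
    if not usable:
        raise ValueError("no converged sites to average")
    med_r = float(np.median([r.fit.r for r in usable]))
    pooled = []
    for rec in usable:
        pts = _site_aligned_points(rec, loc_tables[rec.site_id], med_r / rec.fit.r)
        pooled.append(pts)
    pts = np.vstack(pooled)
    angles = np.radians(step_deg) * np.arange(rotations)
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    x = cos_a[:, None] * pts[:, 0] - sin_a[:, None] * pts[:, 1]
    y = sin_a[:, None] * pts[:, 0] + cos_a[:, None] * pts[:, 1]
    z = np.broadcast_to(pts[:, 2], x.shape)
    all_pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    if box_nm is None:
        box_nm = 2.2 * med_r
    nvox = max(int(np.ceil(2 * box_nm / voxel_nm)), 2)
    edges = [np.linspace(-box_nm, box_nm, nvox + 1)] * 3
    vol, _ = np.histogramdd(all_pts, bins=edges)
    vol = ndimage.gaussian_filter(vol, sigma=render_sigma_nm / voxel_nm)
    return AverageBin(
        volume=vol,
        voxel_nm=voxel_nm,
        edges=tuple(np.asarray(e) for e in edges),
        median_radius=med_r,
        median_t=median_t,
        n_sites=len(usable),
        rotations=rotations,
        step_deg=step_deg,
        meta={"n_localizations": int(len(pts))},
    )


def sliding_window_movie(
    table: pd.DataFrame,
    records: list[SiteRecord],
    loc_tables: dict[int, pd.DataFrame],
    window: int = 30,
    increment: int = 20,
    **render_kw,
) -> list[AverageBin]:
    """Sliding-window pseudotime movie frames.

    Frames cover ranks ``[0, window)``, ``[increment, increment +
    window)``, ...; each frame is the rotational average of its member
    sites labeled with their median pseudotime.
    """
    n = len(table)
    if n < window:
        raise ValueError(f"need at least window={window} sites, got {n}")
    by_id = {r.site_id: r for r in records}
    ordered = table.sort_values(["t", "site_id"], kind="stable").reset_index(drop=True)
    frames = []
    start = 0
    while start + window <= n:
        sub = ordered.iloc[start : start + window]
        recs = [by_id[s] for s in sub["site_id"]]
        frames.append(
            align_rescale_average(
                recs,
                loc_tables,
                median_t=float(sub["t"].median()),
                **render_kw,
            )
        )
        start += increment
    return frames
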