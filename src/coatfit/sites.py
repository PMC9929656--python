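"""Site detection, ROI extraction and population QC flags.

A field of localizations is rendered as a 2D histogram (10 nm pixels),
blurred with a 100 nm Gaussian and thresholded to detect candidate
coat positions; each candidate is cropped to a cylindrical ROI.  After
cap fitting, the population is flagged: *flat* sites (non-positive
signed curvature, set to H = 0, θ = 0), the *disconnected*
high-curvature population of non-endocytic structures (strictly above
a cell-line specific curvature threshold) and a report-only heuristic
for upside-down sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .capfit import CapFitResult, flatten_if_negative
from .geometry import CapGeometry, derive_geometry

__all__ = [
    "DISCONNECTED_H_THRESHOLDS",
    "SiteRecord",
    "detect_sites",
    "crop_roi",
    "flag_disconnected",
    "records_to_frame",
]

#: curvature thresholds (nm^-1) above which sites belong to the
#: disconnected, non-endocytic population
DISCONNECTED_H_THRESHOLDS = {"SK-MEL-2": 0.016, "U2OS": 0.013, "3T3": 0.014}


@dataclass
class SiteRecord:
    """One fitted site with derived geometry and QC flags."""

    site_id: int
    fit: CapFitResult
    H: float = 0.0
    theta: float = 0.0
    geometry: CapGeometry | None = None
    flat: bool = False
    disconnected: bool = False
    excluded: bool = False
    upside_down: bool = False
    cell_id: str | None = None
    cell_line: str | None = None

    @classmethod
    def from_fit(cls, site_id: int, fit: CapFitResult, **kw) -> "SiteRecord":
        """Build a record, applying the flat-site rule to the fit."""
        H, theta, flat = flatten_if_negative(fit)
        geom = derive_geometry(fit.A, theta) if not flat else None
        upside = math.cos(fit.axis_polar) < 0.0 and not flat
        return cls(
            site_id=site_id,
            fit=fit,
            H=H,
            theta=theta,
            geometry=geom,
            flat=flat,
            upside_down=upside,
            **kw,
        )


def detect_sites(
    locs: pd.DataFrame,
    blur_sigma_nm: float = 100.0,
    peak_threshold: float | None = None,
    render_pixel_nm: float = 10.0,
) -> np.ndarray:
    """Detect coat positions in a localization field.

    Renders the lateral localization density at ``render_pixel_nm``,
    blurs with a Gaussian of ``blur_sigma_nm`` and finds local maxima
    above ``peak_threshold`` (default: Otsu threshold of the blurred
    image, a documented stand-in for a manually chosen level).
    Maxima closer than ``2 * blur_sigma_nm`` are merged to their
    centroid.  Returns an (n, 2) array of x/y centers in nm.
    """
    if len(locs) == 0:
        return np.empty((0, 2))
    x = locs["x_nm"].to_numpy(dtype=float)
    y = locs["y_nm"].to_numpy(dtype=float)
    x0, y0 = x.min() - 3 * blur_sigma_nm, y.min() - 3 * blur_sigma_nm
    x1, y1 = x.max() + 3 * blur_sigma_nm, y.max() + 3 * blur_sigma_nm
    nx = max(int(np.ceil((x1 - x0) / render_pixel_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / render_pixel_nm)), 1)
    img, xe, ye = np.histogram2d(x, y, bins=(nx, ny), range=((x0, x1), (y0, y1)))
    img = ndimage.gaussian_filter(img, sigma=blur_sigma_nm / render_pixel_nm)
    if peak_threshold is None:
        if img.max() <= 0:
            return np.empty((0, 2))
        peak_threshold = threshold_otsu(img)
    peaks = peak_local_max(
        img, threshold_abs=peak_threshold, min_distance=max(int(blur_sigma_nm / render_pixel_nm), 1)
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    centers = np.column_stack(
        [x0 + (peaks[:, 0] + 0.5) * render_pixel_nm, y0 + (peaks[:, 1] + 0.5) * render_pixel_nm]
    )
    return _merge_close(centers, 2.0 * blur_sigma_nm)


def _merge_close(centers: np.ndarray, min_dist: float) -> np.ndarray:
    """Greedy agglomeration of detections closer than ``min_dist``."""
    merged: list[list[np.ndarray]] = []
    for c in centers:
        for group in merged:
            if np.linalg.norm(np.mean(group, axis=0) - c) < min_dist:
                group.append(c)
                break
        else:
            merged.append([c])
    return np.array([np.mean(g, axis=0) for g in merged])


def crop_roi(
    locs: pd.DataFrame,
    center,
    radius_nm: float = 300.0,
    site_id: int | None = None,
) -> pd.DataFrame:
    """Localizations within a lateral distance ``radius_nm`` of ``center``."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    cx, cy = float(center[0]), float(center[1])
    d = np.hypot(locs["x_nm"] - cx, locs["y_nm"] - cy)
    out = locs.loc[d <= radius_nm].copy().reset_index(drop=True)
    if site_id is not None:
        out["site_id"] = site_id
    return out


def flag_disconnected(records: list[SiteRecord], H_threshold: float) -> list[SiteRecord]:
    """Flag the disconnected (non-endocytic) high-curvature population.

    A site is disconnected iff its curvature lies strictly above the
    cell-line threshold; disconnected sites are excluded from growth
    fitting and pseudotime.  Flat sites stay included (they enter
    pseudotime at rank 0).  Idempotent.
    """
    if H_threshold <= 0:
        raise ValueError("H_threshold must be positive")
    for rec in records:
        rec.disconnected = rec.H > H_threshold
        rec.excluded = rec.disconnected
    return records


def records_to_frame(records: list[SiteRecord]) -> pd.DataFrame:
    """Site table with fitted parameters, derived geometry and flags."""
    rows = []
    for rec in records:
        f = rec.fit
        rows.append(
            {
                "site_id": rec.site_id,
                "A_nm2": f.A,
                "theta_deg": math.degrees(rec.theta),
                "r_nm": f.r,
                "H_per_nm": rec.H,
                "x0": f.x0,
                "y0": f.y0,
                "z0": f.z0,
                "axis_polar_deg": math.degrees(f.axis_polar),
                "axis_azimuth_deg": math.degrees(f.axis_azimuth),
                "w_bg": f.w_bg,
                "sigma_extra_nm": f.sigma_extra,
                "loglik": f.log_likelihood,
                "n_locs": f.n_localizations,
                "converged": f.converged,
                "flat": rec.flat,
                "disconnected": rec.disconnected,
                "excluded": rec.excluded,
                "upside_down": rec.upside_down,
                "cell_id": rec.cell_id,
                "cell_line": rec.cell_line,
            }
        )
    return pd.DataFrame(rows)
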