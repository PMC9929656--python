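"""Maximum-likelihood spherical-cap fitting of localization point clouds.

The coat model is a spherical cap discretized into M quasi-uniform
surface points that act as putative fluorophore positions.  Each
localization i contributes the mixture density

    p_i = (1 - w_bg) * (1/M) * sum_m N3(x_i | p_m, Sigma_i)  +  w_bg / V_roi

where ``Sigma_i`` is diagonal with variances ``sigma_xy_i^2 +
sigma_extra^2`` laterally and ``sigma_z_i^2 + sigma_extra^2`` axially.
The isotropic ``sigma_extra`` absorbs coat thickness, antibody
displacement and residual blur; ``w_bg`` is the weight of a uniform
background over the padded bounding box of the localizations.

The fit maximizes the summed log density over nine parameters: sphere
center (3), log radius, closing angle, axis polar/azimuth and the two
nuisance parameters, using a derivative-free simplex started from a
grid of closing angles.  Internally the cap is parametrized by the
sphere center; the reported position is the cap surface centroid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .geometry import cap_area, cap_centroid_offset, sample_cap_points
from .simulate import _rotation_to_axis

__all__ = [
    "CapFitOptions",
    "CapFitResult",
    "SphericalCapEstimator",
    "build_cap_density",
    "fit_cap",
    "flatten_if_negative",
]

_LOG_2PI = math.log(2.0 * math.pi)

try:  # optional acceleration; the numpy path is the reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _mixture_loglik_kernel(X, pts, inv2_xy, inv2_z, log_norm, log_w_mix, log_bg):
        n, m = X.shape[0], pts.shape[0]
        total = 0.0
        log_m = math.log(m)
        for i in range(n):
            best = -1.0e300
            for j in range(m):
                dx = X[i, 0] - pts[j, 0]
                dy = X[i, 1] - pts[j, 1]
                dz = X[i, 2] - pts[j, 2]
                q = -(dx * dx + dy * dy) * inv2_xy[i] - dz * dz * inv2_z[i]
                if q > best:
                    best = q
            s = 0.0
            for j in range(m):
                dx = X[i, 0] - pts[j, 0]
                dy = X[i, 1] - pts[j, 1]
                dz = X[i, 2] - pts[j, 2]
                q = -(dx * dx + dy * dy) * inv2_xy[i] - dz * dz * inv2_z[i]
                s += math.exp(q - best)
            log_fg = log_w_mix + log_norm[i] - log_m + best + math.log(s)
            a = log_fg if log_fg > log_bg else log_bg
            total += a + math.log(math.exp(log_fg - a) + math.exp(log_bg - a))
        return total

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _mixture_loglik_numpy(X, pts, inv2_xy, inv2_z, log_norm, log_w_mix, log_bg):
    d_xy = (X[:, None, 0] - pts[None, :, 0]) ** 2 + (X[:, None, 1] - pts[None, :, 1]) ** 2
    d_z = (X[:, None, 2] - pts[None, :, 2]) ** 2
    q = -d_xy * inv2_xy[:, None] - d_z * inv2_z[:, None]
    best = q.max(axis=1)
    s = np.exp(q - best[:, None]).sum(axis=1)
    log_fg = log_w_mix + log_norm - math.log(pts.shape[0]) + best + np.log(s)
    top = np.maximum(log_fg, log_bg)
    return float(np.sum(top + np.log(np.exp(log_fg - top) + math.exp(log_bg - top))))


def _mixture_loglik(X, pts, inv2_xy, inv2_z, log_norm, log_w_mix, log_bg):
    if _HAVE_NUMBA:
        return _mixture_loglik_kernel(
            X, pts, inv2_xy, inv2_z, log_norm, float(log_w_mix), float(log_bg)
        )
    return _mixture_loglik_numpy(X, pts, inv2_xy, inv2_z, log_norm, log_w_mix, log_bg)


@dataclass(frozen=True)
class CapFitOptions:
    """Tuning knobs of the cap fit.

    ``theta_multistart`` (radians) seeds the simplex at several closing
    angles; the multistart stage runs on a coarser surface
    discretization (``coarse_spacing_nm``) and the best start is
    refined at ``model_point_spacing_nm``.  ``w_bg`` and
    ``sigma_extra`` are bounded to keep the background term from
    absorbing nearly-closed caps.
    """

    sigma_extra_init: float = 10.0
    w_bg_init: float = 0.02
    model_point_spacing_nm: float = 6.0
    coarse_spacing_nm: float = 12.0
    theta_multistart: tuple[float, ...] = tuple(
        math.radians(d) for d in (20.0, 60.0, 100.0, 140.0, 170.0)
    )
    roi_padding_nm: float = 50.0
    w_bg_max: float = 0.5
    sigma_extra_max: float = 30.0
    r_min: float = 25.0
    r_max: float = 400.0
    theta_min: float = math.radians(1.0)
    maxfev_start: int = 400
    maxfev_refine: int = 1000
    fatol: float = 0.2
    xatol: float = 0.3

    def __post_init__(self):
        if self.model_point_spacing_nm <= 0 or self.coarse_spacing_nm <= 0:
            raise ValueError("model point spacing must be positive")
        for th in self.theta_multistart:
            if not 0.0 < th < math.pi:
                raise ValueError("multistart closing angles must lie in (0, pi)")


@dataclass
class CapFitResult:
    """Fitted spherical-cap parameters for one site.

    ``x0, y0, z0`` is the cap surface centroid (the reported model
    position); ``sphere_center`` the internal sphere-center
    parametrization.  ``axis_polar``/``axis_azimuth`` give the symmetry
    axis (cap pole direction); a polar angle > 90° means the pole
    points toward the coverslip, which is reported as a negative signed
    curvature for near-flat structures.
    """

    A: float
    theta: float
    r: float
    x0: float
    y0: float
    z0: float
    axis_polar: float
    axis_azimuth: float
    w_bg: float
    sigma_extra: float
    log_likelihood: float
    n_localizations: int
    converged: bool
    sphere_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    @property
    def H(self) -> float:
        return 1.0 / self.r

    @property
    def axis(self) -> np.ndarray:
        sp, az = self.axis_polar, self.axis_azimuth
        return np.array(
            [math.sin(sp) * math.cos(az), math.sin(sp) * math.sin(az), math.cos(sp)]
        )

    @property
    def signed_H(self) -> float:
        """Curvature signed by the axis direction relative to +z.

        Positive when the cap pole points away from the coverslip
        (axis polar <= 90°), negative otherwise; the sign carries the
        "bending away" information used by :func:`flatten_if_negative`.
        """
        return self.H if math.cos(self.axis_polar) >= 0.0 else -self.H


def _extract_coords(locs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(locs, pd.DataFrame):
        X = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        s_xy = locs["sigma_xy_nm"].to_numpy(dtype=float)
        s_z = locs["sigma_z_nm"].to_numpy(dtype=float)
    else:
        arr = np.asarray(locs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 5:
            raise ValueError(
                "array input must have columns [x_nm, y_nm, z_nm, sigma_xy_nm, sigma_z_nm]"
            )
        X, s_xy, s_z = arr[:, :3], arr[:, 3], arr[:, 4]
    if not np.all(np.isfinite(X)):
        raise ValueError("localization coordinates contain non-finite values")
    if np.any(s_xy <= 0) or np.any(s_z <= 0):
        raise ValueError("localization precisions must be positive")
    return np.ascontiguousarray(X), s_xy, s_z


def _model_points(center, r, theta, polar, azimuth, spacing) -> np.ndarray:
    m = max(int(round(cap_area(r, theta) / spacing**2)), 6)
    local = sample_cap_points(r, theta, m)
    axis = np.array(
        [math.sin(polar) * math.cos(azimuth), math.sin(polar) * math.sin(azimuth), math.cos(polar)]
    )
    return local @ _rotation_to_axis(axis).T + np.asarray(center, dtype=float)


def build_cap_density(
    center,
    r: float,
    theta: float,
    polar: float,
    azimuth: float,
    w_bg: float,
    sigma_extra: float,
    locs,
    options: CapFitOptions | None = None,
    roi_bounds: np.ndarray | None = None,
) -> np.ndarray:
    """Per-localization probability density of the cap mixture model.

    ``roi_bounds`` is a (2, 3) array of lower/upper box corners; by
    default the padded bounding box of the localizations.  The density
    integrates to one over the ROI up to surface-discretization error.
    """
    options = options or CapFitOptions()
    if not 0.0 <= w_bg < 1.0:
        raise ValueError(f"w_bg must lie in [0, 1), got {w_bg}")
    X, s_xy, s_z = _extract_coords(locs)
    if roi_bounds is None:
        pad = options.roi_padding_nm
        roi_bounds = np.stack([X.min(axis=0) - pad, X.max(axis=0) + pad])
    v_roi = float(np.prod(roi_bounds[1] - roi_bounds[0]))
    pts = _model_points(center, r, theta, polar, azimuth, options.model_point_spacing_nm)
    var_xy = s_xy**2 + sigma_extra**2
    var_z = s_z**2 + sigma_extra**2
    log_norm = -1.5 * _LOG_2PI - np.log(var_xy) - 0.5 * np.log(var_z)
    out = np.empty(len(X))
    chunk = max(int(5e6 / max(len(pts), 1)), 1)  # bound the broadcast size
    for lo in range(0, len(X), chunk):
        sl = slice(lo, lo + chunk)
        d_xy = (X[sl, None, 0] - pts[None, :, 0]) ** 2 + (
            X[sl, None, 1] - pts[None, :, 1]
        ) ** 2
        d_z = (X[sl, None, 2] - pts[None, :, 2]) ** 2
        q = -d_xy / (2 * var_xy[sl, None]) - d_z / (2 * var_z[sl, None])
        fg = np.exp(log_norm[sl]) * np.exp(q).mean(axis=1)
        out[sl] = (1.0 - w_bg) * fg + w_bg / v_roi
    return out


class SphericalCapEstimator(BaseEstimator):
    """Maximum-likelihood spherical-cap fit (sklearn-style estimator).

    ``fit(locs)`` accepts a localization table (DataFrame with the
    canonical columns, or an (n, 5+) array of x, y, z, sigma_xy,
    sigma_z) and exposes the fitted geometry as ``result_`` plus
    scalar attributes ``A_``, ``theta_``, ``r_``.
    """

    def __init__(self, options: CapFitOptions | None = None):
        self.options = options

    # -- objective ---------------------------------------------------------
    def _nll(self, p, X, s_xy2, s_z2, v_roi, spacing, opt):
        cx, cy, cz, log_r, theta, polar, azim, w_bg, sig_e = p
        penalty = 0.0
        r = math.exp(min(max(log_r, math.log(opt.r_min)), math.log(opt.r_max)))
        penalty += (log_r - math.log(r)) ** 2
        th = min(max(theta, opt.theta_min), math.pi)
        penalty += 100.0 * (theta - th) ** 2
        w = min(max(w_bg, 1e-6), opt.w_bg_max)
        penalty += 1e4 * (w_bg - w) ** 2
        se = min(max(sig_e, 0.0), opt.sigma_extra_max)
        penalty += (sig_e - se) ** 2
        pts = _model_points((cx, cy, cz), r, th, polar, azim, spacing)
        var_xy = s_xy2 + se * se
        var_z = s_z2 + se * se
        inv2_xy = 0.5 / var_xy
        inv2_z = 0.5 / var_z
        log_norm = -1.5 * _LOG_2PI - np.log(var_xy) - 0.5 * np.log(var_z)
        ll = _mixture_loglik(
            X, pts, inv2_xy, inv2_z, log_norm, math.log1p(-w), math.log(w / v_roi)
        )
        return -ll + penalty

    # -- initialization ----------------------------------------------------
    @staticmethod
    def _algebraic_sphere(X, n_iter: int = 3):
        """Least-squares sphere through the points, with outlier trimming.

        Solves the linear system for center and radius, then re-solves
        on the points whose radial residual is within 2.5 median
        absolute deviations.  May still be wild for nearly flat data.
        """
        keep = np.ones(len(X), dtype=bool)
        c, r = np.zeros(3), np.nan
        for _ in range(n_iter):
            Xk = X[keep]
            if len(Xk) < 10:
                break
            A = np.column_stack([2.0 * Xk, np.ones(len(Xk))])
            b = (Xk**2).sum(axis=1)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            c = sol[:3]
            r2 = sol[3] + c @ c
            if r2 <= 0:
                return c, np.nan
            r = math.sqrt(r2)
            resid = np.abs(np.linalg.norm(X - c, axis=1) - r)
            mad = np.median(resid)
            keep = resid <= max(2.5 * 1.4826 * mad, 10.0)
        return c, r

    def _initial_simplex_params(self, X, theta0, opt):
        m = X.mean(axis=0)
        c_alg, r_alg = self._algebraic_sphere(X)
        if np.isfinite(r_alg) and opt.r_min <= r_alg <= opt.r_max:
            # direction of the cap pole: mean of unit vectors from the
            # sphere center to the localizations
            u = X - c_alg
            u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-9)
            axis = u.mean(axis=0)
            r0 = r_alg
        else:
            # near-flat cloud: normal of the best-fit plane, signed upward
            _, _, vt = np.linalg.svd(X - m, full_matrices=False)
            axis = vt[2] if vt[2][2] >= 0 else -vt[2]
            z_ext = np.quantile(X @ axis, 0.95) - np.quantile(X @ axis, 0.05)
            r0 = min(max(z_ext / max(1.0 - math.cos(theta0), 1e-3), opt.r_min), opt.r_max)
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        polar = math.acos(np.clip(axis[2], -1.0, 1.0))
        azim = math.atan2(axis[1], axis[0])
        center = m - axis * cap_centroid_offset(r0, theta0)
        return np.array(
            [
                center[0],
                center[1],
                center[2],
                math.log(r0),
                theta0,
                polar,
                azim,
                opt.w_bg_init,
                opt.sigma_extra_init,
            ]
        )

    def _estimate_theta(self, X, opt) -> float | None:
        """Data-driven closing-angle estimate used as an extra start."""
        c_alg, r_alg = self._algebraic_sphere(X)
        if not (np.isfinite(r_alg) and opt.r_min <= r_alg <= opt.r_max):
            return None
        u = X - c_alg
        u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-9)
        axis = u.mean(axis=0)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            return None
        ang = np.arccos(np.clip(u @ (axis / nrm), -1.0, 1.0))
        th = float(np.quantile(ang, 0.98))
        return min(max(th, opt.theta_min), math.pi - 1e-3)

    @staticmethod
    def _simplex_around(p0, scale: float = 1.0):
        """Initial simplex with physically sensible per-parameter steps."""
        steps = scale * np.array([12.0, 12.0, 12.0, 0.15, 0.18, 0.25, 0.25, 0.05, 4.0])
        return np.vstack([p0, p0 + np.diag(steps)])

    # -- fitting -----------------------------------------------------------
    def fit(self, locs, y=None):
        opt = self.options or CapFitOptions()
        X, s_xy, s_z = _extract_coords(locs)
        n = len(X)
        if n < 20:
            raise ValueError(f"need at least 20 localizations to fit a cap, got {n}")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate input: all localizations identical")
        pad = opt.roi_padding_nm
        lo, hi = X.min(axis=0) - pad, X.max(axis=0) + pad
        v_roi = float(np.prod(hi - lo))
        s_xy2, s_z2 = s_xy**2, s_z**2
        args_coarse = (X, s_xy2, s_z2, v_roi, opt.coarse_spacing_nm, opt)
        theta_starts = list(opt.theta_multistart)
        th_data = self._estimate_theta(X, opt)
        if th_data is not None:
            theta_starts.append(th_data)
        starts = []
        for th0 in theta_starts:
            p0 = self._initial_simplex_params(X, th0, opt)
            res = minimize(
                self._nll,
                p0,
                args=args_coarse,
                method="Nelder-Mead",
                options=dict(
                    maxfev=opt.maxfev_start,
                    fatol=opt.fatol,
                    xatol=opt.xatol,
                    adaptive=True,
                    initial_simplex=self._simplex_around(p0),
                ),
            )
            starts.append(res)
        # best coarse start; ties broken toward smaller theta
        best = min(starts, key=lambda r: (round(r.fun, 9), r.x[4]))
        args_fine = (X, s_xy2, s_z2, v_roi, opt.model_point_spacing_nm, opt)
        refined = minimize(
            self._nll,
            best.x,
            args=args_fine,
            method="Nelder-Mead",
            options=dict(
                maxfev=opt.maxfev_refine,
                fatol=opt.fatol,
                xatol=opt.xatol,
                adaptive=True,
                initial_simplex=self._simplex_around(best.x, scale=0.35),
            ),
        )
        converged = bool(refined.success or best.success)
        if not converged:
            warnings.warn("cap fit did not converge; result flagged")
        cx, cy, cz, log_r, theta, polar, azim, w_bg, sig_e = refined.x
        r = float(np.clip(math.exp(log_r), opt.r_min, opt.r_max))
        theta = float(np.clip(theta, opt.theta_min, math.pi))
        # canonicalize the axis to polar in [0, pi], azimuth in (-pi, pi]
        axis = np.array(
            [
                math.sin(polar) * math.cos(azim),
                math.sin(polar) * math.sin(azim),
                math.cos(polar),
            ]
        )
        polar = math.acos(np.clip(axis[2], -1.0, 1.0))
        azim = math.atan2(axis[1], axis[0])
        w_bg = float(np.clip(w_bg, 0.0, opt.w_bg_max))
        sig_e = float(np.clip(sig_e, 0.0, opt.sigma_extra_max))
        centroid = np.array([cx, cy, cz]) + axis * cap_centroid_offset(r, theta)
        self.result_ = CapFitResult(
            A=cap_area(r, theta),
            theta=theta,
            r=r,
            x0=float(centroid[0]),
            y0=float(centroid[1]),
            z0=float(centroid[2]),
            axis_polar=float(polar),
            axis_azimuth=float(azim),
            w_bg=w_bg,
            sigma_extra=sig_e,
            log_likelihood=float(-refined.fun),
            n_localizations=n,
            converged=converged,
            sphere_center=(float(cx), float(cy), float(cz)),
            meta={
                "start_nll": [float(s.fun) for s in starts],
                "start_theta": [float(s.x[4]) for s in starts],
            },
        )
        self.A_ = self.result_.A
        self.theta_ = self.result_.theta
        self.r_ = self.result_.r
        self.log_likelihood_ = self.result_.log_likelihood
        return self

    def predict_density(self, locs):
        """Density of the fitted model at new localizations."""
        res = self.result_
        return build_cap_density(
            res.sphere_center,
            res.r,
            res.theta,
            res.axis_polar,
            res.axis_azimuth,
            res.w_bg,
            res.sigma_extra,
            locs,
            self.options or CapFitOptions(),
        )


def fit_cap(locs, options: CapFitOptions | None = None) -> CapFitResult:
    """Fit the spherical-cap model to one localization table."""
    return SphericalCapEstimator(options=options).fit(locs).result_


def flatten_if_negative(fit: CapFitResult | float, theta: float | None = None):
    """Apply the flat-site rule: non-positive curvature → H = 0, θ = 0.

    Accepts either a :class:`CapFitResult` (uses its signed curvature)
    or a plain signed curvature value with ``theta``.  Returns
    ``(H, theta, flat)``; positive-curvature fits pass through
    unchanged.  The boundary ``H == 0`` is treated as flat.
    """
    if isinstance(fit, CapFitResult):
        h, th = fit.signed_H, fit.theta
    else:
        if theta is None:
            raise ValueError("theta required when passing a raw curvature value")
        h, th = float(fit), float(theta)
    if h <= 0.0:
        return 0.0, 0.0, True
    return h, th, False
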