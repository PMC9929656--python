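"""Kinetic growth models of the clathrin coat and their fitting.

Four models describe how coat curvature ``H`` depends on the closing
angle ``theta`` during endocytosis:

- constant-area model (CAM): the coat preassembles completely flat with
  area ``A`` and then only bends, ``H(θ) = sqrt(2π(1-cos θ)/A)``;
- constant-curvature model (CCM): the coat grows at its final curvature,
  ``H(θ) = 1/R``;
- cooperative-curvature model (CoopCM): curvature is generated by a
  positive feedback in the lattice, ``dH/dθ = γ (1 - H²/H₀²)``, whose
  solution is ``H(θ) = H₀ tanh(γ θ / H₀)``;
- linear-curvature model (LinearCM): the non-cooperative alternative
  ``dH/dθ = γ (1 - H/H₀)`` with solution ``H(θ) = H₀ (1 - exp(-γθ/H₀))``.

Every other observable follows from ``H`` through the cap geometry:
``A = 2π(1-cos θ)/H²``, ``ε = 2π sin θ / H``, ``A_p = π sin²θ / H²``.

Coat *dynamics* couple area growth to the free rim: ``dA/dt = k_on ε``
with a single rate constant ``k_on`` (nm per pseudotime unit).  Under
the CoopCM this yields, to leading order in θ, the square-root law

    θ(t) = sqrt( 24 γ k_on t / (8 γ² H₀⁻² − 1) ),

which is used to fit ``k_on`` against pseudotime-sorted closing angles.
The full ordinary-differential-equation route (chain rule through the
analytic ``dA/dθ``) is also provided; see docs/methods.md for its
domain of validity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit, minimize_scalar
from sklearn.base import BaseEstimator

__all__ = [
    "OBSERVABLES",
    "THETA_FLOOR",
    "GrowthModel",
    "ConstantAreaModel",
    "ConstantCurvatureModel",
    "CooperativeCurvatureModel",
    "LinearCurvatureModel",
    "MODELS",
    "model_predict",
    "fit_growth_model",
    "compute_A0",
    "compare_models_bic",
    "ThetaTimeCurve",
    "theta_of_time",
    "fit_kon",
    "linkage_sensitivity",
]

OBSERVABLES = ("H", "A", "epsilon", "A_p")

#: substitution used for theta == 0 during fitting (0.0001 degree)
THETA_FLOOR = math.radians(1e-4)


def observable_from_curvature(H, theta, observable: str):
    """Map curvature ``H(θ)`` to another cap observable at the same θ."""
    H = np.asarray(H, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if observable == "H":
        return H
    if observable == "A":
        return 2.0 * np.pi * (1.0 - np.cos(theta)) / H**2
    if observable == "epsilon":
        return 2.0 * np.pi * np.sin(theta) / H
    if observable == "A_p":
        return np.pi * np.sin(theta) ** 2 / H**2
    raise ValueError(f"unknown observable {observable!r}; expected one of {OBSERVABLES}")


def _substitute_theta(theta) -> np.ndarray:
    """Replace θ <= 0 entries by the 0.0001° floor used during fitting."""
    theta = np.asarray(theta, dtype=float).copy()
    theta[theta <= 0.0] = THETA_FLOOR
    return theta


class GrowthModel(BaseEstimator):
    """Base class for coat growth models (sklearn-style regressors).

    Subclasses define the curvature law ``curvature(theta, *params)``,
    the parameter names and initial guesses.  ``fit`` performs an
    unweighted nonlinear least-squares fit of the chosen observable
    against closing angle.  Fitted attributes carry a trailing
    underscore (``params_``, ``stderr_``, ``rss_``, ``bic_``, ...).
    """

    name: str = "base"
    param_names: tuple[str, ...] = ()

    def __init__(self, observable: str = "H"):
        self.observable = observable

    # -- model definition -------------------------------------------------
    def curvature(self, theta, *params):  # pragma: no cover - abstract
        raise NotImplementedError

    def _p0(self, theta, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _bounds(self):
        k = len(self.param_names)
        return (np.full(k, 1e-12), np.full(k, np.inf))

    # -- fitting -----------------------------------------------------------
    def fit(self, theta, y, observable: str | None = None):
        """Least-squares fit of ``y`` (the observable) against ``theta``.

        ``theta`` in radians; values of exactly 0 are replaced by the
        0.0001 degree floor before evaluation so flat sites contribute
        finite residuals.
        """
        if observable is not None:
            self.observable = observable
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        theta = np.asarray(theta, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if theta.shape != y.shape:
            raise ValueError("theta and y must have the same length")
        if theta.size < 5:
            raise ValueError(f"need at least 5 points to fit, got {theta.size}")
        th = _substitute_theta(theta)

        def model_fn(t, *p):
            return observable_from_curvature(self.curvature(t, *p), t, self.observable)

        p0 = self._p0(th, y)
        self.converged_ = True
        try:
            popt, pcov = curve_fit(
                model_fn, th, y, p0=p0, bounds=self._bounds(), maxfev=20000
            )
        except RuntimeError as exc:  # non-convergence: flag, keep diagnostics
            warnings.warn(f"{self.name} fit did not converge: {exc}")
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((len(p0), len(p0)), np.nan)
            self.converged_ = False
        resid = y - model_fn(th, *popt)
        self.params_ = dict(zip(self.param_names, popt))
        with np.errstate(invalid="ignore"):
            self.stderr_ = dict(zip(self.param_names, np.sqrt(np.diag(pcov))))
        self.rss_ = float(resid @ resid)
        self.n_points_ = int(th.size)
        self.n_params_ = len(self.param_names)
        # Gaussian residuals, variance profiled out: identical convention
        # for every model so BIC values are comparable.
        # guard: a perfect (noiseless) fit has RSS = 0 and BIC -> -inf
        rss_safe = max(self.rss_, np.finfo(float).tiny)
        self.bic_ = self.n_points_ * math.log(rss_safe / self.n_points_) + (
            self.n_params_ * math.log(self.n_points_)
        )
        self.theta_ = th
        self.y_ = y
        self._derive()
        return self

    def _derive(self):
        """Populate model-specific derived quantities after fitting."""

    def predict(self, theta, observable: str | None = None):
        """Evaluate the fitted model at ``theta`` for an observable."""
        obs = self.observable if observable is None else observable
        th = _substitute_theta(theta)
        p = [self.params_[k] for k in self.param_names]
        return observable_from_curvature(self.curvature(th, *p), th, obs)


class ConstantAreaModel(GrowthModel):
    """CAM: fixed final area ``A``; only curvature changes."""

    name = "CAM"
    param_names = ("A",)

    def curvature(self, theta, A):
        return np.sqrt(2.0 * np.pi * (1.0 - np.cos(theta)) / A)

    def _p0(self, theta, y):
        if self.observable == "A":
            return [float(np.median(y))]
        H = _invert_observable(theta, y, self.observable)
        A0 = 2.0 * np.pi * 2.0 / np.median(H) ** 2  # area of the closed sphere
        return [float(A0 / 2.0)]


class ConstantCurvatureModel(GrowthModel):
    """CCM: fixed sphere radius ``R``; only area changes."""

    name = "CCM"
    param_names = ("R",)

    def curvature(self, theta, R):
        return np.full_like(np.asarray(theta, dtype=float), 1.0 / R)

    def _p0(self, theta, y):
        H = _invert_observable(theta, y, self.observable)
        return [float(1.0 / np.median(H))]


class CooperativeCurvatureModel(GrowthModel):
    """CoopCM: ``H(θ) = H₀ tanh(γ θ / H₀)``.

    Fitted attributes include the derived preferred radius
    ``R0_ = 1/H0`` (nm) and the flat-preassembly fraction
    ``A0_ = A(θ=0.01)/A(θ=π)``; the growth rate ``kon_`` is populated
    by :func:`fit_kon`.
    """

    name = "CoopCM"
    param_names = ("gamma", "H0")

    def curvature(self, theta, gamma, H0):
        return H0 * np.tanh(gamma * np.asarray(theta, dtype=float) / H0)

    def _p0(self, theta, y):
        H = _invert_observable(theta, y, self.observable)
        H0 = float(np.quantile(H, 0.9))
        H0 = H0 if np.isfinite(H0) and H0 > 0 else 1.2e-2
        return [0.7 * H0, H0]

    def _derive(self):
        g, H0 = self.params_["gamma"], self.params_["H0"]
        self.R0_ = 1.0 / H0
        self.A0_ = compute_A0(g, H0)
        self.kon_ = None


class LinearCurvatureModel(GrowthModel):
    """LinearCM: ``dH/dθ = γ(1 - H/H₀)``, the less cooperative variant."""

    name = "LinearCM"
    param_names = ("gamma", "H0")

    def curvature(self, theta, gamma, H0):
        return H0 * (1.0 - np.exp(-gamma * np.asarray(theta, dtype=float) / H0))

    _p0 = CooperativeCurvatureModel._p0
    _derive = CooperativeCurvatureModel._derive


MODELS = {
    "CAM": ConstantAreaModel,
    "CCM": ConstantCurvatureModel,
    "CoopCM": CooperativeCurvatureModel,
    "LinearCM": LinearCurvatureModel,
}


def _invert_observable(theta, y, observable):
    """Rough per-point curvature implied by an observable value (for p0)."""
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if observable == "H":
            H = y.copy()
        elif observable == "A":
            H = np.sqrt(2.0 * np.pi * (1.0 - np.cos(theta)) / y)
        elif observable == "epsilon":
            H = 2.0 * np.pi * np.sin(theta) / y
        elif observable == "A_p":
            H = np.sqrt(np.pi * np.sin(theta) ** 2 / y)
        else:
            raise ValueError(f"unknown observable {observable!r}")
    H = H[np.isfinite(H) & (H > 0)]
    return H if H.size else np.array([1e-2])


def model_predict(model: str, params, observable: str, theta):
    """Evaluate a named growth model with explicit parameters.

    ``params`` is a scalar (CAM area nm², CCM radius nm) or a
    ``(gamma, H0)`` pair for the curvature-dynamics models.  ``theta``
    must be positive (callers apply the 0.0001° substitution).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0) or np.any(theta > np.pi):
        raise ValueError("theta must lie in (0, pi]; substitute zeros upstream")
    est = MODELS[model]()
    p = np.atleast_1d(np.asarray(params, dtype=float))
    return observable_from_curvature(est.curvature(theta, *p), theta, observable)


def fit_growth_model(theta, y, model: str = "CoopCM", observable: str = "H") -> GrowthModel:
    """Fit one growth model to ``(theta_i, y_i)`` pairs; thin wrapper."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {tuple(MODELS)}")
    return MODELS[model](observable=observable).fit(theta, y)


def compute_A0(gamma: float, H0: float) -> float:
    """Flat-preassembly fraction ``A(θ=0.01 rad) / A(θ=π)`` under CoopCM.

    The fraction of the final coat surface area already present when
    curvature initiation begins.
    """
    if gamma <= 0 or H0 <= 0:
        raise ValueError("gamma and H0 must be positive")

    def area(th):
        H = H0 * math.tanh(gamma * th / H0)
        return 2.0 * math.pi * (1.0 - math.cos(th)) / H**2

    return area(0.01) / area(math.pi)


def compare_models_bic(fits: list[GrowthModel]) -> list[tuple[GrowthModel, float]]:
    """Rank fitted models by BIC on identical data.

    Returns ``[(fit, delta_bic), ...]`` sorted ascending by BIC; the
    best model has ``delta_bic == 0``.  Raises if the fits were not
    computed on the same (theta, y, observable) data.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if (
            f.observable != ref.observable
            or f.n_points_ != ref.n_points_
            or not np.array_equal(f.theta_, ref.theta_)
            or not np.array_equal(f.y_, ref.y_)
        ):
            raise ValueError("BIC comparison requires fits on identical data")
    ranked = sorted(fits, key=lambda f: f.bic_)
    best = ranked[0].bic_
    return [(f, f.bic_ - best) for f in ranked]


# ---------------------------------------------------------------------------
# theta(t) dynamics


@dataclass
class ThetaTimeCurve:
    """Closing angle as a function of pseudotime under the CoopCM."""

    t: np.ndarray
    theta: np.ndarray
    gamma: float
    H0: float
    kon: float
    method: str
    meta: dict = field(default_factory=dict)


def _sqrt_law_coefficient(gamma: float, H0: float, kon: float) -> float:
    denom = 8.0 * gamma**2 / H0**2 - 1.0
    if denom <= 0:
        raise ValueError("sqrt law requires 8 gamma^2 / H0^2 > 1")
    return 24.0 * gamma * kon / denom


def _theta_singular(gamma: float, H0: float) -> float:
    """θ* where dA/dθ = 0 under the CoopCM (area peaks before closure)."""

    def dA(th):
        H = H0 * math.tanh(gamma * th / H0)
        Hp = gamma * (1.0 - H**2 / H0**2)
        return (
            2.0 * math.pi * math.sin(th) / H**2
            - 4.0 * math.pi * (1.0 - math.cos(th)) * Hp / H**3
        )

    lo, hi = 0.5 * math.pi, math.pi - 1e-9
    if dA(lo) <= 0 or dA(hi) >= 0:
        return math.pi
    return brentq(dA, lo, hi)


def theta_of_time(
    t,
    gamma: float,
    H0: float,
    kon: float,
    method: str = "closed_form",
) -> ThetaTimeCurve:
    """Closing angle over pseudotime from the rim-growth dynamics.

    ``closed_form`` evaluates the square-root law (the exact
    leading-order solution of ``dA/dt = k_on ε`` with the tanh
    curvature law), clamped to π.  ``ode`` integrates the chain-rule
    equation ``dθ/dt = k_on ε(θ) / (dA/dθ)``; that equation is singular
    where ``A(θ)`` peaks (θ* slightly below π), so the integration
    stops just below θ* and holds the value afterwards.
    """
    if gamma <= 0 or H0 <= 0 or kon <= 0:
        raise ValueError("gamma, H0 and kon must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("pseudotime must be non-negative")
    if method == "closed_form":
        theta = np.minimum(np.sqrt(_sqrt_law_coefficient(gamma, H0, kon) * t), math.pi)
        return ThetaTimeCurve(t=t, theta=theta, gamma=gamma, H0=H0, kon=kon, method=method)
    if method != "ode":
        raise ValueError(f"unknown method {method!r}")

    th_star = _theta_singular(gamma, H0)
    th_stop = th_star - 1e-3

    def H(th):
        return H0 * math.tanh(gamma * th / H0)

    # Power series of theta * dtheta/dt around theta = 0 (regular there);
    # used below a switch angle where the exact chain-rule expression
    # suffers catastrophic cancellation between its two O(1/theta) terms.
    g2, h2 = gamma**2, H0**2
    c0 = -12.0 * h2 * gamma * kon / (h2 - 8.0 * g2)
    c2 = (
        2.0 * gamma * kon * (3 * h2**2 - 10 * h2 * g2 + 32 * g2**2)
        / (5.0 * (h2**2 - 16 * h2 * g2 + 64 * g2**2))
    )
    c4 = (
        gamma * kon
        * (3 * h2**4 - 1200 * h2**3 * g2 + 224 * h2**2 * g2**2
           + 640 * h2 * g2**3 + 2048 * g2**4)
        / (2100.0 * h2 * (h2**3 - 24 * h2**2 * g2 + 192 * h2 * g2**2 - 512 * g2**3))
    )
    c6 = (
        gamma * kon
        * (h2**6 - 130 * h2**5 * g2 + 20512 * h2**4 * g2**2 + 14880 * h2**3 * g2**3
           - 74752 * h2**2 * g2**4 + 102400 * h2 * g2**5 - 65536 * g2**6)
        / (63000.0 * h2**2
           * (h2**4 - 32 * h2**3 * g2 + 384 * h2**2 * g2**2
              - 2048 * h2 * g2**3 + 4096 * g2**4))
    )
    th_switch = 0.04

    def rhs(_t, y):
        th = y[0]
        if th < th_switch:
            th2 = th * th
            return [(c0 + th2 * (c2 + th2 * (c4 + th2 * c6))) / th]
        Hv = H(th)
        Hp = gamma * (1.0 - Hv**2 / H0**2)
        dA = (
            2.0 * math.pi * math.sin(th) / Hv**2
            - 4.0 * math.pi * (1.0 - math.cos(th)) * Hp / Hv**3
        )
        eps = 2.0 * math.pi * math.sin(th) / Hv
        return [kon * eps / dA]

    # seed the singular origin with the exact asymptotic solution
    t_end = float(max(t.max(), 1e-9))
    t0 = min(1e-12, 1e-6 * t_end)
    th0 = math.sqrt(_sqrt_law_coefficient(gamma, H0, kon) * t0)

    def hit_stop(_t, y):
        return y[0] - th_stop

    hit_stop.terminal = True
    sol = solve_ivp(
        rhs,
        (t0, t_end),
        [th0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
        dense_output=True,
        events=hit_stop,
    )
    if not sol.success and not sol.t_events[0].size:
        raise RuntimeError(f"theta(t) integration failed: {sol.message}")
    t_stop = sol.t_events[0][0] if sol.t_events[0].size else np.inf
    theta = np.empty_like(t)
    small = t <= t0
    theta[small] = np.sqrt(_sqrt_law_coefficient(gamma, H0, kon) * t[small])
    inside = (~small) & (t < t_stop)
    if inside.any():
        theta[inside] = sol.sol(t[inside])[0]
    theta[t >= t_stop] = th_stop
    theta = np.minimum(theta, math.pi)
    return ThetaTimeCurve(
        t=t,
        theta=theta,
        gamma=gamma,
        H0=H0,
        kon=kon,
        method=method,
        meta={"theta_singular": th_star, "t_stop": float(t_stop)},
    )


def fit_kon(
    t,
    theta,
    gamma: float,
    H0: float,
    method: str = "closed_form",
) -> float:
    """One-parameter least-squares fit of ``k_on`` from θ(t) data.

    ``(gamma, H0)`` are held fixed (taken from the corresponding
    observable's CoopCM fit); only the growth rate is free.  Returns
    ``k_on`` in nm per pseudotime unit.
    """
    t = np.asarray(t, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float).ravel()
    if t.shape != theta.shape or t.size < 2:
        raise ValueError("need matching t/theta arrays with at least 2 points")
    if np.ptp(t) == 0.0:
        raise ValueError("degenerate pseudotime axis: all t identical")
    order = np.argsort(t)
    t, theta = t[order], theta[order]

    def ssr(log_kon):
        curve = theta_of_time(t, gamma, H0, math.exp(log_kon), method=method)
        r = theta - curve.theta
        return float(r @ r)

    res = minimize_scalar(ssr, bounds=(math.log(1e-3), math.log(1e6)), method="bounded",
                          options={"xatol": 1e-10})
    return float(math.exp(res.x))


def linkage_sensitivity(theta, r, delta_r: float, observables=OBSERVABLES,
                        model: str = "CoopCM") -> dict:
    """Re-fit growth models after shifting every site radius by ``delta_r``.

    Emulates correcting a systematic labeling (linkage) bias: each
    site's radius becomes ``r + delta_r`` at fixed θ, all observables
    are recomputed, and the growth model is refitted per observable.
    Sites whose shifted radius is non-positive are dropped with a
    warning.  Returns ``{observable: fitted model}``.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    r_new = r + delta_r
    keep = r_new > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} sites with non-positive shifted radius")
    th, rn = theta[keep], r_new[keep]
    H_new = 1.0 / rn
    out = {}
    for obs in observables:
        y = observable_from_curvature(H_new, _substitute_theta(th), obs)
        out[obs] = fit_growth_model(th, y, model=model, observable=obs)
    return out
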