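"""Closed-form spherical-cap geometry.

The clathrin coat is modelled as a spherical cap of sphere radius ``r``
(nm) and closing angle ``theta`` (radians): ``theta = 0`` is a flat
patch, ``theta = pi/2`` a hemisphere and ``theta = pi`` a closed sphere.
All quantities used downstream derive from ``(A, theta)``:

========== =============================== ==================
quantity   closed form                      units
========== =============================== ==================
area       ``A = 2 pi r^2 (1 - cos θ)``    nm²
radius     ``r = sqrt(A / (2π(1-cos θ)))`` nm
curvature  ``H = 1/r``                     nm⁻¹
rim length ``ε = 2 π r sin θ``             nm
rim disc   ``A_p = π r² sin² θ``           nm²
centroid   ``z̄ = r (1 + cos θ)/2``         nm from sphere center
========== =============================== ==================

Angles are radians everywhere inside the package; degrees appear only at
I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CapGeometry",
    "cap_area",
    "derive_geometry",
    "cap_centroid_offset",
    "sample_cap_points",
]

#: golden angle in radians, used for quasi-uniform spherical lattices
GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class CapGeometry:
    """Complete description of one spherical cap.

    Attributes
    ----------
    A : float
        Coat surface area in nm².
    theta : float
        Closing angle in radians, in (0, pi].
    r : float
        Sphere radius in nm.
    H : float
        Mean curvature ``1/r`` in nm⁻¹.
    A_p : float
        Projected (rim-disc) area ``pi r^2 sin^2 theta`` in nm².
    epsilon : float
        Rim (edge) length ``2 pi r sin theta`` in nm.
    z_centroid : float
        Signed distance of the cap's surface centroid from the sphere
        center along the symmetry axis, in nm.
    """

    A: float
    theta: float
    r: float
    H: float
    A_p: float
    epsilon: float
    z_centroid: float


def cap_area(r: float, theta: float) -> float:
    """Surface area ``2 pi r^2 (1 - cos theta)`` of a spherical cap."""
    return 2.0 * math.pi * r * r * (1.0 - math.cos(theta))


def derive_geometry(A: float, theta: float) -> CapGeometry:
    """Derive all cap quantities from surface area and closing angle.

    Parameters
    ----------
    A : float
        Surface area in nm², must be positive.
    theta : float
        Closing angle in radians, in (0, pi].

    Returns
    -------
    CapGeometry

    Raises
    ------
    ValueError
        If ``A <= 0`` or ``theta`` is outside (0, pi].
    """
    if not np.isfinite(A) or A <= 0.0:
        raise ValueError(f"surface area must be positive, got A={A!r}")
    if not np.isfinite(theta) or theta <= 0.0 or theta > math.pi:
        raise ValueError(f"closing angle must lie in (0, pi], got theta={theta!r}")
    r = math.sqrt(A / (2.0 * math.pi * (1.0 - math.cos(theta))))
    sin_t = math.sin(theta)
    return CapGeometry(
        A=A,
        theta=theta,
        r=r,
        H=1.0 / r,
        A_p=math.pi * r * r * sin_t * sin_t,
        epsilon=2.0 * math.pi * r * abs(sin_t),
        z_centroid=cap_centroid_offset(r, theta),
    )


def cap_centroid_offset(r: float, theta: float) -> float:
    """Centroid of the cap *surface* along the symmetry axis.

    Integrating ``z`` over the cap surface gives
    ``z̄ = r (1 + cos theta) / 2`` measured from the sphere center:
    ``r`` for a vanishing cap at the pole, ``r/2`` for a hemisphere and
    ``0`` for the full sphere.
    """
    if r <= 0.0:
        raise ValueError(f"radius must be positive, got r={r!r}")
    if theta < 0.0 or theta > math.pi:
        raise ValueError(f"closing angle must lie in [0, pi], got theta={theta!r}")
    return r * (1.0 + math.cos(theta)) / 2.0


def sample_cap_points(
    r: float,
    theta: float,
    n_points: int,
    mode: str = "spiral",
    seed: int | None = None,
    jitter: bool = False,
) -> np.ndarray:
    """Quasi-uniform lattice of points on a spherical cap.

    Points are placed on the sphere of radius ``r`` with polar angles
    ``<= theta`` (pole toward +z) using a golden-angle lattice: the
    cosine of the polar angle is stratified evenly over
    ``[cos theta, 1]`` (equal-area annuli) and azimuths advance by the
    golden angle (``mode="spiral"``) or by the golden-ratio rotation
    (``mode="fibonacci"``).  Both are deterministic; ``jitter=True``
    adds a random global azimuthal phase drawn from ``seed``.

    Returns an ``(n_points, 3)`` float array in nm.
    """
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    if r <= 0.0:
        raise ValueError(f"radius must be positive, got r={r!r}")
    if theta <= 0.0 or theta > math.pi:
        raise ValueError(f"closing angle must lie in (0, pi], got theta={theta!r}")
    k = np.arange(n_points, dtype=float)
    cos_polar = 1.0 - (1.0 - math.cos(theta)) * (k + 0.5) / n_points
    if mode == "spiral":
        az = k * GOLDEN_ANGLE
    elif mode == "fibonacci":
        az = 2.0 * math.pi * k * (math.sqrt(5.0) - 1.0) / 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'spiral' or 'fibonacci'")
    if jitter:
        az = az + np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi)
    sin_polar = np.sqrt(np.clip(1.0 - cos_polar**2, 0.0, None))
    pts = np.empty((n_points, 3))
    pts[:, 0] = r * sin_polar * np.cos(az)
    pts[:, 1] = r * sin_polar * np.sin(az)
    pts[:, 2] = r * cos_polar
    return pts
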