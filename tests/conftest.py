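"""Shared fixtures.

The two expensive simulate-and-fit cohorts (the U-shape bias
experiment and the closing-angle calibration sweep) are session-scoped
so several tests can share one computation.  All seeds are fixed so
the suite is deterministic.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

from coatfit import (
    GroundTruthShape,
    SimulationConfig,
    fit_cap,
    simulate_site,
    simulate_ushape_cohort,
)

def azimuthal_sector_means(
    volume,
    voxel_nm: float,
    rho_nm: float,
    z_nm: float,
    n_sectors: int = 24,
    band_nm: float = 7.5,
    slab_nm: float = 7.5,
):
    """Mean intensity per azimuthal sector on a ring through a rendered
    volume (ring radius ``rho_nm`` at height ``z_nm`` from the volume
    center, integrating radially over ``±band_nm`` and axially over
    ``±slab_nm``)."""
    n = volume.shape[0]
    c = (n - 1) / 2.0
    idx = np.arange(n)
    xx, yy = np.meshgrid((idx - c) * voxel_nm, (idx - c) * voxel_nm, indexing="ij")
    rho = np.hypot(xx, yy)
    phi = np.arctan2(yy, xx) % (2 * math.pi)
    ring = np.abs(rho - rho_nm) <= band_nm
    zc = int(round(c + z_nm / voxel_nm))
    half = max(int(round(slab_nm / voxel_nm)), 1)
    slab = volume[:, :, zc - half : zc + half + 1].mean(axis=2)
    sector = np.minimum((phi * n_sectors / (2 * math.pi)).astype(int), n_sectors - 1)
    means = np.array(
        [slab[ring & (sector == k)].mean() for k in range(n_sectors)]
    )
    return means


USHAPE_SEED = 42
CALIBRATION_SEED = 7
N_USHAPE = 100
N_CALIBRATION = 200


@pytest.fixture(scope="session")
def ushape_cohort_fits():
    """100 simulated U-shaped coats (R=97 nm, D=R/2) and their cap fits."""
    cohort = simulate_ushape_cohort(n_sites=N_USHAPE, seed=USHAPE_SEED)
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _shape, table in cohort:
            fits.append(fit_cap(table))
    return cohort, fits


@pytest.fixture(scope="session")
def calibration_fits():
    """200 simulated caps with θ ~ U(10°, 170°) along the growth law,
    fitted with the default estimator; returns (theta_true, fits)."""
    rng = np.random.default_rng(CALIBRATION_SEED)
    gamma, H0 = 9.4e-3, 13.9e-3
    cfg = SimulationConfig()
    theta_true, fits = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(N_CALIBRATION):
            th = rng.uniform(math.radians(10.0), math.radians(170.0))
            r = 1.0 / (H0 * math.tanh(gamma * th / H0))
            shape = GroundTruthShape(kind="cap", r=r, theta=th)
            table = simulate_site(shape, cfg, seed=int(rng.integers(2**31 - 1)))
            theta_true.append(th)
            fits.append(fit_cap(table))
    return np.asarray(theta_true), fits
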