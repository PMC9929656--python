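"""Pseudotime ordering, rolling statistics, binning, averaging."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from coatfit import (
    assign_pseudotime,
    bin_equal_counts,
    rolling_median,
    sliding_window_movie,
)
from coatfit.capfit import CapFitResult
from coatfit.pseudotime import align_rescale_average
from coatfit.sites import SiteRecord
from coatfit.geometry import sample_cap_points


def _record(site_id, theta, flat=False, r=90.0, polar=0.0, azim=0.0,
            center=(0.0, 0.0, 0.0)):
    fit = CapFitResult(
        A=2 * math.pi * r**2 * (1 - math.cos(max(theta, 0.1))),
        theta=theta, r=r, x0=center[0], y0=center[1], z0=center[2],
        axis_polar=polar, axis_azimuth=azim, w_bg=0.0, sigma_extra=5.0,
        log_likelihood=0.0, n_localizations=100, converged=True,
        sphere_center=center,
    )
    return SiteRecord(site_id=site_id, fit=fit, H=0.0 if flat else 1.0 / r,
                      theta=theta, flat=flat)


def _cap_table(r=90.0, theta=2.0, n=400, jitter=0.0, seed=0, shift=(0, 0, 0), rot=None):
    pts = sample_cap_points(r, theta, n)
    if jitter:
        pts = pts + np.random.default_rng(seed).normal(0, jitter, pts.shape)
    if rot is not None:
        pts = pts @ np.asarray(rot).T
    pts = pts + np.asarray(shift, dtype=float)
    return pd.DataFrame(
        {
            "frame": 0, "x_nm": pts[:, 0], "y_nm": pts[:, 1], "z_nm": pts[:, 2],
            "sigma_xy_nm": 4.0, "sigma_z_nm": 10.0, "photons": 1e4, "bg": 130.0,
            "site_id": 0,
        }
    )


class TestAssign:
    def test_rank_normalization(self):
        thetas = [math.radians(d) for d in (10, 50, 90, 130, 170)]
        recs = [_record(i, th) for i, th in enumerate(thetas)]
        table = assign_pseudotime(recs)
        assert list(table["t"]) == [0.0, 0.25, 0.5, 0.75, 1.0]

    def test_flat_sites_share_rank_zero(self):
        recs = [_record(0, 1.0), _record(1, 2.0)]
        recs += [_record(i, 0.0, flat=True) for i in (2, 3, 4)]
        table = assign_pseudotime(recs)
        flat_t = table.loc[table["site_id"].isin([2, 3, 4]), "t"]
        assert (flat_t == 0.0).all()
        assert table["theta"].is_monotonic_increasing

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        thetas = rng.uniform(0.1, 3.0, 40)
        recs = [_record(i, th) for i, th in enumerate(thetas)]
        a = assign_pseudotime(recs)
        shuffled = [recs[i] for i in rng.permutation(40)]
        b = assign_pseudotime(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_excluded_sites_dropped_and_empty_ok(self):
        recs = [_record(0, 1.0)]
        recs[0].excluded = True
        assert len(assign_pseudotime(recs)) == 0
        assert len(assign_pseudotime([])) == 0


class TestRollingMedian:
    def test_constant_and_window_one(self):
        assert np.allclose(rolling_median([5.0] * 7, window=3), 5.0)
        x = [3.0, 1.0, 4.0, 1.0]
        assert np.allclose(rolling_median(x, window=1), x)

    def test_against_brute_force_oracle(self):
        series = np.array([1.0, 2.0, 100.0, 3.0, 4.0])
        window = 3
        # oracle: median of the centered window truncated at the edges
        expected = []
        for i in range(len(series)):
            lo = max(i - window // 2, 0)
            hi = min(i + window // 2 + 1, len(series))
            expected.append(np.median(series[lo:hi]))
        out = rolling_median(series, window=window)
        assert np.allclose(out, expected)
        assert out[2] == 3.0

    def test_fractional_default_window(self):
        out = rolling_median(np.arange(100.0), frac=0.05)
        assert len(out) == 100

    def test_oversized_window_warns(self):
        with pytest.warns(UserWarning):
            out = rolling_median([1.0, 2.0, 9.0], window=10)
        assert np.allclose(out, 2.0)


class TestBinning:
    def _table(self, n):
        recs = [_record(i, 0.1 + 3.0 * i / n) for i in range(n)]
        return assign_pseudotime(recs)

    def test_exact_division(self):
        table = bin_equal_counts(self._table(100), 10)
        counts = table.loc[table["bin"] >= 0, "bin"].value_counts()
        assert (counts == 10).all()

    def test_remainder_dropped_from_high_t(self):
        with pytest.warns(UserWarning):
            table = bin_equal_counts(self._table(107), 10)
        dropped = table[table["bin"] == -1]
        assert len(dropped) == 7
        assert dropped["t"].min() >= table.loc[table["bin"] >= 0, "t"].max()

    def test_bins_contiguous_in_t(self):
        table = bin_equal_counts(self._table(60), 6)
        kept = table[table["bin"] >= 0]
        maxima = kept.groupby("bin")["t"].max().to_numpy()
        minima = kept.groupby("bin")["t"].min().to_numpy()
        assert (maxima[:-1] <= minima[1:]).all()

    def test_too_many_bins(self):
        with pytest.raises(ValueError):
            bin_equal_counts(self._table(5), 10)


class TestAveraging:
    def test_single_site_rotational_symmetrization(self):
        from conftest import azimuthal_sector_means

        rec = _record(0, 2.0)
        tab = _cap_table(jitter=3.0)
        avg = align_rescale_average([rec], {0: tab}, voxel_nm=5.0)
        # azimuthal sector profile through the shell: CV < 5 %
        means = azimuthal_sector_means(
            avg.volume, 5.0, rho_nm=90.0 * math.sin(1.2), z_nm=90.0 * math.cos(1.2)
        )
        assert means.std() / means.mean() < 0.05

    def test_equivariance_under_global_transform(self):
        # same structure recorded at two poses averages to the same volume
        rec_a = _record(0, 2.0)
        tab_a = _cap_table(jitter=2.0, seed=1)
        ang = math.radians(90)
        rot = np.array(
            [[1, 0, 0],
             [0, math.cos(ang), -math.sin(ang)],
             [0, math.sin(ang), math.cos(ang)]]
        )
        # rotation about x by +90° maps the +z pole onto -y
        rec_b = _record(1, 2.0, polar=math.radians(90), azim=math.radians(-90),
                        center=(200.0, 0.0, 0.0))
        tab_b = _cap_table(jitter=2.0, seed=1, rot=rot, shift=(200.0, 0.0, 0.0))
        avg_a = align_rescale_average([rec_a], {0: tab_a})
        avg_ab = align_rescale_average([rec_a, rec_b], {0: tab_a, 1: tab_b})
        na = avg_a.volume / avg_a.volume.sum()
        nab = avg_ab.volume / avg_ab.volume.sum()
        assert np.abs(na - nab).sum() < 0.15  # total-variation distance

    def test_rescaling_to_median_radius(self):
        recs = [_record(0, 2.0, r=80.0), _record(1, 2.0, r=120.0)]
        tabs = {0: _cap_table(r=80.0, jitter=1.0), 1: _cap_table(r=120.0, jitter=1.0)}
        avg = align_rescale_average(recs, tabs)
        assert avg.median_radius == pytest.approx(100.0)
        # radial peak of the rendered shell sits near the common radius
        n = avg.volume.shape[0]
        c = n // 2
        prof = avg.volume[c:, c, c:].diagonal()
        # shell present (non-degenerate rendering)
        assert avg.volume.sum() > 0

    def test_non_converged_sites_skipped(self):
        good = _record(0, 2.0)
        bad = _record(1, 2.0)
        bad.fit.converged = False
        tabs = {0: _cap_table(), 1: _cap_table()}
        with pytest.warns(UserWarning):
            avg = align_rescale_average([good, bad], tabs)
        assert avg.n_sites == 1


class TestMovie:
    def test_frame_arithmetic_and_labels(self):
        recs = [_record(i, 0.1 + 3.0 * i / 70) for i in range(70)]
        table = assign_pseudotime(recs)
        tabs = {i: _cap_table(n=60) for i in range(70)}
        frames = sliding_window_movie(
            table, recs, tabs, window=30, increment=20, voxel_nm=10.0
        )
        assert len(frames) == 3
        medians = [f.median_t for f in frames]
        assert medians == sorted(medians)
        first_expected = table.sort_values("t").head(30)["t"].median()
        assert frames[0].median_t == pytest.approx(first_expected)

    def test_window_larger_than_population(self):
        recs = [_record(i, 0.5 + i / 10) for i in range(5)]
        table = assign_pseudotime(recs)
        with pytest.raises(ValueError):
            sliding_window_movie(table, recs, {}, window=30, increment=20)
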