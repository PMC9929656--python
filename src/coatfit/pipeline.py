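"""End-to-end geometric analysis pipeline.

Ties the stages together: simulate (or read) localizations → detect →
crop → cap fit → flat/disconnected flags → growth-model fits × BIC →
pseudotime → k_on → pseudo-temporal averages.  Every artifact is
written under the configured output directory together with
provenance (config hash, seed, package version); identical config and
seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .capfit import SphericalCapEstimator
from .growth import compare_models_bic, fit_growth_model, fit_kon
from .io import PipelineConfig, read_localizations, write_ground_truth, write_localizations
from .pseudotime import align_rescale_average, assign_pseudotime, bin_equal_counts
from .simulate import simulate_dataset
from .sites import SiteRecord, crop_roi, detect_sites, flag_disconnected, records_to_frame

logger = logging.getLogger("coatfit.pipeline")

__all__ = ["run_pipeline"]


def _stage_log(log_path: Path, stage: str, **counts):
    logger.info("%s: %s", stage, counts)
    with open(log_path, "a") as fh:
        fh.write(json.dumps({"stage": stage, **counts}) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a result bundle of DataFrames.

    Input is either ``config.input_path`` (CSV/HDF5 localization
    table, possibly a multi-site field) or a simulation request
    (``config.n_sites > 0``).  Raises on empty input before any
    fitting stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    log_path.write_text("")
    rng = np.random.default_rng(config.seed)

    # -- stage: input ------------------------------------------------------
    shapes = {}
    if config.input_path:
        locs = read_localizations(config.input_path)
        if len(locs) == 0:
            raise ValueError("input localization table is empty")
        if locs["site_id"].nunique() > 1:
            site_tables = {int(s): t.reset_index(drop=True) for s, t in locs.groupby("site_id")}
        else:
            centers = detect_sites(locs)
            _stage_log(log_path, "detect", n_centers=len(centers))
            if len(centers) == 0:
                raise ValueError("no sites detected in input field")
            site_tables = {
                i: crop_roi(locs, c, config.crop_radius_nm, site_id=i)
                for i, c in enumerate(centers)
            }
    else:
        if config.n_sites < 1:
            raise ValueError("no input file and no simulation requested (n_sites=0)")
        sim = simulate_dataset(
            config.n_sites,
            theta_sampling=config.theta_sampling,
            config=config.simulation,
            seed=int(rng.integers(2**31 - 1)),
        )
        site_tables = {i: t for i, (_s, t) in enumerate(sim)}
        shapes = {i: s for i, (s, _t) in enumerate(sim)}
        all_locs = pd.concat(
            [t.assign(site_id=i) for i, t in site_tables.items()], ignore_index=True
        )
        write_localizations(all_locs, out / "localizations.csv")
        write_ground_truth(shapes, out / "ground_truth.csv", seed=config.seed)
    _stage_log(log_path, "input", n_sites=len(site_tables))

    # -- stage: cap fitting ------------------------------------------------
    records: list[SiteRecord] = []
    for sid, table in site_tables.items():
        if len(table) < 20:
            logger.warning("site %s: too few localizations (%d), skipped", sid, len(table))
            continue
        fit = SphericalCapEstimator(options=config.capfit).fit(table).result_
        records.append(SiteRecord.from_fit(sid, fit, cell_line=config.cell_line))
    if not records:
        raise ValueError("no sites could be fitted")
    flag_disconnected(records, config.disconnected_H_per_nm)
    site_df = records_to_frame(records)
    site_df.to_csv(out / "sites.csv", index=False)
    _stage_log(
        log_path,
        "capfit",
        n_fitted=len(records),
        n_flat=int(site_df["flat"].sum()),
        n_disconnected=int(site_df["disconnected"].sum()),
        n_converged=int(site_df["converged"].sum()),
    )

    # -- stage: growth-model fits + BIC -------------------------------------
    fit_rows, bic_rows = [], []
    kept = [r for r in records if not r.excluded and not r.flat]
    theta = np.array([r.theta for r in kept])
    geoms = {r.site_id: r.geometry for r in kept}
    obs_values = {
        "H": np.array([g.H for g in geoms.values()]),
        "A": np.array([g.A for g in geoms.values()]),
        "epsilon": np.array([g.epsilon for g in geoms.values()]),
        "A_p": np.array([g.A_p for g in geoms.values()]),
    }
    coop_by_obs = {}
    if len(kept) >= 5:
        for obs in config.observables:
            fits = []
            for model in config.growth_models:
                f = fit_growth_model(theta, obs_values[obs], model=model, observable=obs)
                fits.append(f)
                row = {
                    "model": model,
                    "observable": obs,
                    "rss": f.rss_,
                    "bic": f.bic_,
                    "n": f.n_points_,
                    "converged": f.converged_,
                }
                row.update({f"param_{k}": v for k, v in f.params_.items()})
                row.update({f"stderr_{k}": v for k, v in f.stderr_.items()})
                if hasattr(f, "R0_"):
                    row["R0_nm"] = f.R0_
                    row["A0"] = f.A0_
                fit_rows.append(row)
                if model == "CoopCM":
                    coop_by_obs[obs] = f
            for f, delta in compare_models_bic(fits):
                bic_rows.append(
                    {"observable": obs, "model": f.name, "bic": f.bic_, "delta_bic": delta}
                )
    growth_df = pd.DataFrame(fit_rows)
    growth_df.to_csv(out / "growth_fits.csv", index=False)
    pd.DataFrame(bic_rows).to_csv(out / "bic.csv", index=False)
    _stage_log(log_path, "growth", n_points=len(kept), n_fits=len(fit_rows))

    # -- stage: pseudotime + k_on -------------------------------------------
    ptime = assign_pseudotime(records)
    kon_rows = []
    if "H" in coop_by_obs and len(ptime) >= 2:
        th_by_site = {r.site_id: r.theta for r in records}
        tvals = ptime["t"].to_numpy()
        thvals = np.array([th_by_site[s] for s in ptime["site_id"]])
        for obs, f in coop_by_obs.items():
            kon = fit_kon(tvals, thvals, f.params_["gamma"], f.params_["H0"])
            f.kon_ = kon
            kon_rows.append({"observable": obs, "k_on": kon})
    ptime.to_csv(out / "pseudotime.csv", index=False)
    pd.DataFrame(kon_rows).to_csv(out / "kon.csv", index=False)
    _stage_log(log_path, "pseudotime", n_ranked=len(ptime))

    # -- stage: averages -----------------------------------------------------
    averages = []
    n_bins = min(config.n_bins, max(len(ptime) // 2, 1))
    if len(ptime) >= 2:
        binned = bin_equal_counts(ptime, n_bins)
        by_id = {r.site_id: r for r in records}
        for b, sub in binned[binned["bin"] >= 0].groupby("bin"):
            recs = [by_id[s] for s in sub["site_id"]]
            try:
                avg = align_rescale_average(
                    recs, site_tables, median_t=float(sub["t"].median())
                )
            except ValueError as exc:
                logger.warning("bin %s skipped: %s", b, exc)
                continue
            averages.append(avg)
        _write_averages(averages, out)
        _stage_log(log_path, "averages", n_bins=len(averages))

    # -- provenance ----------------------------------------------------------
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "run.json").write_text(json.dumps(provenance, indent=2))
    config.to_yaml(out / "config.yaml")
    return {
        "sites": site_df,
        "growth_fits": growth_df,
        "bic": pd.DataFrame(bic_rows),
        "pseudotime": ptime,
        "kon": pd.DataFrame(kon_rows),
        "averages": averages,
        "records": records,
        "shapes": shapes,
        "provenance": provenance,
        "output_dir": out,
    }


def _write_averages(averages, out: Path):
    """TIFF volume per bin plus a PNG montage of central z-slices."""
    if not averages:
        return
    import tifffile

    for i, avg in enumerate(averages):
        tifffile.imwrite(
            out / f"average_bin{i:02d}.tif",
            avg.volume.astype(np.float32),
            metadata={"voxel_nm": avg.voxel_nm, "median_t": avg.median_t},
        )
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(averages)
        fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.4), squeeze=False)
        for ax, avg in zip(axes[0], averages):
            mid = avg.volume.shape[1] // 2
            half = max(int(25.0 / avg.voxel_nm) // 2, 1)
            sl = avg.volume[:, mid - half : mid + half, :].sum(axis=1)
            ax.imshow(sl.T, origin="lower", cmap="hot")
            ax.set_title(f"t≈{avg.median_t:.2f}", fontsize=8)
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / "averages_montage.png", dpi=150)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - display-level only
        logger.warning("montage rendering failed: %s", exc)
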