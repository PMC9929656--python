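"""Localization-table and configuration I/O.

Localization tables travel as CSV (one header row, canonical columns
``frame,x_nm,y_nm,z_nm,sigma_xy_nm,sigma_z_nm,photons,bg,site_id``) or
as HDF5 with one group per site (``/sites/<id>/localizations`` plus
ground-truth attributes).  Pipeline configuration round-trips through
YAML (JSON is valid YAML and therefore also accepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .capfit import CapFitOptions
from .simulate import LOCALIZATION_COLUMNS, GroundTruthShape, SimulationConfig

__all__ = [
    "read_localizations",
    "write_localizations",
    "write_ground_truth",
    "PipelineConfig",
]

REQUIRED_COLUMNS = (
    "frame",
    "x_nm",
    "y_nm",
    "z_nm",
    "sigma_xy_nm",
    "sigma_z_nm",
    "photons",
    "bg",
)


def _validate_table(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{source}: missing required column '{col}'")
    if "site_id" not in df.columns:
        df["site_id"] = 0
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{source}: column '{col}' has a non-numeric or NaN entry at row {row}"
            )
        df[col] = vals
    return df[list(LOCALIZATION_COLUMNS)]


def read_localizations(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a localization table from CSV or HDF5 (validated, nm units)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if fmt == "csv":
        return _validate_table(pd.read_csv(path), str(path))
    if fmt != "hdf5":
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'hdf5'")
    frames = []
    with h5py.File(path, "r") as f:
        if "sites" not in f:
            raise ValueError(f"{path}: missing /sites group")
        for sid in sorted(f["sites"], key=lambda s: int(s)):
            arr = f["sites"][sid]["localizations"][()]
            df = pd.DataFrame({name: arr[name] for name in arr.dtype.names})
            df["site_id"] = int(sid)
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(LOCALIZATION_COLUMNS))
    return _validate_table(pd.concat(frames, ignore_index=True), str(path))


def write_localizations(df: pd.DataFrame, path, fmt: str | None = None,
                        ground_truth: dict | None = None) -> Path:
    """Write a localization table to CSV or HDF5.

    For HDF5, rows are grouped by ``site_id`` under ``/sites/<id>``;
    ``ground_truth`` maps site_id to an attribute dict stored on the
    group.
    """
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if fmt == "csv":
        df[list(LOCALIZATION_COLUMNS)].to_csv(path, index=False)
        return path
    if fmt != "hdf5":
        raise ValueError(f"unknown format {fmt!r}")
    numeric = [c for c in LOCALIZATION_COLUMNS if c != "site_id"]
    with h5py.File(path, "w") as f:
        grp = f.create_group("sites")
        for sid, sub in df.groupby("site_id"):
            g = grp.create_group(str(int(sid)))
            rec = sub[numeric].to_records(index=False)
            g.create_dataset("localizations", data=rec)
            if ground_truth and sid in ground_truth:
                gt = g.create_group("ground_truth")
                for k, v in ground_truth[sid].items():
                    if v is not None:
                        gt.attrs[k] = v
    return path


def write_ground_truth(shapes: dict[int, GroundTruthShape], path, seed=None) -> Path:
    """Ground-truth sidecar CSV for a simulated cohort."""
    rows = []
    for sid, s in shapes.items():
        rows.append(
            {
                "site_id": sid,
                "kind": s.kind,
                "r_nm": s.r,
                "theta_deg": math.degrees(s.theta) if s.theta is not None else "",
                "D_nm": s.D if s.D is not None else "",
                "cx_nm": s.center[0],
                "cy_nm": s.center[1],
                "cz_nm": s.center[2],
                "ax": s.axis[0],
                "ay": s.axis[1],
                "az": s.axis[2],
                "true_area_nm2": s.true_area,
                "seed": seed if seed is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


@dataclass
class PipelineConfig:
    """Serializable end-to-end pipeline configuration.

    Every stochastic stage derives its seed deterministically from
    ``seed``; units are embedded in the field names.
    """

    cell_line: str = "SK-MEL-2"
    disconnected_H_per_nm: float = 0.016
    seed: int = 0
    output_dir: str = "coatfit_out"
    # simulation request (used when no input file is given)
    n_sites: int = 0
    theta_sampling: str = "uniform_pseudotime"
    input_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    capfit: CapFitOptions = field(default_factory=CapFitOptions)
    growth_models: tuple[str, ...] = ("CAM", "CCM", "CoopCM", "LinearCM")
    observables: tuple[str, ...] = ("H", "A", "epsilon", "A_p")
    rolling_window_frac: float = 0.05
    n_bins: int = 10
    movie_window: int = 30
    movie_increment: int = 20
    crop_radius_nm: float = 300.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)
        return Path(path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "simulation" in kw and isinstance(kw["simulation"], dict):
            kw["simulation"] = SimulationConfig(**kw["simulation"])
        if "capfit" in kw and isinstance(kw["capfit"], dict):
            cf = dict(kw["capfit"])
            if "theta_multistart" in cf:
                cf["theta_multistart"] = tuple(cf["theta_multistart"])
            kw["capfit"] = CapFitOptions(**cf)
        for key in ("growth_models", "observables"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _listify(obj):
    """yaml-safe: tuples to lists, recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
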