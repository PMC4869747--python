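"""Readers and writers for the pipeline's on-disk formats.

* Images and maps: TIFF (raw images float/integer; masks 8-bit; LOF maps
  32-bit float degrees with NaN off-mask).
* Force curves: a small CSV dialect — ``#`` header lines carrying the
  calibration metadata (spring constant, tip half-angle, glass reference,
  curve id), then two columns ``z_nm,d_nm``.
* Per-cell records and fit tables: TSV.
* Configuration and calibration models: YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import ForceCurve
from .calibration import CalibrationModel

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_lof",
    "read_lof",
    "write_curve",
    "read_curve",
    "write_records",
    "read_records",
    "write_calibration",
    "read_calibration",
]


def write_image(path, image):
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask(path, mask):
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_lof(path, lof_deg):
    tifffile.imwrite(path, np.asarray(lof_deg, dtype=np.float32))


def read_lof(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_curve(path, curve: ForceCurve):
    with open(path, "w") as fh:
        fh.write(f"# k={curve.k_n_per_m:g}\n")
        fh.write(f"# theta_deg={curve.theta_deg:g}\n")
        fh.write(f"# z_glass_nm={curve.z_glass_nm:g}\n")
        if curve.curve_id:
            fh.write(f"# id={curve.curve_id}\n")
        fh.write("z_nm,d_nm\n")
        for z, d in zip(curve.z_nm, curve.d_nm):
            fh.write(f"{z:.6g},{d:.6g}\n")


def read_curve(path) -> ForceCurve:
    meta = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body.append(line)
    for required in ("k", "theta_deg", "z_glass_nm"):
        if required not in meta:
            raise ValueError(f"curve file {path} missing '# {required}=' header")
    table = pd.read_csv(_io.StringIO("".join(body)))
    if not {"z_nm", "d_nm"} <= set(table.columns):
        raise ValueError(f"curve file {path} must have z_nm,d_nm columns")
    return ForceCurve(
        z_nm=table["z_nm"].to_numpy(),
        d_nm=table["d_nm"].to_numpy(),
        k_n_per_m=float(meta["k"]),
        theta_deg=float(meta["theta_deg"]),
        z_glass_nm=float(meta["z_glass_nm"]),
        curve_id=meta.get("id", Path(path).stem),
    )


def write_records(path, records: pd.DataFrame):
    records.to_csv(path, sep="\t", index=False)


def read_records(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_calibration(path, model: CalibrationModel):
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"p_endo": model.p_endo, "batch": model.batch,
             "n_cells": model.n_cells, "diagnostics": model.diagnostics},
            fh,
        )


def read_calibration(path) -> CalibrationModel:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CalibrationModel(p_endo=float(raw["p_endo"]),
                            batch=raw.get("batch", ""),
                            n_cells=int(raw.get("n_cells", 0)),
                            diagnostics=raw.get("diagnostics", {}))
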