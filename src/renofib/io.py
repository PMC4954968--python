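"""Reading and writing the pipeline's on-disk formats.

Image series and parametric maps travel as NIfTI volumes with a JSON sidecar
(``{"b_values": [...]}``, ``{"inversion_times_ms": [...]}`` or
``{"units": ...}``); b-values are also accepted in FSL-style ``.bval`` text
layout. ROI tables are CSV, histology images TIFF/PNG with a JSON sidecar
carrying the µm/pixel calibration and ROI polygon.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mapping import DiffusionSeries, InversionSeries, ParametricMap


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_series(series: DiffusionSeries | InversionSeries, path: str | Path) -> None:
    path = Path(path)
    # NIfTI stores the stack axis last
    data = np.moveaxis(series.volumes, 0, -1)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    if isinstance(series, DiffusionSeries):
        sidecar = {
            "b_values": series.b_values.tolist(),
            "pixel_spacing_mm": list(series.pixel_spacing),
        }
    else:
        sidecar = {"inversion_times_ms": series.inversion_times.tolist()}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_diffusion_series(path: str | Path, bval_path: str | Path | None = None) -> DiffusionSeries:
    """Load a DWI stack; b-values from the JSON sidecar or an FSL .bval file."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:2])
    if bval_path is not None:
        b = np.loadtxt(str(bval_path)).ravel()
        return DiffusionSeries(data, b, spacing)
    sidecar = json.loads(_sidecar_path(path).read_text())
    spacing = tuple(sidecar.get("pixel_spacing_mm", spacing))
    return DiffusionSeries(data, np.asarray(sidecar["b_values"], float), spacing)


def load_inversion_series(path: str | Path) -> InversionSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    sidecar = json.loads(_sidecar_path(path).read_text())
    return InversionSeries(data, np.asarray(sidecar["inversion_times_ms"], float))


def save_map(pmap: ParametricMap, path: str | Path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(pmap.values, affine=np.eye(4)), str(path))
    _sidecar_path(path).write_text(json.dumps({"units": pmap.units}, indent=1))
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii", 1))
    nib.save(nib.Nifti1Image(pmap.mask.astype(np.uint8), affine=np.eye(4)), str(mask_path))


def load_map(path: str | Path) -> ParametricMap:
    path = Path(path)
    values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    units = json.loads(_sidecar_path(path).read_text())["units"]
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii", 1))
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    else:
        mask = np.isfinite(values)
    return ParametricMap(values, mask, units)


def save_label_map(labels: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine=np.eye(4)), str(Path(path)))


def load_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(Path(path))).dataobj).astype(int)


def load_roi_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"label", "compartment"}
    if not required <= set(df.columns):
        raise ValueError(f"roi table must have columns {sorted(required)}")
    return df


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
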