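"""File formats: NIfTI volumes, delimited physio/cohort tables, configs, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from cvrkit.errors import InvalidArgumentError
from cvrkit.physio import EtCO2Trace

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_physio",
    "write_physio",
    "read_cohort",
    "write_cohort",
    "load_config",
    "save_config",
    "write_manifest",
]

PHYSIO_COLUMNS = ("time_s", "co2_mmHg")


def read_nifti(path):
    """Read a NIfTI-1/2 image.

    Returns (data, affine, spacing_mm) for 3-D images and
    (data, affine, spacing_mm, tr_s) for 4-D, with the TR taken from the
    header's fourth zoom.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise InvalidArgumentError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if data.ndim == 4:
        tr_s = float(zooms[3]) if len(zooms) > 3 else float("nan")
        return data, img.affine, spacing, tr_s
    return data, img.affine, spacing


def write_nifti(volume, path, affine=None, spacing_mm=None, tr_s=None):
    """Write an array as NIfTI, preserving spacing (and TR for 4-D data)."""
    volume = np.asarray(volume)
    if affine is None:
        spacing_mm = spacing_mm or (1.0, 1.0, 1.0)
        affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.astype(np.float32), affine)
    if spacing_mm is not None:
        zooms = list(spacing_mm)
        if volume.ndim == 4:
            zooms.append(tr_s if tr_s else 1.0)
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_physio(path) -> EtCO2Trace:
    """Read a delimited physio table; requires time_s and co2_mmHg columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PHYSIO_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"physio file {path} lacks columns {missing}")
    return EtCO2Trace(
        times_s=df["time_s"].to_numpy(float),
        values_mmHg=df["co2_mmHg"].to_numpy(float),
        source="measured",
    )


def write_physio(trace: EtCO2Trace, path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "co2_mmHg": trace.values_mmHg}).to_csv(
        path, index=False
    )


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"config {path} must be a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
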