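"""File round-trips for the pipeline's standard formats: NIfTI runs
with JSON sidecars, pattern tables, and provenance YAML."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synth.bold import BoldTimeseries

__all__ = [
    "write_bold_nifti",
    "read_bold_nifti",
    "write_pattern_table",
    "read_pattern_table",
    "write_provenance",
]


def write_bold_nifti(ts: BoldTimeseries, path: str | Path) -> None:
    """4-D NIfTI (voxels laid out on the first axis) + JSON sidecar
    carrying TR and run index."""
    path = Path(path)
    data = ts.data.astype(np.float32)  # (V, T) -> (V, 1, 1, T)
    img = nib.Nifti1Image(data[:, None, None, :], affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"RepetitionTime": ts.tr, "run": ts.run_index}, fh)


def read_bold_nifti(path: str | Path) -> BoldTimeseries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    V = data.shape[0]
    data = data.reshape(V, -1)
    sidecar = path.with_suffix(".json")
    tr, run = float(img.header.get_zooms()[-1]), 0
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        tr = float(meta.get("RepetitionTime", tr))
        run = int(meta.get("run", 0))
    return BoldTimeseries(data=data, tr=tr, run_index=run)


def write_pattern_table(names, array: np.ndarray, path: str | Path) -> None:
    """Scene x voxel table as CSV with the scene/regressor id as index."""
    pd.DataFrame(array, index=list(names)).to_csv(path, index_label="name")


def read_pattern_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col="name")
    return list(df.index), df.to_numpy(dtype=float)


def write_provenance(path: str | Path, **payload) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
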