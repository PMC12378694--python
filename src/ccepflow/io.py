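"""Readers/writers for the pipeline's on-disk formats.

Electrode tables are TSV, masks NIfTI (1 mm isotropic, identity-plus-offset
affine), epochs HDF5 (``/stim_pair_{id}/data`` with trials x channels x
samples and fs/t0/stim attributes), tabular results CSV, model reports JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import Geometry
from .localization import VolumeMask
from .preprocess import EpochSet


def write_electrode_tsv(geometry: Geometry, path) -> Path:
    path = Path(path)
    geometry.contact_table().to_csv(path, sep="\t", index=False)
    return path


def read_electrode_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mask_nifti(mask: VolumeMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask.values, dtype=np.float32), mask.affine)
    nib.save(img, str(path))
    return path


def read_mask_nifti(path) -> VolumeMask:
    img = nib.load(str(path))
    return VolumeMask(np.asarray(img.get_fdata()), img.affine)


def write_epochs_h5(epoch_sets: dict[int, EpochSet], path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for stim_id, ep in epoch_sets.items():
            grp = f.create_group(f"stim_pair_{stim_id}")
            grp.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
            grp.attrs["fs"] = ep.fs
            grp.attrs["t0_ms"] = ep.t0_ms
            grp.attrs["stim_channel"] = ep.stim_channel
            grp.attrs["channel_ids"] = [str(c) for c in ep.channel_ids]
    return path


def read_epochs_h5(path) -> dict[int, EpochSet]:
    out = {}
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            stim_id = int(name.rsplit("_", 1)[1])
            out[stim_id] = EpochSet(
                data=grp["data"][()],
                fs=float(grp.attrs["fs"]),
                t0_ms=float(grp.attrs["t0_ms"]),
                stim_channel=int(grp.attrs["stim_channel"]),
                channel_ids=[str(c) for c in grp.attrs["channel_ids"]],
            )
    return out


def write_evoked_h5(waveforms: dict[tuple[int, int], np.ndarray], fs: float, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("edges")
        grp.attrs["fs"] = fs
        for (stim, rec), w in waveforms.items():
            grp.create_dataset(f"{stim}__{rec}/waveform", data=w)
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
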