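"""File I/O: NIfTI volumes, offset tables, sidecar metadata.

Saturation stacks are stored as (H, W, K) NIfTI volumes with identity
affines (single 2D slice; the third axis indexes offsets), the offset table
as a two-column CSV (index, ppm), labels as integer NIfTI, and B0 maps as
NIfTI with a sidecar JSON recording the unit (ppm).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import LabelImage, OffsetSchedule, ROI_NAMES
from .preproc import B0Map, WassrImage, ZSpectrumImage


def save_nifti(array: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), np.eye(4)), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_offsets(schedule: OffsetSchedule, path) -> None:
    pd.DataFrame({"index": np.arange(len(schedule)), "ppm": schedule.offsets}).to_csv(
        path, index=False)


def load_offsets(path) -> OffsetSchedule:
    ppm = pd.read_csv(path)["ppm"].to_numpy(dtype=float)
    return OffsetSchedule(offsets=np.sort(np.unique(ppm)), segments=(), sides="symmetric")


def save_zspec(zspec: ZSpectrumImage, prefix) -> None:
    prefix = Path(prefix)
    save_nifti(zspec.data, prefix.with_suffix(".nii"))
    save_nifti(zspec.reference, prefix.parent / (prefix.name + "_ref.nii"))
    save_nifti(zspec.mask.astype(np.uint8), prefix.parent / (prefix.name + "_mask.nii"))
    save_offsets(zspec.schedule, prefix.parent / (prefix.name + "_offsets.csv"))


def load_zspec(prefix) -> ZSpectrumImage:
    prefix = Path(prefix)
    return ZSpectrumImage(
        data=load_nifti(prefix.with_suffix(".nii")),
        schedule=load_offsets(prefix.parent / (prefix.name + "_offsets.csv")),
        reference=load_nifti(prefix.parent / (prefix.name + "_ref.nii")),
        mask=load_nifti(prefix.parent / (prefix.name + "_mask.nii")) > 0.5,
    )


def save_wassr(wassr: WassrImage, prefix) -> None:
    prefix = Path(prefix)
    save_nifti(wassr.data, prefix.with_suffix(".nii"))
    save_offsets(wassr.schedule, prefix.parent / (prefix.name + "_offsets.csv"))


def load_wassr(prefix) -> WassrImage:
    prefix = Path(prefix)
    sched = load_offsets(prefix.parent / (prefix.name + "_offsets.csv"))
    return WassrImage(data=load_nifti(prefix.with_suffix(".nii")), schedule=sched)


def save_labels(labels: LabelImage, path) -> None:
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), np.eye(4)), str(path))
    with open(str(path) + ".json", "w") as fh:
        json.dump({str(k): v for k, v in labels.roi_names.items()}, fh, indent=2)


def load_labels(path) -> LabelImage:
    arr = np.asarray(nib.load(str(path)).get_fdata()).astype(np.int32)
    names_path = Path(str(path) + ".json")
    if names_path.exists():
        with open(names_path) as fh:
            names = {int(k): v for k, v in json.load(fh).items()}
    else:
        names = dict(ROI_NAMES)
    return LabelImage(labels=arr, roi_names=names)


def save_b0map(b0: B0Map, path) -> None:
    save_nifti(b0.shift, path)
    save_nifti(b0.valid.astype(np.uint8), Path(str(path)).parent / (Path(str(path)).name + "_valid.nii"))
    with open(str(path) + ".json", "w") as fh:
        json.dump({"units": "ppm"}, fh)
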