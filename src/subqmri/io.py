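"""NIfTI-1 and table I/O helpers.

Volumes are written as float32 NIfTI-1 (masks as uint8); statistics stay in
double precision and go to CSV. File naming is a flat convention:
``<subject>_<kind>[_<structure>_<hemi>[_<rater>]].nii``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["write_volume", "read_volume", "write_mask", "read_mask", "save_subject"]


def write_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_mask(path, mask: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8), np.asarray(affine)
    )
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, np.asarray(img.affine)


def save_subject(record, out_dir, write_echoes: bool = True) -> None:
    """Write one phantom subject's maps, masks, and echoes to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    aff = record.affine
    write_volume(out / f"{sid}_t1map.nii", record.t1_map, aff)
    write_volume(out / f"{sid}_t2starmap-truth.nii", record.t2s_map, aff)
    write_volume(out / f"{sid}_chimap-truth.nii", record.chi_map, aff)
    write_mask(out / f"{sid}_brainmask.nii", record.brain_mask, aff)
    for (name, hemi), (r1, r2) in record.rater_masks.items():
        write_mask(out / f"{sid}_mask_{name}_{hemi}_rater1.nii", r1, aff)
        write_mask(out / f"{sid}_mask_{name}_{hemi}_rater2.nii", r2, aff)
    if write_echoes and record.series is not None:
        for i in range(len(record.series.echo_times_ms)):
            write_volume(out / f"{sid}_echo{i + 1}_mag.nii",
                         record.series.magnitude[..., i], aff)
            write_volume(out / f"{sid}_echo{i + 1}_phase.nii",
                         record.series.phase[..., i], aff)


def save_subject_table(records, path) -> pd.DataFrame:
    """Write the cohort subject table (subject, age, group, seed) as CSV."""
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "group": [r.group for r in records],
            "seed": [r.seed for r in records],
        }
    )
    df.to_csv(path, index=False)
    return df
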