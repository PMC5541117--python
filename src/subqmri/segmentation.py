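"""Inter-rater agreement, conjunction masks, and ROI value extraction.

Manual parcellations by two raters are compared with the Dice coefficient
and combined by voxelwise intersection (the conjunction mask), which is
the ROI used for all quantitative extraction. For structures that abut CSF
(striatum next to the lateral ventricle, periaqueductal grey around the
cerebral aqueduct), partial-volume voxels carry CSF-like T1/T2* values;
the mean value of the CSF reference compartment is used as an upper
threshold when extracting the ROI mean, and both the thresholded and
non-thresholded means are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ROISummary", "dice", "conjunction", "mask_volume_mm3", "extract_roi_means"]


@dataclass
class ROISummary:
    """Quantitative summary of one ROI on one map."""

    structure: str
    hemisphere: str
    n_voxels: int
    mean: float  # thresholded mean if a CSF reference was applied
    mean_unthresholded: float
    csf_threshold: float | None
    n_excluded: int


def _check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"masks live on different grids: {a.shape} vs {b.shape}")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A| + |B|).

    Undefined (raises) when both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    _check_same_grid(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice coefficient is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise AND of two rater masks; warns if the intersection is empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    _check_same_grid(a, b)
    out = a & b
    if not out.any():
        warnings.warn("conjunction mask is empty", stacklevel=2)
    return out


def mask_volume_mm3(mask: np.ndarray, voxel_size) -> float:
    """Mask volume: voxel count times voxel volume (mm^3)."""
    return float(np.asarray(mask, dtype=bool).sum()) * float(np.prod(voxel_size))


def extract_roi_means(
    qmap: np.ndarray,
    roi_mask: np.ndarray,
    csf_reference_mask: np.ndarray | None = None,
    structure: str = "",
    hemisphere: str = "",
) -> ROISummary:
    """Mean map value over an ROI, optionally CSF-upper-thresholded.

    When ``csf_reference_mask`` is given, its mean on the same map becomes
    an upper threshold: ROI voxels with value >= that mean are excluded
    (strict exclusion at the threshold) before averaging. Both the
    thresholded and the plain mean are reported.
    """
    qmap = np.asarray(qmap, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    _check_same_grid(qmap, roi)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = qmap[roi]
    plain_mean = float(vals.mean())
    if csf_reference_mask is None:
        return ROISummary(
            structure=structure,
            hemisphere=hemisphere,
            n_voxels=int(roi.sum()),
            mean=plain_mean,
            mean_unthresholded=plain_mean,
            csf_threshold=None,
            n_excluded=0,
        )
    csf = np.asarray(csf_reference_mask, dtype=bool)
    _check_same_grid(qmap, csf)
    if not csf.any():
        raise ValueError("CSF reference mask is empty")
    threshold = float(qmap[csf].mean())
    keep = vals < threshold
    if not keep.any():
        raise ValueError(
            f"CSF threshold {threshold:g} excluded every ROI voxel"
        )
    return ROISummary(
        structure=structure,
        hemisphere=hemisphere,
        n_voxels=int(roi.sum()),
        mean=float(vals[keep].mean()),
        mean_unthresholded=plain_mean,
        csf_threshold=threshold,
        n_excluded=int((~keep).sum()),
    )
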