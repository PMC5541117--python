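"""Location analysis: centers of mass, mirrored-CoM PCA, atlas overlap.

To test whether a nucleus shifts location with age, each subject's
structure center of mass is taken to template millimeter coordinates,
left-hemisphere X coordinates are mirrored to positive X (no a-priori
lateralization hypothesis), and a single PCA across subjects and
hemispheres reduces (X, Y, Z) to a first-component score per observation —
the latent location variable that is subsequently correlated with age.

Probabilistic atlas maps report, per voxel, the percentage of subjects
whose mask contains it; the maximum and the mean percentage overlap over
the atlas support summarize inter-subject anatomical consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoMRecord",
    "LocationPCAResult",
    "AtlasProbMap",
    "center_of_mass",
    "location_pca",
    "overlap_metrics",
]


@dataclass
class CoMRecord:
    """One structure's center of mass in template millimeters."""

    subject: str
    structure: str
    hemisphere: str
    xyz_mm: tuple[float, float, float]
    mirrored: bool = False


@dataclass
class LocationPCAResult:
    """First-principal-component summary of mirrored CoM coordinates."""

    structure: str
    loadings: np.ndarray  # (3, 3), rows = components, unit norm
    explained_variance_ratio: np.ndarray  # (3,), sums to 1
    scores: np.ndarray  # (n,) first-component scores
    mean_xyz: np.ndarray


@dataclass
class AtlasProbMap:
    """Diedrichsen-style probabilistic atlas of one structure."""

    structure: str
    group: str
    probability: np.ndarray  # % of subjects, 0-100, zero off-support
    n_subjects: int
    max_overlap: float
    mean_overlap: float


def center_of_mass(
    mask: np.ndarray,
    affine: np.ndarray,
    subject: str = "",
    structure: str = "",
    hemisphere: str = "",
) -> CoMRecord:
    """Unweighted voxel centroid mapped through the affine to mm coordinates."""
    mask = np.asarray(mask, dtype=bool)
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError("cannot compute the center of mass of an empty mask")
    com_vox = np.array([i.mean() for i in idx], dtype=float)
    xyz = (np.asarray(affine) @ np.append(com_vox, 1.0))[:3]
    return CoMRecord(
        subject=subject,
        structure=structure,
        hemisphere=hemisphere,
        xyz_mm=tuple(float(v) for v in xyz),
    )


def location_pca(
    records: list[CoMRecord],
    mirror_left: bool = True,
    structure: str | None = None,
) -> LocationPCAResult:
    """PCA of (X, Y, Z) CoM coordinates pooled across hemispheres.

    Negative X coordinates (the left hemisphere in a right-positive
    template) are converted to positive values so both hemispheres enter
    one analysis; the result is therefore invariant to which hemisphere is
    labeled left. The covariance matrix (coordinates share mm units) is
    eigen-decomposed; the first component's scores are returned per
    record, with the component sign fixed so its largest-magnitude loading
    is positive.
    """
    if len(records) < 4:
        raise ValueError("location PCA needs at least 4 CoM records")
    names = {r.structure for r in records}
    if structure is None:
        if len(names) > 1:
            raise ValueError(f"records mix structures: {sorted(names)}")
        structure = next(iter(names))
    coords = np.array([r.xyz_mm for r in records], dtype=float)
    if mirror_left:
        negative = coords[:, 0] < 0
        coords[:, 0] = np.abs(coords[:, 0])
        for r, was_neg in zip(records, negative):
            r.mirrored = bool(was_neg)
    mean = coords.mean(axis=0)
    centered = coords - mean
    cov = centered.T @ centered / (len(records) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 1e-12:
        raise ValueError("CoM coordinates are rank deficient (all identical)")
    # sign convention: largest-|loading| entry of each component positive
    for j in range(3):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    ratio = evals / evals.sum()
    scores = centered @ evecs[:, 0]
    return LocationPCAResult(
        structure=structure,
        loadings=evecs.T,
        explained_variance_ratio=ratio,
        scores=scores,
        mean_xyz=mean,
    )


def overlap_metrics(
    masks: list[np.ndarray],
    structure: str = "",
    group: str = "",
) -> AtlasProbMap:
    """Probabilistic atlas and its maximum / mean percentage overlap.

    probability(v) = 100 * (# subjects whose mask contains v) / n, defined
    on the union support (count >= 1). The maximum is the peak
    probability; the mean averages over the support.
    """
    if len(masks) < 2:
        raise ValueError("overlap metrics need at least 2 masks")
    shape = np.asarray(masks[0]).shape
    count = np.zeros(shape, dtype=np.int32)
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError(f"masks live on different grids: {m.shape} vs {shape}")
        count += m
    n = len(masks)
    prob = 100.0 * count / n
    support = count >= 1
    if not support.any():
        raise ValueError("all masks are empty")
    return AtlasProbMap(
        structure=structure,
        group=group,
        probability=np.where(support, prob, 0.0),
        n_subjects=n,
        max_overlap=float(prob[support].max()),
        mean_overlap=float(prob[support].mean()),
    )
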