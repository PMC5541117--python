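"""Quantitative susceptibility mapping from gradient-echo phase.

The reconstruction chain is the classic single-orientation one:

1. :func:`phase_to_field` — unwrap the phase of one echo and scale it to a
   relative field shift in ppm of the static field.
2. :func:`remove_background` — SHARP-style spherical-mean-value (SMV)
   filtering with truncated deconvolution, removing field components that
   are harmonic inside the brain (air/tissue interfaces, shim).
3. :func:`invert_dipole` — thresholded k-space division (TKD) by the unit
   dipole kernel ``D(k) = 1/3 - kz^2/|k|^2``.
4. :func:`normalize_to_ventricles` — reference the susceptibility map to
   the CSF of the lateral ventricles (eroded conjunction mask), since the
   raw offset of a single-echo QSM is arbitrary.

All operators share one k-space convention (B0 along the third array
axis, DC term of the dipole kernel set to zero), so the forward model in
:func:`field_from_susceptibility` is the exact grid adjoint of the
inversion — phantom round trips are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.stats import norm
from skimage.restoration import unwrap_phase as _unwrap_region

__all__ = [
    "FieldMap",
    "SusceptibilityMap",
    "dipole_kernel",
    "field_from_susceptibility",
    "phase_to_field",
    "remove_background",
    "invert_dipole",
    "normalize_to_ventricles",
    "erode_mask_gaussian",
]

#: Larmor frequency (MHz) of protons at 7 T; converts phase/TE to ppm.
F0_MHZ_7T = 297.2


@dataclass
class FieldMap:
    """Relative field perturbation in ppm with its region of validity."""

    field: np.ndarray  # ppm
    brain_mask: np.ndarray  # bool
    valid_mask: np.ndarray  # bool, subset of brain_mask
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if np.any(self.valid_mask & ~self.brain_mask):
            raise ValueError("valid-region mask must be a subset of the brain mask")


@dataclass
class SusceptibilityMap:
    """Susceptibility map (ppm) plus reconstruction provenance."""

    chi: np.ndarray  # ppm
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    reference_offset: float = 0.0  # ppm subtracted during normalization
    inversion_threshold: float | None = None
    metadata: dict = dc_field(default_factory=dict)


@lru_cache(maxsize=8)
def _dipole_kernel_cached(shape, voxel_size) -> np.ndarray:
    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    k2 = kx * kx + ky * ky + kz * kz
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kz * kz / k2
    d[0, 0, 0] = 0.0
    d.setflags(write=False)
    return d


def dipole_kernel(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Unit magnetic dipole kernel in k-space, B0 along the third axis.

    ``D(k) = 1/3 - kz^2 / |k|^2`` with the k = 0 component set to 0 (the
    mean field shift of a susceptibility distribution is not observable).
    The kernel is cached per grid, so forward simulation and inversion
    share one array.
    """
    return _dipole_kernel_cached(tuple(shape), tuple(float(v) for v in voxel_size))


def field_from_susceptibility(
    chi: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Forward dipole convolution: susceptibility (ppm) -> field shift (ppm).

    Because the kernel is mean-free, adding a uniform offset to ``chi``
    does not change the internal field perturbation.
    """
    d = dipole_kernel(chi.shape, voxel_size)
    return np.fft.ifftn(np.fft.fftn(chi) * d).real


def _laplacian_unwrap(phase: np.ndarray, voxel_size) -> np.ndarray:
    """FFT Laplacian-based phase unwrapping (periodic boundary)."""
    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(phase.shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    k2 = (2 * np.pi) ** 2 * (kx * kx + ky * ky + kz * kz)
    lap = (
        np.cos(phase) * np.fft.ifftn(-k2 * np.fft.fftn(np.sin(phase)))
        - np.sin(phase) * np.fft.ifftn(-k2 * np.fft.fftn(np.cos(phase)))
    ).real
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(k2 > 0, 1.0 / k2, 0.0)
    return np.fft.ifftn(-np.fft.fftn(lap) * inv).real


def unwrap(phase: np.ndarray, mask: np.ndarray, method: str = "region",
           voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Unwrap a wrapped phase volume inside ``mask``.

    ``region`` (default) uses the reliability-sorted algorithm from
    scikit-image, which recovers the true phase up to a single global
    2*pi multiple; that multiple is anchored by rounding the masked
    median offset from the wrapped input. ``laplacian`` solves the
    Poisson equation for the phase Laplacian in k-space; it is faster on
    large volumes but only approximate near the mask edge.
    """
    mask = np.asarray(mask, dtype=bool)
    if method == "region":
        marr = np.ma.array(phase, mask=~mask)
        out = np.asarray(_unwrap_region(marr))
        off = np.ma.median(np.ma.array(out - phase, mask=~mask))
        out = out - 2 * np.pi * np.round(off / (2 * np.pi))
        return np.where(mask, out, 0.0)
    if method == "laplacian":
        out = _laplacian_unwrap(phase, voxel_size)
        # re-anchor: the Poisson solve loses the global offset
        off = np.median((out - phase)[mask])
        return np.where(mask, out - 2 * np.pi * np.round(off / (2 * np.pi)), 0.0)
    raise ValueError(f"unknown unwrap method {method!r}")


def phase_to_field(
    series,
    echo_index: int = 0,
    mask: np.ndarray | None = None,
    f0_mhz: float = F0_MHZ_7T,
    unwrap_method: str = "region",
) -> FieldMap:
    """Estimate the relative field shift (ppm) from one echo's phase.

    field_ppm = unwrapped_phase / (2*pi * TE_s * f0_MHz); a single echo is
    used (the first echo has the highest SNR at 7 T).
    """
    if series.phase is None:
        raise ValueError("multi-echo series carries no phase data")
    n_echoes = len(series.echo_times_ms)
    if not (0 <= echo_index < n_echoes):
        raise IndexError(f"echo index {echo_index} out of range for {n_echoes} echoes")
    phase = np.asarray(series.phase[..., echo_index], dtype=float)
    if mask is None:
        mask = np.ones(phase.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    te_s = series.echo_times_ms[echo_index] * 1e-3
    unwrapped = unwrap(phase, mask, method=unwrap_method, voxel_size=series.voxel_size)
    fld = unwrapped / (2.0 * np.pi * te_s * f0_mhz)
    return FieldMap(
        field=np.where(mask, fld, 0.0),
        brain_mask=mask,
        valid_mask=mask.copy(),
        voxel_size=tuple(series.voxel_size),
    )


@lru_cache(maxsize=8)
def _smv_sphere_fft(shape, voxel_size, radius_mm: float) -> np.ndarray:
    """k-space transfer function of a normalized sphere centered at the origin."""
    coords = [np.fft.fftfreq(n, d=1.0) * n * v for n, v in zip(shape, voxel_size)]
    rx, ry, rz = np.meshgrid(*coords, indexing="ij")
    sphere = (rx * rx + ry * ry + rz * rz <= radius_mm**2).astype(float)
    total = sphere.sum()
    if total < 2:
        raise ValueError(f"SMV radius {radius_mm} mm spans fewer than 2 voxels")
    out = np.fft.fftn(sphere / total).real  # symmetric kernel -> real spectrum
    out.setflags(write=False)
    return out


def remove_background(
    fieldmap: FieldMap,
    radius_mm: float = 4.0,
    threshold: float = 0.05,
    valid_mask: np.ndarray | None = None,
) -> FieldMap:
    """SHARP background-field removal via SMV filtering and deconvolution.

    Harmonic fields satisfy the spherical-mean-value property, so the
    high-pass operator ``(1 - S)`` (S = normalized sphere) annihilates
    them; the remaining internal field is recovered by truncated k-space
    deconvolution of the same operator. The result is valid only on the
    brain mask eroded by the kernel radius; a precomputed ``valid_mask``
    (the eroded mask) may be passed to skip the distance transform when
    the same brain mask is processed repeatedly.
    """
    voxel = fieldmap.voxel_size
    if radius_mm < min(voxel):
        raise ValueError(
            f"SMV radius {radius_mm} mm is below one voxel ({min(voxel)} mm)"
        )
    mask = fieldmap.brain_mask
    shape = fieldmap.field.shape
    c = 1.0 - _smv_sphere_fft(
        tuple(shape), tuple(float(v) for v in voxel), float(radius_mm)
    )

    # valid region: mask eroded by the kernel radius (euclidean distance)
    if valid_mask is not None:
        eroded = np.asarray(valid_mask, dtype=bool)
        if np.any(eroded & ~mask):
            raise ValueError("valid_mask must be a subset of the brain mask")
    else:
        dist = ndimage.distance_transform_edt(mask, sampling=voxel)
        eroded = dist > radius_mm
    if not eroded.any():
        raise ValueError(
            "brain mask is thinner than the SMV kernel everywhere; "
            "reduce radius_mm"
        )

    filtered = np.fft.ifftn(np.fft.fftn(fieldmap.field * mask) * c).real
    filtered *= eroded
    spec = np.fft.fftn(filtered)
    c_abs = np.abs(c)
    inv = np.where(c_abs >= threshold, spec / np.where(c_abs >= threshold, c, 1.0), 0.0)
    internal = np.fft.ifftn(inv).real * eroded
    return FieldMap(
        field=internal,
        brain_mask=mask,
        valid_mask=eroded,
        voxel_size=voxel,
    )


def invert_dipole(fieldmap: FieldMap, threshold: float = 0.1) -> SusceptibilityMap:
    """Thresholded k-space division (TKD / superfast dipole inversion).

    Divides the field spectrum by the dipole kernel, flooring the divisor
    at ``threshold * sign(D)`` on the kernel's zero cone. ``threshold``
    must lie in (0, 2/3), the kernel's maximum magnitude.
    """
    if not 0.0 < threshold < 2.0 / 3.0:
        raise ValueError(f"TKD threshold must be in (0, 2/3), got {threshold}")
    d = dipole_kernel(fieldmap.field.shape, fieldmap.voxel_size)
    sign = np.where(d >= 0, 1.0, -1.0)
    d_reg = np.where(np.abs(d) < threshold, threshold * sign, d)
    spec = np.fft.fftn(fieldmap.field * fieldmap.valid_mask)
    chi = np.fft.ifftn(spec / d_reg).real
    chi[~fieldmap.valid_mask] = 0.0
    return SusceptibilityMap(
        chi=chi,
        voxel_size=fieldmap.voxel_size,
        inversion_threshold=threshold,
    )


def erode_mask_gaussian(
    mask: np.ndarray,
    kernel_mm: float,
    voxel_size=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Erode a binary mask by ``kernel_mm`` via Gaussian smooth-and-threshold.

    The binary mask is smoothed with sigma = kernel/2 (mm) and
    re-thresholded at Phi(kernel/sigma) = Phi(2) ~ 0.977 — the smoothed
    value found exactly ``kernel_mm`` inside a flat boundary — so a flat
    face recedes by the kernel width with sub-voxel accuracy.
    """
    mask = np.asarray(mask, dtype=float)
    sigma_mm = kernel_mm / 2.0
    sigma_vox = [sigma_mm / v for v in voxel_size]
    smoothed = ndimage.gaussian_filter(mask, sigma=sigma_vox)
    return smoothed >= norm.cdf(kernel_mm / sigma_mm)


def normalize_to_ventricles(
    chi_map: SusceptibilityMap,
    ventricle_mask: np.ndarray,
    erosion_mm: float = 2.0,
) -> SusceptibilityMap:
    """Zero-reference a susceptibility map to lateral-ventricle CSF.

    The ventricle conjunction mask is eroded (to keep partial-volume gray
    matter out of the reference) and the mean susceptibility over the
    eroded mask is subtracted everywhere. The subtracted offset is
    recorded so the operation is invertible and idempotent.
    """
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if erosion_mm > 0:
        eroded = erode_mask_gaussian(ventricle_mask, erosion_mm, chi_map.voxel_size)
    else:
        eroded = ventricle_mask
    if not eroded.any():
        raise ValueError(
            f"eroding the ventricle mask by {erosion_mm} mm left no voxels; "
            "use a smaller erosion kernel"
        )
    offset = float(chi_map.chi[eroded].mean())
    meta = dict(chi_map.metadata)
    meta["ventricle_erosion_mm"] = erosion_mm
    meta["erosion_interpretation"] = "gaussian smooth-and-threshold (sigma=kernel/2)"
    return SusceptibilityMap(
        chi=chi_map.chi - offset,
        voxel_size=chi_map.voxel_size,
        reference_offset=chi_map.reference_offset + offset,
        inversion_threshold=chi_map.inversion_threshold,
        metadata=meta,
    )
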