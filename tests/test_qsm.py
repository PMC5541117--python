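"""QSM operators: dipole convolution, unwrapping, SHARP, TKD, normalization."""

import numpy as np
import pytest
from scipy import ndimage

from subqmri.phantom import MultiEchoSeries
from subqmri.qsm import (
    F0_MHZ_7T,
    FieldMap,
    SusceptibilityMap,
    dipole_kernel,
    erode_mask_gaussian,
    field_from_susceptibility,
    invert_dipole,
    normalize_to_ventricles,
    phase_to_field,
    remove_background,
)

SHAPE = (32, 32, 32)


def _sphere(shape, radius, value=1.0, center=None):
    c = [(n - 1) / 2 if center is None else center[i] for i, n in enumerate(shape)]
    x, y, z = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    m = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= radius**2
    return m, value * m.astype(float)


def _series_from_field(field_ppm, te_ms=(11.22,), wrap=True):
    phases = np.empty(field_ppm.shape + (len(te_ms),), dtype=float)
    for i, te in enumerate(te_ms):
        ph = 2 * np.pi * F0_MHZ_7T * field_ppm * te * 1e-3
        if wrap:
            ph = np.angle(np.exp(1j * ph))
            ph = np.where(ph <= -np.pi, ph + 2 * np.pi, ph)
        phases[..., i] = ph
    return MultiEchoSeries(
        echo_times_ms=tuple(te_ms),
        magnitude=np.ones_like(phases),
        phase=phases,
    )


def test_dipole_kernel_is_mean_free():
    """Adding a uniform susceptibility offset leaves the internal field unchanged."""
    _, chi = _sphere(SHAPE, 6, 0.1)
    f1 = field_from_susceptibility(chi)
    f2 = field_from_susceptibility(chi + 0.05)
    assert np.abs(f1 - f2).max() < 1e-12


def test_zero_phase_gives_zero_field():
    series = _series_from_field(np.zeros(SHAPE))
    fm = phase_to_field(series, 0, np.ones(SHAPE, bool))
    assert np.abs(fm.field).max() < 1e-12


def test_linear_phase_recovers_known_frequency_shift():
    """Unwrapped phase linear in TE from a known Δf maps to Δf/f0 in ppm."""
    field = np.full(SHAPE, 0.02)  # ppm, small enough to stay unwrapped
    series = _series_from_field(field, wrap=False)
    mask, _ = _sphere(SHAPE, 13)
    fm = phase_to_field(series, 0, mask)
    assert fm.field[mask] == pytest.approx(0.02, rel=1e-5)


@pytest.mark.parametrize("method", ["region", "laplacian"])
def test_wrapped_phase_matches_wrap_free_oracle(method):
    """Fields strong enough to wrap are recovered away from the mask edge.

    A smoothed cubic source (uniform spheres have no internal field)
    drives the phase past +/- pi while keeping the true inter-voxel phase
    step below pi — the sampling limit beyond which no unwrapper can
    succeed. The recovered field is compared with the wrap-free
    simulation; the global 2*pi branch is anchored by the masked median.
    """
    chi = np.zeros(SHAPE)
    chi[11:21, 11:21, 11:21] = 0.8
    chi = ndimage.gaussian_filter(chi, 2.0)
    field = field_from_susceptibility(chi)
    series = _series_from_field(field, te_ms=(29.57,), wrap=True)
    assert np.abs(
        2 * np.pi * F0_MHZ_7T * field * 29.57e-3
    ).max() > 1.5 * np.pi  # wraps are actually present
    mask, _ = _sphere(SHAPE, 14)
    fm = phase_to_field(series, 0, mask, unwrap_method=method)
    interior = ndimage.binary_erosion(mask, iterations=3)
    err = np.abs(fm.field - field)[interior]
    tol = 1e-3 if method == "region" else 2e-2
    assert err.max() < tol


def test_smv_annihilates_harmonic_field():
    """A linear gradient (harmonic) is removed to numerical precision."""
    x = np.arange(SHAPE[0])[:, None, None] - 15.5
    harmonic = 0.01 * np.broadcast_to(x, SHAPE).astype(float)
    mask, _ = _sphere(SHAPE, 13)
    fm = FieldMap(harmonic * mask, mask, mask)
    out = remove_background(fm, radius_mm=4.0)
    scale = np.ptp(harmonic[mask])
    assert np.abs(out.field[out.valid_mask]).max() < 1e-6 * scale


def test_smv_preserves_internal_dipole_field():
    """An internal source's field survives background removal within 5% RMS."""
    _, chi = _sphere(SHAPE, 4, 0.1)
    internal = field_from_susceptibility(chi)
    mask, _ = _sphere(SHAPE, 14)
    fm = FieldMap(internal * mask, mask, mask)
    # fine truncation: the default (0.05) trades fidelity for noise robustness
    out = remove_background(fm, radius_mm=3.0, threshold=0.02)
    v = out.valid_mask
    rms_err = np.sqrt(np.mean((out.field[v] - internal[v]) ** 2))
    rms_sig = np.sqrt(np.mean(internal[v] ** 2))
    assert rms_err < 0.05 * rms_sig


def test_smv_radius_below_voxel_errors():
    mask, _ = _sphere(SHAPE, 13)
    fm = FieldMap(np.zeros(SHAPE), mask, mask)
    with pytest.raises(ValueError, match="radius"):
        remove_background(fm, radius_mm=0.0)


def test_smv_mask_thinner_than_kernel_errors():
    mask = np.zeros(SHAPE, bool)
    mask[10:12] = True  # 2-voxel slab, thinner than the kernel everywhere
    fm = FieldMap(np.zeros(SHAPE), mask, mask)
    with pytest.raises(ValueError, match="thinner"):
        remove_background(fm, radius_mm=6.0)


def test_tkd_sphere_round_trip():
    """Forward field from a 0.1 ppm sphere inverts to ~0.1 ppm inside it."""
    sph, chi = _sphere(SHAPE, 6, 0.1)
    field = field_from_susceptibility(chi)
    fm = FieldMap(field, np.ones(SHAPE, bool), np.ones(SHAPE, bool))
    rec = invert_dipole(fm, threshold=0.1)
    assert rec.chi[sph].mean() == pytest.approx(0.1, rel=0.15)
    assert abs(rec.chi[~sph].mean()) < 0.01


def test_tkd_zero_field_and_linearity():
    fm0 = FieldMap(np.zeros(SHAPE), np.ones(SHAPE, bool), np.ones(SHAPE, bool))
    assert np.abs(invert_dipole(fm0, 0.2).chi).max() == 0.0

    _, chi = _sphere(SHAPE, 5, 0.07)
    field = field_from_susceptibility(chi)
    ones = np.ones(SHAPE, bool)
    c1 = invert_dipole(FieldMap(field, ones, ones), 0.1).chi
    c2 = invert_dipole(FieldMap(2.0 * field, ones, ones), 0.1).chi
    np.testing.assert_allclose(c2, 2.0 * c1, atol=1e-12)


@pytest.mark.parametrize("delta", [0.0, -0.1, 2.0 / 3.0, 1.0])
def test_tkd_threshold_range_errors(delta):
    fm = FieldMap(np.zeros(SHAPE), np.ones(SHAPE, bool), np.ones(SHAPE, bool))
    with pytest.raises(ValueError, match="threshold"):
        invert_dipole(fm, threshold=delta)


def test_normalization_constant_map_and_idempotence():
    mask, _ = _sphere(SHAPE, 8)
    chi = SusceptibilityMap(chi=np.full(SHAPE, 0.37))
    out = normalize_to_ventricles(chi, mask, erosion_mm=2.0)
    assert np.abs(out.chi).max() < 1e-12
    assert out.reference_offset == pytest.approx(0.37)
    again = normalize_to_ventricles(out, mask, erosion_mm=2.0)
    assert again.reference_offset == pytest.approx(0.37)  # second offset is 0
    assert np.abs(again.chi[mask]).max() < 1e-12


def test_eroded_reference_mean_is_zero():
    rng = np.random.default_rng(0)
    mask, _ = _sphere(SHAPE, 8)
    chi = SusceptibilityMap(chi=rng.normal(0, 0.05, SHAPE))
    out = normalize_to_ventricles(chi, mask, erosion_mm=2.0)
    eroded = erode_mask_gaussian(mask, 2.0, out.voxel_size)
    assert abs(out.chi[eroded].mean()) < 1e-9


def test_gaussian_erosion_matches_distance_transform_oracle():
    """10^3 cube, 1 mm voxels, 2 mm kernel vs euclidean-distance erosion."""
    cube = np.zeros((20, 20, 20), bool)
    cube[5:15, 5:15, 5:15] = True
    eroded = erode_mask_gaussian(cube, 2.0, (1.0, 1.0, 1.0))
    oracle = ndimage.distance_transform_edt(cube) > 2.0
    assert eroded.sum() == pytest.approx(oracle.sum(), rel=0.10)


def test_erosion_emptying_mask_errors():
    tiny = np.zeros(SHAPE, bool)
    tiny[16, 16, 16] = True
    chi = SusceptibilityMap(chi=np.zeros(SHAPE))
    with pytest.raises(ValueError, match="smaller erosion"):
        normalize_to_ventricles(chi, tiny, erosion_mm=2.0)


def test_valid_mask_must_be_subset_of_brain_mask():
    mask, _ = _sphere(SHAPE, 8)
    with pytest.raises(ValueError, match="subset"):
        FieldMap(np.zeros(SHAPE), mask, np.ones(SHAPE, bool))
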