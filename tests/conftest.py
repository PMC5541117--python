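import numpy as np
import pytest

from subqmri.phantom import MultiEchoSeries, PhantomSpec, StructureDef, default_spec


@pytest.fixture
def paper_tes():
    """The acquisition's echo times (ms)."""
    return (11.22, 20.39, 29.57)


def make_series(t2s_ms, s0, echo_times_ms, shape=(1, 1, 1)):
    """Noiseless magnitude-only series for a uniform T2*/S0 voxel block."""
    te = np.asarray(echo_times_ms, dtype=float)
    mag = np.empty(shape + (len(te),))
    for i, t in enumerate(te):
        mag[..., i] = s0 * np.exp(-t / t2s_ms)
    return MultiEchoSeries(echo_times_ms=tuple(te), magnitude=mag, phase=None)


def quiet_spec(**overrides) -> PhantomSpec:
    """Default phantom with all randomness silenced (identity conditions)."""
    base = dict(
        noise_sd=0.0,
        rater_flip_prob=(0.0, 0.0),
        com_jitter_mm=0.0,
        com_jitter_structure_mm=0.0,
        value_hemi_jitter_frac=0.0,
        ventricle_scale_sd=0.0,
    )
    base.update(overrides)
    spec = default_spec(seed=0, **base)
    for s in spec.structures:
        s.t1 = (s.t1[0], s.t1[1], 0.0)
        s.t2s = (s.t2s[0], s.t2s[1], 0.0)
        s.chi = (s.chi[0], s.chi[1], 0.0)
    return spec


def small_location_spec(drift_z_mm_per_year: float) -> PhantomSpec:
    """Compact phantom (striatum + lateral ventricles) for location analyses."""
    structures = [
        StructureDef(
            name="STR", hemisphere=hemi,
            center_mm=(sx * 26.0, 4.0, 2.0), semi_axes_mm=(5.5, 13.0, 8.0),
            drift_mm_per_year=(0.0, 0.0, drift_z_mm_per_year),
        )
        for hemi, sx in (("right", 1.0), ("left", -1.0))
    ] + [
        StructureDef(
            name="LV", hemisphere=hemi,
            center_mm=(sx * 11.0, 12.0, 8.0), semi_axes_mm=(3.5, 12.0, 5.5),
            t1=(4000.0, 0.0, 0.0), t2s=(150.0, 0.0, 0.0),
            is_csf=True, grows_with_age=True,
        )
        for hemi, sx in (("right", 1.0), ("left", -1.0))
    ]
    return PhantomSpec(
        shape=(48, 48, 32),
        structures=structures,
        brain_semi_axes_mm=(34.0, 34.0, 22.0),
    )
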