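"""Synthetic multi-echo gradient-echo phantom cohorts with known ground truth.

The generator emulates the study design of a cross-sectional 7 T aging
cohort: three age groups (young / middle-aged / elderly), ellipsoidal
stand-ins for the subcortical nuclei (striatum, globus pallidus externa and
interna, red nucleus, subthalamic nucleus, substantia nigra, periaqueductal
grey) and CSF compartments (lateral ventricles, cerebral aqueduct), each
carrying a linear age model for its quantitative parameters (T1 ms, T2* ms,
susceptibility ppm), an age-dependent center-of-mass drift, ventricle
growth, and two simulated raters whose masks differ from the ground truth
only at boundary voxels.

The forward signal model matches the analysis modules exactly: magnitude
decays mono-exponentially, S(TE) = S0 * exp(-TE / T2*); phase accrues
linearly in TE from the dipole-convolved susceptibility map plus a smooth
polynomial background field; complex Gaussian noise is added to the real
and imaginary channels.

Everything is deterministic given the cohort seed: per-subject generators
are spawned from one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache as _lru_cache

import numpy as np
from scipy import ndimage

from subqmri.qsm import F0_MHZ_7T, field_from_susceptibility

__all__ = [
    "StructureDef",
    "PhantomSpec",
    "MultiEchoSeries",
    "SubjectRecord",
    "default_spec",
    "build_phantom",
    "simulate_signal",
    "perturb_rater_masks",
    "generate_cohort",
    "assign_group",
    "GROUP_AGE_RANGES",
    "GROUP_SIZES",
    "NUCLEI",
]

#: Age ranges (years) of the three groups.
GROUP_AGE_RANGES = {"young": (19.0, 29.0), "middle": (40.0, 60.0), "elderly": (60.0, 75.0)}
#: Default group sizes (after exclusions).
GROUP_SIZES = {"young": 30, "middle": 14, "elderly": 9}

#: Gray-matter nuclei in the structure catalog (bilateral except the PAG).
NUCLEI = ("STR", "GPe", "GPi", "RN", "STN", "SN", "PAG")

# Group-mean anchors for the linear age models: (value at mean young age
# 23.8 y, value at mean elderly age 69.6 y), per structure. T1/T2* in ms,
# susceptibility in ppm. Between-subject SD is the young-group SD.
_T1_ANCHORS = {
    "STR": (1683.61, 1747.01, 56.79),
    "GPe": (1261.43, 1336.44, 33.62),
    "GPi": (1232.44, 1313.33, 33.03),
    "RN": (1230.54, 1317.36, 36.60),
    "STN": (1192.26, 1265.29, 38.92),
    "SN": (1314.97, 1346.82, 43.27),
    "PAG": (1750.91, 1952.60, 74.30),
}
_T2S_ANCHORS = {
    "STR": (27.97, 22.70, 1.92),
    "GPe": (12.77, 18.22, 1.04),
    "GPi": (12.74, 21.61, 0.88),
    "RN": (17.26, 14.15, 1.49),
    "STN": (15.05, 14.41, 1.51),
    "SN": (13.22, 19.96, 1.03),
    "PAG": (42.31, 43.92, 2.84),
}
_CHI_ANCHORS = {
    "STR": (0.007, 0.035, 0.028),
    "GPe": (0.115, 0.131, 0.039),
    "GPi": (0.106, 0.113, 0.041),
    "RN": (0.028, 0.083, 0.036),
    "STN": (0.027, 0.036, 0.043),
    "SN": (0.095, 0.133, 0.034),
    "PAG": (-0.045, -0.053, 0.030),
}
_ANCHOR_AGES = (23.8, 69.6)

# Ellipsoid geometry in template millimeters (x lateral, y anterior,
# z superior; right hemisphere has x > 0, left is mirrored).
_GEOMETRY = {
    # name: (center, semi-axes)
    "STR": ((26.0, 4.0, 2.0), (5.5, 13.0, 8.0)),
    "GPe": ((16.0, -2.0, 0.0), (2.8, 6.5, 4.5)),
    "GPi": ((10.5, -5.0, -3.0), (2.0, 3.8, 2.8)),
    "RN": ((5.0, -24.0, -9.0), (3.0, 3.6, 3.6)),
    "STN": ((10.0, -13.0, -7.0), (2.2, 3.6, 2.4)),
    "SN": ((11.0, -20.5, -13.5), (3.2, 5.0, 2.5)),
    "PAG": ((0.0, -30.0, -6.0), (3.2, 3.8, 7.5)),
}
_CSF_GEOMETRY = {
    # name: (center, semi-axes, grows_with_age)
    "LV": ((11.0, 12.0, 8.0), (5.0, 14.0, 6.5), True),
    "third_ventricle": ((0.0, 4.0, 4.0), (1.8, 9.0, 5.0), True),
    "aqueduct": ((0.0, -30.0, -6.0), (1.6, 1.6, 8.5), True),
    "fourth_ventricle": ((0.0, -36.0, -16.0), (3.0, 3.5, 4.5), False),
}

# Structures reported to shift location with age get a nonzero default
# drift (mm/year); the remaining nuclei stay put.
_DEFAULT_DRIFT = {
    "STR": (0.0, -0.01, 0.017),
    "GPe": (0.0, 0.01, 0.017),
    "STN": (0.01, 0.0, 0.017),
    "RN": (0.0, 0.01, 0.017),
    "PAG": (0.0, 0.0, 0.017),
    "GPi": (0.0, 0.0, 0.0),
    "SN": (0.0, 0.0, 0.0),
}

_CSF_T1_MS = 4000.0
_CSF_T2S_MS = 150.0
_CSF_CHI_PPM = 0.0


@dataclass
class StructureDef:
    """One ellipsoidal structure and its age models.

    ``t1``, ``t2s`` and ``chi`` are (intercept at age 20, slope per year,
    between-subject SD) triples. ``drift_mm_per_year`` moves the center by
    drift * (age - 20); for left-hemisphere copies the x component is
    mirrored.
    """

    name: str
    hemisphere: str  # left | right | midline
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    t1: tuple[float, float, float] = (1300.0, 0.0, 0.0)
    t2s: tuple[float, float, float] = (30.0, 0.0, 0.0)
    chi: tuple[float, float, float] = (0.0, 0.0, 0.0)
    drift_mm_per_year: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_csf: bool = False
    grows_with_age: bool = False

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError(f"{self.name}: semi-axes must be positive")


@dataclass
class PhantomSpec:
    """Full description of the phantom cohort's study conditions."""

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: float = 1.5
    structures: list[StructureDef] = dc_field(default_factory=list)
    background_t1_ms: float = 1300.0
    background_t2s_ms: float = 30.0
    background_chi_ppm: float = 0.0
    s0: float = 100.0
    echo_times_ms: tuple[float, ...] = (11.22, 20.39, 29.57)
    noise_sd: float = 0.02  # fraction of mean first-echo brain magnitude
    ventricle_growth_per_year: float = 0.006  # fractional volume per year
    ventricle_scale_sd: float = 0.15  # between-subject log-volume SD of CSF spaces
    background_field_coeffs: tuple[float, ...] = (
        0.0, 0.06, 0.05, -0.07, 0.04, -0.03, 0.05,
    )  # ppm: const, x, y, z, x^2, y^2, z^2 in normalized [-1, 1] coords
    rater_flip_prob: tuple[float, float] = (0.3, 0.3)
    com_jitter_mm: float = 0.35  # per-subject rigid shift (anatomy/registration)
    com_jitter_structure_mm: float = 0.08  # small independent per-structure jitter
    value_hemi_jitter_frac: float = 0.3  # hemisphere jitter, fraction of subject SD
    brain_semi_axes_mm: tuple[float, float, float] = (45.0, 45.0, 33.0)
    f0_mhz: float = F0_MHZ_7T
    group_sizes: dict = dc_field(default_factory=lambda: dict(GROUP_SIZES))
    seed: int = 0

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        v = self.voxel_size_mm
        return (v, v, v)

    @property
    def affine(self) -> np.ndarray:
        """Template affine: isotropic voxels, world origin at grid center."""
        v = self.voxel_size_mm
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * v
        return aff


@dataclass
class MultiEchoSeries:
    """Multi-echo gradient-echo data: magnitude and wrapped phase per echo."""

    echo_times_ms: tuple[float, ...]
    magnitude: np.ndarray  # (x, y, z, n_echoes), arbitrary units >= 0
    phase: np.ndarray | None  # (x, y, z, n_echoes), radians in (-pi, pi]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.ndim != 1 or len(te) == 0:
            raise ValueError("echo times must be a non-empty 1-D sequence")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.magnitude.shape[-1] != len(te):
            raise ValueError("number of magnitude volumes must equal number of echoes")
        if self.phase is not None and self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude must have identical shapes")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")


@dataclass
class SubjectRecord:
    """One phantom subject: ground truth, simulated data, and derived masks."""

    subject_id: str
    age: float
    group: str
    affine: np.ndarray  # subject-space affine (template affine + known rigid)
    to_template: np.ndarray  # exact inverse of the rigid perturbation
    t1_map: np.ndarray
    t2s_map: np.ndarray
    chi_map: np.ndarray
    brain_mask: np.ndarray
    truth_masks: dict  # (name, hemisphere) -> bool array
    rater_masks: dict  # (name, hemisphere) -> (rater1, rater2) bool arrays
    ventricle_volume_mm3: float
    seed: int
    series: MultiEchoSeries | None = None

    @property
    def t1_series_map(self) -> np.ndarray:
        """Alias: the T1 map is consumed as given (vendor-style input)."""
        return self.t1_map


def assign_group(age: float) -> str:
    """Map a continuous age to its group label (elderly wins the 60 y tie)."""
    if age < 40.0:
        return "young"
    if age < 60.0:
        return "middle"
    return "elderly"


def _linear_model(anchors: tuple[float, float, float]) -> tuple[float, float, float]:
    """Anchor pair at the young/elderly mean ages -> (intercept@20, slope, sd)."""
    y, e, sd = anchors
    slope = (e - y) / (_ANCHOR_AGES[1] - _ANCHOR_AGES[0])
    intercept = y - slope * (_ANCHOR_AGES[0] - 20.0)
    return (intercept, slope, sd)


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The default phantom: nuclei anchored to the reported group means.

    Linear age models are fixed by the young (23.8 y) and elderly (69.6 y)
    group means of each structure's T1, T2* and susceptibility; the
    between-subject SD is the young-group SD. Keyword overrides replace
    any :class:`PhantomSpec` field.
    """
    structures: list[StructureDef] = []
    for name in NUCLEI:
        center, semi = _GEOMETRY[name]
        hemis = ("midline",) if name == "PAG" else ("right", "left")
        for hemi in hemis:
            c = np.asarray(center, dtype=float)
            drift = np.asarray(_DEFAULT_DRIFT[name], dtype=float)
            if hemi == "left":
                c = c * np.array([-1.0, 1.0, 1.0])
                drift = drift * np.array([-1.0, 1.0, 1.0])
            structures.append(
                StructureDef(
                    name=name,
                    hemisphere=hemi,
                    center_mm=tuple(c),
                    semi_axes_mm=semi,
                    t1=_linear_model(_T1_ANCHORS[name]),
                    t2s=_linear_model(_T2S_ANCHORS[name]),
                    chi=_linear_model(_CHI_ANCHORS[name]),
                    drift_mm_per_year=tuple(drift),
                )
            )
    for name, (center, semi, grows) in _CSF_GEOMETRY.items():
        hemis = ("right", "left") if name == "LV" else ("midline",)
        for hemi in hemis:
            c = np.asarray(center, dtype=float)
            if hemi == "left":
                c = c * np.array([-1.0, 1.0, 1.0])
            structures.append(
                StructureDef(
                    name=name,
                    hemisphere=hemi,
                    center_mm=tuple(c),
                    semi_axes_mm=semi,
                    t1=(_CSF_T1_MS, 0.0, 0.0),
                    t2s=(_CSF_T2S_MS, 0.0, 0.0),
                    chi=(_CSF_CHI_PPM, 0.0, 0.0),
                    is_csf=True,
                    grows_with_age=grows,
                )
            )
    spec = PhantomSpec(structures=structures, seed=seed)
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"unknown PhantomSpec field {key!r}")
        setattr(spec, key, value)
    return spec


def _world_axes(spec: PhantomSpec) -> list[np.ndarray]:
    aff = spec.affine
    return [
        np.arange(n, dtype=float) * aff[i, i] + aff[i, 3]
        for i, n in enumerate(spec.shape)
    ]


def _paint_ellipsoid(axes, center, semi_axes, out: np.ndarray | None = None):
    """Paint an ellipsoid onto the grid, touching only its bounding box."""
    shape = tuple(len(a) for a in axes)
    if out is None:
        out = np.zeros(shape, dtype=bool)
    slices, rel = [], []
    for i in range(3):
        lo = np.searchsorted(axes[i], center[i] - semi_axes[i]) - 1
        hi = np.searchsorted(axes[i], center[i] + semi_axes[i]) + 1
        sl = slice(max(lo, 0), min(hi, shape[i]))
        slices.append(sl)
        rel.append((axes[i][sl] - center[i]) / semi_axes[i])
    if any(r.size == 0 for r in rel):
        return out
    d = (
        rel[0][:, None, None] ** 2
        + rel[1][None, :, None] ** 2
        + rel[2][None, None, :] ** 2
    )
    out[tuple(slices)] |= d <= 1.0
    return out


def _bbox_slices(mask: np.ndarray, pad: int = 2) -> tuple[slice, ...]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, n))
        for i, n in zip(idx, mask.shape)
    )


def build_phantom(spec: PhantomSpec, age: float, seed: int) -> SubjectRecord:
    """Generate one subject's ground truth at a given age.

    Parameter maps are painted per structure from the linear age models
    plus a subject-level random effect (shared across hemispheres) and a
    smaller independent hemisphere effect. Structure centers are displaced
    by drift * (age - 20), a rigid per-hemisphere positional shift
    (anatomical variability / residual registration error; midline
    structures take the two hemispheres' average), and a small independent
    per-structure jitter; CSF compartments grow
    with age. Gray-matter structures may not collide; CSF takes precedence
    where a nucleus abuts a ventricle (partial voluming), which is what
    the CSF-threshold extraction rule handles downstream.
    """
    if not 18.0 <= age <= 80.0:
        raise ValueError(f"age {age} outside the supported range [18, 80]")
    rng = np.random.default_rng(seed)
    axes = _world_axes(spec)

    t1 = np.full(spec.shape, spec.background_t1_ms, dtype=np.float32)
    t2s = np.full(spec.shape, spec.background_t2s_ms, dtype=np.float32)
    chi = np.full(spec.shape, spec.background_chi_ppm, dtype=np.float32)

    brain = _paint_ellipsoid(axes, (0.0, 0.0, 0.0), spec.brain_semi_axes_mm)

    dage = age - 20.0
    # CSF linear growth with age on top of a subject-level (lognormal) size
    subject_csf_scale = (
        float(np.exp(rng.normal(0.0, spec.ventricle_scale_sd)))
        if spec.ventricle_scale_sd > 0
        else 1.0
    )
    growth = (
        max(1.0 + spec.ventricle_growth_per_year * dage, 0.05) * subject_csf_scale
    ) ** (1.0 / 3.0)

    # subject-level random effects are drawn once per structure name so
    # both hemispheres share them; iterate names in catalog order
    subject_effects: dict[str, tuple[float, float, float]] = {}
    for s in spec.structures:
        if s.name not in subject_effects:
            subject_effects[s.name] = (
                rng.normal(0.0, s.t1[2]) if s.t1[2] > 0 else 0.0,
                rng.normal(0.0, s.t2s[2]) if s.t2s[2] > 0 else 0.0,
                rng.normal(0.0, s.chi[2]) if s.chi[2] > 0 else 0.0,
            )

    # positional variability: one rigid shift per hemisphere (midline
    # structures take the average), so left and right observations are
    # independent while same-hemisphere geometry stays rigid and
    # collision-free
    if spec.com_jitter_mm > 0:
        hemi_shift = {
            "right": rng.normal(0.0, spec.com_jitter_mm, size=3),
            "left": rng.normal(0.0, spec.com_jitter_mm, size=3),
        }
        hemi_shift["midline"] = 0.5 * (hemi_shift["right"] + hemi_shift["left"])
    else:
        hemi_shift = {h: np.zeros(3) for h in ("right", "left", "midline")}

    csf_mask = np.zeros(spec.shape, dtype=bool)
    masks: dict[tuple[str, str], np.ndarray] = {}
    painted = np.zeros(spec.shape, dtype=np.int16)
    claimed: dict[int, str] = {}

    # CSF first: it carves partial-volume voxels out of adjacent nuclei
    ordered = [s for s in spec.structures if s.is_csf] + [
        s for s in spec.structures if not s.is_csf
    ]
    ventricle_volume = 0.0
    voxel_volume = float(np.prod(spec.voxel_size))
    for idx, s in enumerate(ordered, start=1):
        center = np.asarray(s.center_mm, dtype=float)
        center = center + np.asarray(s.drift_mm_per_year, dtype=float) * dage
        center = center + hemi_shift[s.hemisphere]
        if spec.com_jitter_structure_mm > 0:
            center = center + rng.normal(0.0, spec.com_jitter_structure_mm, size=3)
        semi = np.asarray(s.semi_axes_mm, dtype=float)
        if s.grows_with_age:
            semi = semi * growth
        mask = _paint_ellipsoid(axes, center, semi)
        if s.is_csf:
            csf_mask |= mask
            ventricle_volume += float(mask.sum()) * voxel_volume
        else:
            mask = mask & ~csf_mask
            collision = painted[mask]
            hit = collision[collision > 0]
            if hit.size:
                other = claimed[int(hit[0])]
                raise ValueError(
                    f"structures overlap after drift at age {age:.1f}: "
                    f"{s.name}/{s.hemisphere} collides with {other}"
                )
        painted[mask] = idx
        claimed[idx] = f"{s.name}/{s.hemisphere}"
        masks[(s.name, s.hemisphere)] = mask

        eff = subject_effects[s.name]
        hemi_frac = spec.value_hemi_jitter_frac
        hj = (
            rng.normal(0.0, s.t1[2] * hemi_frac) if s.t1[2] > 0 and hemi_frac > 0 else 0.0,
            rng.normal(0.0, s.t2s[2] * hemi_frac) if s.t2s[2] > 0 and hemi_frac > 0 else 0.0,
            rng.normal(0.0, s.chi[2] * hemi_frac) if s.chi[2] > 0 and hemi_frac > 0 else 0.0,
        )
        t1[mask] = s.t1[0] + s.t1[1] * dage + eff[0] + hj[0]
        t2s_val = s.t2s[0] + s.t2s[1] * dage + eff[1] + hj[1]
        t2s[mask] = max(t2s_val, 1.0)  # keep decay physical
        chi[mask] = s.chi[0] + s.chi[1] * dage + eff[2] + hj[2]

    # two independent raters per gray-matter structure
    rater_masks: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, mask in masks.items():
        name, hemi = key
        sdef = next(
            s for s in spec.structures if s.name == name and s.hemisphere == hemi
        )
        if sdef.is_csf:
            p = (min(spec.rater_flip_prob[0], 0.15), min(spec.rater_flip_prob[1], 0.15))
        else:
            p = spec.rater_flip_prob
        rater_masks[key] = perturb_rater_masks(
            mask, p, int(rng.integers(0, 2**31 - 1))
        )

    # known small rigid perturbation of the header affine; its inverse is
    # stored so template-space coordinates are recovered exactly
    angle = rng.normal(0.0, 0.01)
    trans = rng.normal(0.0, 0.5, size=3)
    ca, sa = np.cos(angle), np.sin(angle)
    rigid = np.array(
        [[ca, -sa, 0, trans[0]], [sa, ca, 0, trans[1]], [0, 0, 1, trans[2]], [0, 0, 0, 1.0]]
    )
    affine = rigid @ spec.affine
    to_template = np.linalg.inv(rigid)

    return SubjectRecord(
        subject_id=f"sub-{seed:010d}",
        age=float(age),
        group=assign_group(age),
        affine=affine,
        to_template=to_template,
        t1_map=t1,
        t2s_map=t2s,
        chi_map=chi,
        brain_mask=brain,
        truth_masks=masks,
        rater_masks=rater_masks,
        ventricle_volume_mm3=ventricle_volume,
        seed=seed,
    )


def simulate_signal(
    record: SubjectRecord,
    spec: PhantomSpec,
    noise_seed: int | None = None,
) -> MultiEchoSeries:
    """Forward-simulate the multi-echo complex signal for one subject.

    Magnitude: S0 * exp(-TE / T2*) inside the brain, zero outside. Phase:
    2*pi * f0 * (dipole field from the susceptibility map + polynomial
    background field) * TE, wrapped to (-pi, pi]. Complex Gaussian noise
    (SD = noise_sd * mean first-echo brain magnitude) is added to the real
    and imaginary channels.
    """
    if np.any(record.t2s_map[record.brain_mask] <= 0):
        raise ValueError("ground-truth T2* must be positive inside the brain")
    shape = record.t2s_map.shape
    te = np.asarray(spec.echo_times_ms, dtype=float)

    field_ppm = field_from_susceptibility(
        record.chi_map.astype(float), spec.voxel_size
    ).astype(np.float32)
    total_field = field_ppm + _background_field(shape, spec.background_field_coeffs)

    brain = record.brain_mask
    s0 = np.where(brain, spec.s0, 0.0).astype(np.float32)
    inv_t2s = np.where(brain, 1.0 / record.t2s_map, 0.0).astype(np.float32)

    rng = np.random.default_rng(record.seed + 1 if noise_seed is None else noise_seed)
    mags = np.empty(shape + (len(te),), dtype=np.float32)
    phases = np.empty_like(mags)
    noise = 0.0
    for i, t in enumerate(te):
        mag = s0 * np.exp(np.float32(-t) * inv_t2s)
        if i == 0:
            mean_mag = float(mag[brain].mean()) if brain.any() else 0.0
            noise = spec.noise_sd * mean_mag
        ph = np.float32(2.0 * np.pi * spec.f0_mhz * t * 1e-3) * total_field
        sig = (mag * np.exp(1j * ph.astype(np.float32))).astype(np.complex64)
        if noise > 0:
            sig = sig + (
                rng.standard_normal(shape, dtype=np.float32)
                + 1j * rng.standard_normal(shape, dtype=np.float32)
            ) * np.float32(noise)
        mags[..., i] = np.abs(sig)
        # wrap to (-pi, pi]
        p = np.angle(sig)
        phases[..., i] = np.where(p <= -np.pi, p + 2 * np.pi, p)
    series = MultiEchoSeries(
        echo_times_ms=tuple(te),
        magnitude=mags,
        phase=phases,
        voxel_size=spec.voxel_size,
        affine=record.affine,
    )
    record.series = series
    return series


@_lru_cache(maxsize=4)
def _background_field(shape, coeffs) -> np.ndarray:
    """Smooth polynomial background field (ppm) in normalized coordinates."""
    u, v, w = [
        np.linspace(-1.0, 1.0, n, dtype=np.float32).reshape(
            [-1 if i == j else 1 for j in range(3)]
        )
        for i, n in enumerate(shape)
    ]
    c = coeffs
    bg = (
        c[0] + c[1] * u + c[2] * v + c[3] * w + c[4] * u**2 + c[5] * v**2 + c[6] * w**2
    ).astype(np.float32)
    bg.setflags(write=False)
    return bg


def _boundary_shells(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inner boundary (in mask, touching outside) and outer boundary."""
    struct = ndimage.generate_binary_structure(3, 1)
    inner = mask & ~ndimage.binary_erosion(mask, structure=struct)
    outer = ndimage.binary_dilation(mask, structure=struct) & ~mask
    return inner, outer


def perturb_rater_masks(
    truth: np.ndarray,
    flip_prob: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate two raters by flipping boundary voxels of the truth mask.

    For each rater, every inner-boundary voxel is dropped and every
    outer-boundary voxel added independently with the rater's flip
    probability. The expected Dice between the raters is a closed-form
    function of the flip probabilities and the shell sizes, so agreement
    is controllable.
    """
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise ValueError("truth mask is empty")
    box = _bbox_slices(truth)
    crop = truth[box]
    inner, outer = _boundary_shells(crop)
    rng = np.random.default_rng(seed)
    out = []
    for p in flip_prob:
        m = crop.copy()
        if p > 0:
            drop = inner & (rng.random(crop.shape) < p)
            add = outer & (rng.random(crop.shape) < p)
            m = (m & ~drop) | add
        if not m.any():
            raise ValueError(
                f"rater flip probability {p} emptied the mask; reduce it"
            )
        full = np.zeros(truth.shape, dtype=bool)
        full[box] = m
        out.append(full)
    return out[0], out[1]


def generate_cohort(
    spec: PhantomSpec,
    seed: int | None = None,
    simulate: bool = True,
) -> list[SubjectRecord]:
    """Generate the full three-group cohort.

    Ages are drawn uniformly within each group's range; per-subject seeds
    are spawned from the cohort seed, so cohorts are reproducible and
    subjects are independent.
    """
    cohort_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(cohort_seed)
    total = sum(spec.group_sizes.values())
    children = ss.spawn(total + 1)
    age_rng = np.random.default_rng(children[0])
    records: list[SubjectRecord] = []
    i = 1
    for group, n in spec.group_sizes.items():
        lo, hi = GROUP_AGE_RANGES[group]
        ages = age_rng.uniform(lo, hi, size=n)
        for age in ages:
            sub_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            rec = build_phantom(spec, float(age), sub_seed)
            rec.subject_id = f"sub-{i:03d}"
            if simulate:
                simulate_signal(rec, spec)
            records.append(rec)
            i += 1
    return records
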