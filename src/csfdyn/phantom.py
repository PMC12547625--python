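"""Synthetic DWI, rs-fMRI, and cohort fixtures with machine-readable truth.

Every generator is seeded and emits a truth record sufficient to compute the
expected marker analytically, so each pipeline stage can be verified without
real scans.

* DWI phantoms follow the single-tensor forward model
  S = S0 * exp(-b g'Dg) per voxel, with spherical regions overriding a
  background tensor and optional Gaussian or Rician magnitude noise.
* fMRI phantoms plant a band-limited global signal g(t) in a gray-matter
  region and a CSF inflow signal in the bottom slices built on the regressor
  scale, max(0, -g'(t - lag)), so the planted optimum coincides with the
  coupling pipeline's definition of the marker.
* Cohort tables plant a known number of violators for every QC rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alps import RoiSpec
from .errors import ValidationError
from .io_core import GradientTable, MaskVolume, Series4D

__all__ = [
    "DwiPhantomSpec",
    "FmriPhantomSpec",
    "gen_dwi_phantom",
    "gen_fmri_phantom",
    "gen_cohort_table",
    "alps_roi_layout",
    "default_dwi_spec",
    "default_fmri_spec",
]

# diffusivity unit: mm^2/s; typical parenchyma ~0.7e-3
ISOTROPIC_TENSOR = (0.7e-3, 0.7e-3, 0.7e-3, 0.0, 0.0, 0.0)

# canonical 6-direction scheme spanning a full-rank tensor design
_CANONICAL_DIRS = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
        [1, 0, 1],
        [0, 1, 1],
    ],
    dtype=float,
)
_CANONICAL_DIRS /= np.linalg.norm(_CANONICAL_DIRS, axis=1, keepdims=True)


def _extra_directions(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the sphere for schemes > 6 dirs."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _tensor_matrix(components) -> np.ndarray:
    xx, yy, zz, xy, xz, yz = components
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]], dtype=float)


def _check_psd(components, what: str) -> None:
    lams = np.linalg.eigvalsh(_tensor_matrix(components))
    if lams.min() < -1e-15:
        raise ValidationError(f"{what} tensor is not positive semidefinite: eigenvalues {lams}")


@dataclass(frozen=True)
class SphereRegion:
    """A spherical tensor override: world-space centre (mm), radius (mm), tensor."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    tensor: tuple[float, float, float, float, float, float]


@dataclass
class DwiPhantomSpec:
    """Specification of a synthetic diffusion acquisition."""

    shape: tuple[int, int, int] = (40, 20, 16)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_tensor: tuple = ISOTROPIC_TENSOR
    regions: tuple = ()
    s0: float = 1000.0
    bvals_shells: tuple[float, ...] = (0.0, 1000.0)
    n_b0: int = 1
    n_directions: int = 6
    noise: str = "none"  # none | gaussian | rician
    sigma: float = 0.0
    seed: int = 0

    def affine(self) -> np.ndarray:
        """Grid centred on the world origin, axis-aligned."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_dims)
        aff[:3, 3] = -(np.array(self.shape) - 1) / 2.0 * np.array(self.voxel_dims)
        return aff

    def validate(self) -> None:
        if self.n_b0 < 1:
            raise ValidationError("need at least one b=0 volume")
        if self.n_directions < 6:
            raise ValidationError("need at least 6 directions per nonzero shell")
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        _check_psd(self.background_tensor, "background")
        for region in self.regions:
            _check_psd(region.tensor, "region")


def gen_dwi_phantom(spec: DwiPhantomSpec):
    """Generate (Series4D, GradientTable, brain MaskVolume, truth record).

    Signals follow S = S0 exp(-b g'Dg) voxelwise; the truth record stores the
    full per-voxel tensor field plus each region's components so expected ROI
    means and the expected ALPS ratio can be computed analytically.
    """
    spec.validate()
    affine = spec.affine()
    shape = spec.shape

    # tensor field: background everywhere, spherical overrides
    field6 = np.broadcast_to(
        np.asarray(spec.background_tensor, dtype=float), shape + (6,)
    ).copy()
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    for region in spec.regions:
        inside = np.linalg.norm(world - np.asarray(region.center_mm), axis=1) <= region.radius_mm
        field6.reshape(-1, 6)[inside] = np.asarray(region.tensor, dtype=float)

    # gradient scheme
    nz_shells = [b for b in spec.bvals_shells if b > 0]
    dirs = (
        _CANONICAL_DIRS
        if spec.n_directions == 6
        else np.vstack([_CANONICAL_DIRS, _extra_directions(spec.n_directions - 6)])
    )
    bvals = [0.0] * spec.n_b0
    bvecs = [np.zeros(3)] * spec.n_b0
    for b in nz_shells:
        for g in dirs:
            bvals.append(float(b))
            bvecs.append(g)
    bvals = np.asarray(bvals)
    bvecs = np.asarray(bvecs)

    # forward model: exponent = b * g'Dg, vectorized over voxels x volumes
    D = field6.reshape(-1, 6)
    g = bvecs
    quad = (
        D[:, 0][:, None] * g[:, 0] ** 2
        + D[:, 1][:, None] * g[:, 1] ** 2
        + D[:, 2][:, None] * g[:, 2] ** 2
        + 2 * D[:, 3][:, None] * g[:, 0] * g[:, 1]
        + 2 * D[:, 4][:, None] * g[:, 0] * g[:, 2]
        + 2 * D[:, 5][:, None] * g[:, 1] * g[:, 2]
    )
    signal = spec.s0 * np.exp(-bvals[None, :] * quad)

    rng = np.random.default_rng(spec.seed)
    if spec.noise == "gaussian" and spec.sigma > 0:
        signal = signal + rng.normal(0.0, spec.sigma, signal.shape)
    elif spec.noise == "rician" and spec.sigma > 0:
        re = signal + rng.normal(0.0, spec.sigma, signal.shape)
        im = rng.normal(0.0, spec.sigma, signal.shape)
        signal = np.hypot(re, im)

    series = Series4D(data=signal.reshape(shape + (len(bvals),)), affine=affine)
    grad = GradientTable(bvals=bvals, bvecs=bvecs)
    brain = MaskVolume(data=np.ones(shape, dtype=np.uint8), affine=affine)
    truth = {
        "tensor_field": field6,
        "background_tensor": tuple(spec.background_tensor),
        "regions": [
            {
                "center_mm": tuple(r.center_mm),
                "radius_mm": float(r.radius_mm),
                "tensor": tuple(r.tensor),
            }
            for r in spec.regions
        ],
        "s0": spec.s0,
        "seed": spec.seed,
    }
    return series, grad, brain, truth


def alps_roi_layout(
    proj_x_mm: float = 8.0,
    assoc_x_mm: float = 14.0,
    radius_mm: float = 2.5,
) -> list[RoiSpec]:
    """Four ROI specs (projection/association x left/right) in phantom space.

    Centres sit on the world x-axis, mirroring the bilateral placement of
    the real ROIs at the lateral-ventricle level; phantom tests never depend
    on literature template coordinates.
    """
    return [
        RoiSpec("projection", "left", (-proj_x_mm, 0.0, 0.0), radius_mm),
        RoiSpec("projection", "right", (proj_x_mm, 0.0, 0.0), radius_mm),
        RoiSpec("association", "left", (-assoc_x_mm, 0.0, 0.0), radius_mm),
        RoiSpec("association", "right", (assoc_x_mm, 0.0, 0.0), radius_mm),
    ]


def default_dwi_spec(
    proj_tensor=ISOTROPIC_TENSOR,
    assoc_tensor=None,
    region_radius_mm: float = 5.5,
    **kwargs,
) -> tuple[DwiPhantomSpec, list[RoiSpec], float]:
    """A standard 4-ROI ALPS phantom: spec, ROI layout, and expected index.

    Tensor overrides are planted in spheres large enough to cover the whole
    displacement-search neighbourhood of each ROI, so the expected per-ROI
    component means equal the region tensor components exactly and the
    expected index is mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).
    """
    if assoc_tensor is None:
        assoc_tensor = proj_tensor
    rois = alps_roi_layout()
    regions = tuple(
        SphereRegion(
            center_mm=r.center_mm,
            radius_mm=region_radius_mm,
            tensor=tuple(proj_tensor if r.label == "projection" else assoc_tensor),
        )
        for r in rois
    )
    spec = DwiPhantomSpec(regions=regions, **kwargs)
    expected = (0.5 * (proj_tensor[0] + assoc_tensor[0])) / (
        0.5 * (proj_tensor[1] + assoc_tensor[2])
    )
    return spec, rois, expected


# ---------------------------------------------------------------------------
# rs-fMRI phantom
# ---------------------------------------------------------------------------

@dataclass
class FmriPhantomSpec:
    """Specification of a synthetic resting-state acquisition.

    The global signal g(t) is a unit-variance sum of ``n_components``
    random-phase sinusoids with frequencies inside ``band_hz``; the CSF
    inflow signal is planted on the regressor scale at ``lag_s`` (a multiple
    of TR).  ``noise_sigma`` is additive white noise per voxel, so with a
    unit-variance g the temporal SNR is 1/noise_sigma.
    """

    shape: tuple[int, int, int] = (10, 10, 10)
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 1.0
    n_volumes: int = 490
    band_hz: tuple[float, float] = (0.01, 0.05)
    n_components: int = 4
    lag_s: float = 6.0
    coupling_strength: float = 1.0
    noise_sigma: float = 0.0
    n_csf_voxels: int = 12
    seed: int = 0

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_dims)
        aff[:3, 3] = -(np.array(self.shape) - 1) / 2.0 * np.array(self.voxel_dims)
        return aff

    def validate(self) -> None:
        if abs(self.lag_s) > 20.0:
            raise ValidationError("planted |lag| must be <= 20 s")
        ratio = self.lag_s / self.tr_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                f"planted lag {self.lag_s}s is not a multiple of TR {self.tr_s}s"
            )
        nyq = 0.5 / self.tr_s
        lo, hi = self.band_hz
        if not (0 < lo < hi < nyq):
            raise ValidationError(f"band {self.band_hz} must lie inside (0, {nyq}) Hz")
        if not (0 <= self.coupling_strength <= 1):
            raise ValidationError("coupling_strength must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.n_volumes <= 2 * 5 + 30:
            raise ValidationError("too few volumes for edge discard + minimum overlap")


def _band_limited_signal(
    rng: np.random.Generator, band: tuple[float, float], n_components: int
):
    """Random band-limited signal as a closed-form function of time (s).

    Component frequencies sit on an evenly spaced lattice spanning the band
    with a common random offset, so every pairwise difference is at least
    one lattice step.  This keeps the intermodulation products created by
    half-wave rectification of the derivative (difference tones at |f_i -
    f_j|, sum tones at f_i + f_j) inside the downstream analysis band, which
    is what makes the planted inflow signal survive the coupling pipeline's
    band-pass coherently.  Phases are fully random.
    """
    lo, hi = band
    step = (hi - lo) / n_components
    freqs = lo + step * (np.arange(n_components) + rng.uniform(0.0, 1.0))
    phases = rng.uniform(0, 2 * np.pi, n_components)
    amps = np.ones(n_components) / math.sqrt(n_components / 2.0)  # unit variance

    def g(t):
        t = np.asarray(t, dtype=float)
        return np.sum(
            amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
            axis=0,
        )

    return g, freqs, phases


def gen_fmri_phantom(spec: FmriPhantomSpec):
    """Generate (Series4D, gm MaskVolume, csf MaskVolume, truth record).

    GM voxels (upper half of the grid) carry g(t) scaled by a smooth spatial
    weight plus noise on a baseline with a mild linear drift.  CSF voxels
    (in the bottom three slices) carry

        coupling_strength * max(0, -(g(t - lag) - g(t - lag - TR)))
        + (1 - coupling_strength) * independent band-limited noise

    plus the same white noise, so the planted optimum matches the pipeline's
    regressor definition exactly and the best correlation sits at +lag.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g, freqs, phases = _band_limited_signal(rng, spec.band_hz, spec.n_components)

    shape = spec.shape
    affine = spec.affine()
    nt = spec.n_volumes
    t = np.arange(nt) * spec.tr_s

    # masks: GM = upper half of the slab, CSF = voxels in the bottom 3 slices
    gm = np.zeros(shape, dtype=np.uint8)
    gm[1:-1, 1:-1, shape[2] // 2 :] = 1
    csf = np.zeros(shape, dtype=np.uint8)
    cx, cy = shape[0] // 2, shape[1] // 2
    offsets = [(0, 0), (1, 0), (0, 1), (1, 1), (-1, 0), (0, -1), (-1, 1), (1, -1), (-1, -1)]
    positions = [
        (cx + dx, cy + dy, z) for z in range(min(3, shape[2])) for dx, dy in offsets
    ]
    if spec.n_csf_voxels > len(positions):
        raise ValidationError(
            f"n_csf_voxels={spec.n_csf_voxels} exceeds the {len(positions)} "
            "available bottom-slice positions"
        )
    for i, j, k in positions[: spec.n_csf_voxels]:
        csf[i, j, k] = 1

    data = np.zeros(shape + (nt,), dtype=np.float64)
    # baseline + mild scanner drift, removed by detrending downstream
    baseline = 1000.0
    drift = 0.05 * t

    g_t = g(t)
    gm_idx = np.argwhere(gm > 0)
    # smooth spatial weight in (0.5, 1] so the GM mean stays proportional to g
    w = 0.5 + 0.5 * np.exp(
        -np.sum((gm_idx - gm_idx.mean(axis=0)) ** 2, axis=1)
        / (2.0 * max(shape) ** 2)
    )
    gm_signal = baseline + drift[None, :] + w[:, None] * g_t[None, :]
    if spec.noise_sigma > 0:
        gm_signal = gm_signal + rng.normal(0.0, spec.noise_sigma, gm_signal.shape)
    data[gm_idx[:, 0], gm_idx[:, 1], gm_idx[:, 2], :] = gm_signal

    # planted inflow on the regressor scale
    d_shift = g(t - spec.lag_s) - g(t - spec.lag_s - spec.tr_s)
    inflow = np.maximum(0.0, -d_shift)
    indep = _band_limited_signal(rng, spec.band_hz, spec.n_components)[0](t)
    csf_base = spec.coupling_strength * inflow + (1 - spec.coupling_strength) * indep
    csf_idx = np.argwhere(csf > 0)
    csf_signal = baseline + drift[None, :] + np.tile(csf_base, (len(csf_idx), 1))
    if spec.noise_sigma > 0:
        csf_signal = csf_signal + rng.normal(0.0, spec.noise_sigma, csf_signal.shape)
    data[csf_idx[:, 0], csf_idx[:, 1], csf_idx[:, 2], :] = csf_signal

    series = Series4D(data=data, affine=affine, t_spacing=spec.tr_s)
    truth = {
        "g": g_t,
        "inflow": inflow,
        "lag_s": spec.lag_s,
        "coupling_strength": spec.coupling_strength,
        "frequencies_hz": freqs,
        "phases": phases,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return (
        series,
        MaskVolume(data=gm, affine=affine),
        MaskVolume(data=csf, affine=affine),
        truth,
    )


def default_fmri_spec(**kwargs) -> FmriPhantomSpec:
    return FmriPhantomSpec(**kwargs)


# ---------------------------------------------------------------------------
# Cohort table phantom
# ---------------------------------------------------------------------------

def _top_percent_count(m: int, percent: float = 1.0) -> int:
    """How many of m distinct values sit at/above the (100-percent)th
    percentile under the 'higher' interpolation convention."""
    q = (100.0 - percent) / 100.0
    return m - math.ceil(q * (m - 1))


def gen_cohort_table(
    n: int,
    seed: int = 0,
    n_low_csf: int = 3,
    n_negative_coupling: int = 5,
):
    """Seeded participant table with planted violators for every QC rule.

    Motion metrics are continuous (almost surely distinct); the planted
    top-percentile outliers are far above the bulk so each top-1% rule
    removes exactly its planted rows when the rules run in the published
    sequence.  The truth record lists the planted ids per rule.
    """
    import pandas as pd

    if n < 10:
        raise ValidationError("cohort table needs n >= 10")
    rng = np.random.default_rng(seed)
    ids = np.array([f"sub-{i:05d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "participant_id": ids,
            "t1_motion": rng.uniform(0.1, 1.0, n),
            "dwi_motion": rng.uniform(0.1, 1.0, n),
            "fmri_motion": rng.uniform(0.1, 1.0, n),
            "csf_voxel_count": rng.integers(5, 60, n),
            "coupling": rng.uniform(0.0, 0.8, n),
        }
    )
    truth: dict[str, list[str]] = {}
    eligible = np.ones(n, dtype=bool)

    def plant_top(col: str, rule: str) -> None:
        m = int(eligible.sum())
        k = _top_percent_count(m)
        pick = rng.choice(np.flatnonzero(eligible), size=k, replace=False)
        df.loc[pick, col] = 10.0 + rng.uniform(0, 1, k)
        truth[rule] = list(ids[np.sort(pick)])
        eligible[pick] = False

    plant_top("t1_motion", "t1_motion_top1pct")
    plant_top("dwi_motion", "dwi_motion_top1pct")

    pool = np.flatnonzero(eligible)
    pick_csf = rng.choice(pool, size=n_low_csf, replace=False)
    df.loc[pick_csf, "csf_voxel_count"] = rng.integers(0, 5, n_low_csf)
    truth["csf_voxels_min5"] = list(ids[np.sort(pick_csf)])
    eligible[pick_csf] = False

    pool = np.flatnonzero(eligible)
    pick_neg = rng.choice(pool, size=n_negative_coupling, replace=False)
    df.loc[pick_neg, "coupling"] = rng.uniform(-0.5, -0.01, n_negative_coupling)
    truth["negative_coupling"] = list(ids[np.sort(pick_neg)])
    eligible[pick_neg] = False

    plant_top("fmri_motion", "fmri_motion_top1pct")
    truth["survivors"] = list(ids[eligible])
    return df, truth
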