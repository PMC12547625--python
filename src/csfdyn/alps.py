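"""Automated DTI-ALPS: tensor fit, FA, WM classification, ROI search, index.

The ALPS (analysis along the perivascular space) index contrasts diffusivity
along the medullary-vein perivascular direction (the image x-axis at the
level of the lateral-ventricle body) against diffusivity across the dominant
fibre directions of the neighbouring tracts:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

with Dxx/Dyy/Dzz the diagonal diffusion-tensor components averaged over a
spherical ROI on the projection fibres (y-dominant) and one on the
association fibres (z-dominant), per hemisphere.  An index of 1 means
isotropy; higher values are read as better perivascular diffusivity.

ROI placement is automated: each 2.5 mm spherical ROI may shift in-plane by
up to ``search_bound`` voxels and lands where the summed white-matter
probability is highest, and voxels whose WM probability falls below a 90%
threshold are excluded, keeping white-matter lesions and lacunes out of the
index.  WM probability comes from a two-component Gaussian-mixture model
fitted to the FA map by EM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    ComputationError,
    ConfigError,
    InsufficientDataError,
    PlacementError,
    ValidationError,
)
from .io_core import GradientTable, MaskVolume, Series4D

__all__ = [
    "TensorVolume",
    "FaVolume",
    "WmProbVolume",
    "RoiSpec",
    "PlacedRoi",
    "AlpsResult",
    "fit_tensor",
    "compute_fa",
    "classify_wm",
    "place_roi",
    "compute_alps",
    "load_roi_config",
]

# tensor component storage order (upper triangle)
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

DEFAULT_ROI_RADIUS_MM = 2.5
DEFAULT_SEARCH_BOUND = 2
DEFAULT_WM_THRESHOLD = 0.90

#: relative signal floor applied before taking logs in the tensor fit
SIGNAL_FLOOR_REL = 1e-6

_EM_MAX_ITER = 200
_EM_TOL = 1e-6
_MIN_WM_VOXELS = 100


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors (mm^2/s) and log-signal intercept.

    ``components`` has shape (X, Y, Z, 6) ordered Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz.  Voxels outside ``fit_mask`` carry a null tensor.
    """

    components: np.ndarray
    log_s0: np.ndarray
    fit_mask: np.ndarray
    affine: np.ndarray

    def component(self, name: str) -> np.ndarray:
        return self.components[..., TENSOR_COMPONENTS.index(name)]

    def as_matrices(self) -> np.ndarray:
        """Full 3x3 symmetric matrices, shape (X, Y, Z, 3, 3)."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.components, -1, 0)
        m = np.empty(self.components.shape[:-1] + (3, 3), dtype=self.components.dtype)
        m[..., 0, 0] = xx
        m[..., 1, 1] = yy
        m[..., 2, 2] = zz
        m[..., 0, 1] = m[..., 1, 0] = xy
        m[..., 0, 2] = m[..., 2, 0] = xz
        m[..., 1, 2] = m[..., 2, 1] = yz
        return m


@dataclass
class FaVolume:
    """Per-voxel fractional anisotropy in [0, 1]."""

    data: np.ndarray
    affine: np.ndarray


@dataclass
class WmProbVolume:
    """Per-voxel posterior probability of white matter in [0, 1]."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any((self.data < -1e-9) | (self.data > 1 + 1e-9)):
            raise ValidationError("WM probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class RoiSpec:
    """A spherical ROI: fibre label, hemisphere, template-space centre (mm)."""

    label: str  # "projection" | "association"
    hemisphere: str  # "left" | "right"
    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_ROI_RADIUS_MM

    def __post_init__(self) -> None:
        if self.label not in ("projection", "association"):
            raise ValidationError(f"unknown ROI label {self.label!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.radius_mm <= 0:
            raise ValidationError("ROI radius must be positive")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


@dataclass
class PlacedRoi:
    """Result of the in-plane displacement search for one ROI."""

    spec: RoiSpec
    displacement: tuple[int, int]
    member_voxels: np.ndarray  # (n, 3) integer voxel indices
    wm_prob_sum: float


@dataclass
class AlpsResult:
    """Per-hemisphere directional diffusivity means and ALPS indices."""

    per_hemisphere: dict  # hemisphere -> {dxx_proj, dxx_assoc, dyy_proj, dzz_assoc, alps}
    alps_mean: float
    retained_counts: dict  # (label, hemisphere) -> int
    displacements: dict  # (label, hemisphere) -> (dx, dy)

    def to_dict(self) -> dict:
        return {
            "per_hemisphere": {
                h: {k: float(v) for k, v in d.items()}
                for h, d in self.per_hemisphere.items()
            },
            "alps_mean": float(self.alps_mean),
            "retained_counts": {
                f"{lab}_{hemi}": int(n) for (lab, hemi), n in self.retained_counts.items()
            },
            "displacements": {
                f"{lab}_{hemi}": list(map(int, d))
                for (lab, hemi), d in self.displacements.items()
            },
        }


# ---------------------------------------------------------------------------
# Tensor fit (log-linear ordinary least squares)
# ---------------------------------------------------------------------------

def _design_matrix(grad: GradientTable) -> np.ndarray:
    """Design for ln S = ln S0 - b g'Dg, 7 columns: [1, -b gx^2, ...]."""
    b = grad.bvals
    g = grad.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: Series4D, grad: GradientTable, brain_mask: MaskVolume) -> TensorVolume:
    """Fit the diffusion tensor voxelwise by log-linear least squares.

    Solves ln S = ln S0 - b g'Dg per voxel inside ``brain_mask``.  Requires
    at least one b~0 volume and six non-collinear b>0 directions (the design
    must have full column rank).  Signals <= 0 are clamped to a small
    positive floor (1e-6 of the in-mask b0 scale) before the log, which
    avoids -inf without biasing typical voxels.
    """
    if len(grad) != dwi.n_volumes:
        raise ValidationError(
            f"gradient table ({len(grad)}) does not match volume count ({dwi.n_volumes})"
        )
    if brain_mask.shape != dwi.grid_shape:
        raise ValidationError("brain mask shape does not match DWI grid")
    b0 = grad.bvals <= DEFAULT_B0_THRESHOLD
    if not np.any(b0):
        raise ComputationError("tensor fit needs at least one b~0 volume")
    if np.count_nonzero(~b0) < 6:
        raise ComputationError("tensor fit needs at least 6 diffusion-weighted volumes")

    design = _design_matrix(grad)
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        raise ComputationError(
            f"rank-deficient gradient design (rank {rank} < 7): directions are "
            "collinear or span too few orientations"
        )

    mask = brain_mask.data
    signals = dwi.data[mask]  # (n_vox, n_volumes)
    s0_scale = float(np.median(signals[:, b0][signals[:, b0] > 0])) if np.any(
        signals[:, b0] > 0
    ) else 1.0
    floor = SIGNAL_FLOOR_REL * s0_scale
    log_s = np.log(np.maximum(signals, floor))

    # one pinv for all voxels: deterministic least-squares solution
    coef = log_s @ np.linalg.pinv(design).T  # (n_vox, 7)

    shape = dwi.grid_shape
    components = np.zeros(shape + (6,), dtype=np.float64)
    log_s0 = np.zeros(shape, dtype=np.float64)
    components[mask] = coef[:, 1:]
    log_s0[mask] = coef[:, 0]
    return TensorVolume(
        components=components, log_s0=log_s0, fit_mask=mask.copy(), affine=dwi.affine
    )


DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2, same window as shell matching


# ---------------------------------------------------------------------------
# Fractional anisotropy
# ---------------------------------------------------------------------------

def compute_fa(tensor: TensorVolume) -> FaVolume:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, eigenvalues clipped at 0.

    Null tensors (all-zero, e.g. outside the fit mask) map to FA = 0.
    """
    lams = np.linalg.eigvalsh(tensor.as_matrices())
    lams = np.clip(lams, 0.0, None)
    norm = np.linalg.norm(lams, axis=-1)
    dev = lams - lams.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    fa = np.where(norm > 0, fa, 0.0)
    return FaVolume(data=np.clip(fa, 0.0, 1.0), affine=tensor.affine)


# ---------------------------------------------------------------------------
# White-matter classification: 2-component Gaussian mixture on FA
# ---------------------------------------------------------------------------

def _gmm2_em(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Two-component 1-D Gaussian-mixture EM; returns P(high-mean component).

    Deterministic initialization: component means at the 25th/75th FA
    percentiles, shared variance from the sample, equal weights.  Runs at
    most 200 iterations to a 1e-6 log-likelihood tolerance.  If the sample
    is (numerically) constant the components are tied and every posterior
    is 0.5.
    """
    x = values.astype(float)
    n = x.size
    var0 = float(np.var(x))
    if var0 < 1e-12:
        return np.full(n, 0.5), True
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu = np.array([mu[0] - 1e-3, mu[1] + 1e-3])
    var = np.full(2, var0)
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    min_var = 1e-10
    for _ in range(_EM_MAX_ITER):
        # E-step: responsibilities via log densities for stability
        logp = (
            -0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
            - 0.5 * np.log(2 * np.pi * var[None, :])
            + np.log(w[None, :])
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
        if abs(ll - prev_ll) < _EM_TOL:
            converged = True
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, min_var)
        w = nk / n
    hi = int(np.argmax(mu))
    post_hi = resp[:, hi]
    if mu[0] == mu[1]:
        post_hi = np.full(n, 0.5)
    return post_hi, converged


def classify_wm(fa: FaVolume, brain_mask: MaskVolume) -> WmProbVolume:
    """Posterior probability of white matter from a 2-class mixture on FA.

    White matter is the mixture component with the higher mean FA.  Voxels
    outside the brain mask get probability 0.  Fewer than 100 in-mask voxels
    is an error; EM non-convergence after the iteration cap warns and
    returns the last iterate.
    """
    if brain_mask.shape != fa.data.shape:
        raise ValidationError("brain mask shape does not match FA volume")
    mask = brain_mask.data
    n_in = int(mask.sum())
    if n_in < _MIN_WM_VOXELS:
        raise InsufficientDataError(
            f"only {n_in} in-mask voxels; need >= {_MIN_WM_VOXELS} for WM classification"
        )
    post, converged = _gmm2_em(fa.data[mask])
    if not converged:
        import warnings

        warnings.warn(
            "WM mixture EM did not converge within the iteration cap; "
            "returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros_like(fa.data, dtype=float)
    out[mask] = post
    return WmProbVolume(data=out, affine=fa.affine)


# ---------------------------------------------------------------------------
# ROI placement: in-plane displacement search
# ---------------------------------------------------------------------------

def _sphere_members(
    center_mm: np.ndarray, radius_mm: float, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxel indices whose world-space centres lie within radius of center_mm.

    Rasterized in world coordinates so anisotropic voxels are handled
    correctly.  Raises PlacementError if the sphere's bounding box exceeds
    the grid (ROI would be truncated).
    """
    inv = np.linalg.inv(affine)
    # bounding box of the sphere in voxel space via its 8 world-space corners
    corners = center_mm + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    vox_corners = (inv[:3, :3] @ corners.T).T + inv[:3, 3]
    lo = np.floor(vox_corners.min(axis=0)).astype(int)
    hi = np.ceil(vox_corners.max(axis=0)).astype(int)
    if np.any(lo < 0) or np.any(hi > np.array(shape) - 1):
        raise PlacementError(
            f"ROI sphere at {tuple(np.round(center_mm, 2))} mm "
            f"(r={radius_mm} mm) extends outside the grid {shape}"
        )
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = (affine[:3, :3] @ vox.T).T + affine[:3, 3]
    inside = np.linalg.norm(world - center_mm, axis=1) <= radius_mm
    return vox[inside].astype(int)


def place_roi(
    spec: RoiSpec, wm: WmProbVolume, search_bound: int = DEFAULT_SEARCH_BOUND
) -> PlacedRoi:
    """Choose the in-plane ROI displacement maximizing summed WM probability.

    Every integer displacement (dx, dy) with |dx|, |dy| <= ``search_bound``
    (dz = 0, in voxel units along the grid's x-y plane) is evaluated,
    including the undisplaced position.  Ties are broken by smaller
    Euclidean displacement, then lexicographically on (dx, dy).
    """
    if search_bound < 0:
        raise ValidationError("search_bound must be >= 0")
    affine = wm.affine
    shape = wm.data.shape
    center = np.asarray(spec.center_mm, dtype=float)
    rng = range(-search_bound, search_bound + 1)
    candidates = sorted(
        ((dx, dy) for dx in rng for dy in rng),
        key=lambda d: (d[0] * d[0] + d[1] * d[1], d),
    )
    best: PlacedRoi | None = None
    for dx, dy in candidates:
        shifted = center + affine[:3, :3] @ np.array([dx, dy, 0.0])
        members = _sphere_members(shifted, spec.radius_mm, affine, shape)
        total = float(wm.data[members[:, 0], members[:, 1], members[:, 2]].sum())
        if best is None or total > best.wm_prob_sum:
            best = PlacedRoi(
                spec=spec, displacement=(dx, dy), member_voxels=members, wm_prob_sum=total
            )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# The ALPS index
# ---------------------------------------------------------------------------

def _check_specs(specs: Sequence[RoiSpec]) -> dict:
    if len(specs) != 4:
        raise ValidationError(f"ALPS needs exactly 4 ROIs, got {len(specs)}")
    by_key = {(s.label, s.hemisphere): s for s in specs}
    want = {(lab, hemi) for lab in ("projection", "association") for hemi in ("left", "right")}
    if set(by_key) != want:
        raise ValidationError(
            "ALPS needs one ROI per (label, hemisphere) pair: "
            "projection/association x left/right"
        )
    return by_key


def compute_alps(
    tensor: TensorVolume,
    wm: WmProbVolume,
    specs: Sequence[RoiSpec],
    wm_threshold: float = DEFAULT_WM_THRESHOLD,
    search_bound: int = DEFAULT_SEARCH_BOUND,
) -> AlpsResult:
    """Compute the per-hemisphere and mean ALPS index.

    Each of the four ROIs is placed by :func:`place_roi`; within each placed
    ROI, voxels with WM probability below ``wm_threshold`` (default 0.90) are
    excluded.  Per hemisphere,

        ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

    where each term is the mean of that tensor component over the retained
    voxels of the named ROI.  The reported index is the mean of the left and
    right indices.  An ROI retaining zero voxels is an error naming the ROI.
    """
    by_key = _check_specs(specs)
    if tensor.components.shape[:3] != wm.data.shape:
        raise ValidationError("tensor and WM-probability grids differ in shape")

    placed: dict[tuple[str, str], PlacedRoi] = {}
    retained: dict[tuple[str, str], np.ndarray] = {}
    for key, spec in by_key.items():
        try:
            roi = place_roi(spec, wm, search_bound=search_bound)
        except PlacementError as exc:
            raise PlacementError(f"ROI {key[0]}/{key[1]}: {exc}") from exc
        vox = roi.member_voxels
        probs = wm.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        keep = vox[probs >= wm_threshold]
        if len(keep) == 0:
            raise ComputationError(
                f"ROI {key[0]}/{key[1]}: no voxels reach WM probability "
                f">= {wm_threshold}"
            )
        placed[key] = roi
        retained[key] = keep

    def roi_mean(component: str, key: tuple[str, str]) -> float:
        vox = retained[key]
        vals = tensor.component(component)[vox[:, 0], vox[:, 1], vox[:, 2]]
        return float(vals.mean())

    per_hemisphere = {}
    for hemi in ("left", "right"):
        dxx_proj = roi_mean("Dxx", ("projection", hemi))
        dxx_assoc = roi_mean("Dxx", ("association", hemi))
        dyy_proj = roi_mean("Dyy", ("projection", hemi))
        dzz_assoc = roi_mean("Dzz", ("association", hemi))
        denom = 0.5 * (dyy_proj + dzz_assoc)
        if denom == 0:
            raise ComputationError(f"{hemi} hemisphere: zero denominator diffusivity")
        per_hemisphere[hemi] = {
            "dxx_proj": dxx_proj,
            "dxx_assoc": dxx_assoc,
            "dyy_proj": dyy_proj,
            "dzz_assoc": dzz_assoc,
            "alps": 0.5 * (dxx_proj + dxx_assoc) / denom,
        }

    alps_mean = 0.5 * (per_hemisphere["left"]["alps"] + per_hemisphere["right"]["alps"])
    return AlpsResult(
        per_hemisphere=per_hemisphere,
        alps_mean=alps_mean,
        retained_counts={k: len(v) for k, v in retained.items()},
        displacements={k: p.displacement for k, p in placed.items()},
    )


# ---------------------------------------------------------------------------
# ROI configuration file
# ---------------------------------------------------------------------------

def load_roi_config(path) -> dict:
    """Load an ROI YAML config: list of ROIs plus search/threshold options.

    Expected layout::

        rois:
          - {label: projection, hemisphere: left, center_mm: [-26, -14, 28], radius_mm: 2.5}
          ...
        search_bound: 2
        wm_threshold: 0.90
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "rois" not in raw:
        raise ConfigError(f"{path}: ROI config must be a mapping with a 'rois' list")
    try:
        specs = [
            RoiSpec(
                label=r["label"],
                hemisphere=r["hemisphere"],
                center_mm=tuple(r["center_mm"]),
                radius_mm=float(r.get("radius_mm", DEFAULT_ROI_RADIUS_MM)),
            )
            for r in raw["rois"]
        ]
    except (KeyError, TypeError, ValidationError) as exc:
        raise ConfigError(f"{path}: malformed ROI entry: {exc}") from exc
    _check_specs(specs)
    return {
        "specs": specs,
        "search_bound": int(raw.get("search_bound", DEFAULT_SEARCH_BOUND)),
        "wm_threshold": float(raw.get("wm_threshold", DEFAULT_WM_THRESHOLD)),
    }
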