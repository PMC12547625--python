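"""BOLD-CSF coupling from resting-state fMRI.

During non-REM sleep and, more weakly, wakeful rest, large global dips in the
cortical BOLD signal are followed by an inflow of fresh CSF at the bottom of
the imaging volume, visible as a bright inflow signal in the lowest slices.
The coupling marker quantifies this: the negated, zero-clipped first
derivative of the mean cortical BOLD signal is cross-correlated against the
mean CSF signal from the bottom three slices, over lags up to +/-20 s in
steps of one TR, and the coupling is the maximal correlation (the lag at the
maximum is reported alongside).

Preprocessing follows two paths after discarding the first and last five
volumes:

* BOLD path: 4 mm FWHM Gaussian smoothing -> linear detrend -> 0.01-0.1 Hz
  band-pass -> voxelwise z-transform -> mean over the cortical GM mask ->
  first difference -> negate and clip at zero.
* CSF path: NO smoothing (the signal lives in a handful of voxels) ->
  linear detrend -> band-pass -> z-transform -> mean over the CSF mask
  restricted to the three most inferior slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    InsufficientDataError,
    MaskError,
    ParameterError,
    QcError,
    ValidationError,
)
from .io_core import MaskVolume, Series4D

__all__ = [
    "SignalTrace",
    "CouplingResult",
    "CouplingConfig",
    "discard_edge_volumes",
    "gaussian_smooth",
    "detrend_linear",
    "bandpass",
    "zscore_voxelwise",
    "cortical_bold_regressor",
    "csf_inflow_signal",
    "lagged_max_correlation",
    "compute_coupling",
    "circular_shift_null",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SignalTrace:
    """A 1D time series sampled every ``dt`` seconds.

    ``t0_index`` records which acquisition volume the first sample refers to,
    so traces shortened by edge discarding or differentiation stay aligned.
    """

    values: np.ndarray
    dt: float
    t0_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValidationError("SignalTrace needs at least 2 samples")
        if self.dt <= 0:
            raise ValidationError("sampling interval must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CouplingResult:
    """Maximal lagged correlation between the BOLD regressor and CSF signal.

    ``lag_s`` uses the convention that a positive lag means the BOLD
    regressor precedes (leads) the CSF signal.  ``profile`` maps each
    admissible lag (seconds) to its Pearson correlation; shifts skipped for
    zero variance are NaN.
    """

    coupling: float
    lag_s: float
    profile_lags: np.ndarray
    profile_r: np.ndarray
    csf_voxel_count: int
    n_samples_at_peak: int

    def to_dict(self) -> dict:
        return {
            "coupling": float(self.coupling),
            "lag_s": float(self.lag_s),
            "lag_sign_convention": "positive = BOLD regressor precedes CSF signal",
            "profile": {
                f"{lag:g}": (None if np.isnan(r) else float(r))
                for lag, r in zip(self.profile_lags, self.profile_r)
            },
            "csf_voxel_count": int(self.csf_voxel_count),
            "n_samples_at_peak": int(self.n_samples_at_peak),
        }


@dataclass(frozen=True)
class CouplingConfig:
    """Tunable parameters of the coupling pipeline (defaults as published)."""

    n_edge_volumes: int = 5
    fwhm_mm: float = 4.0
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.1
    max_lag_s: float = 20.0
    n_bottom_slices: int = 3
    min_csf_voxels: int = 5
    min_overlap: int = 30

    def to_dict(self) -> dict:
        return {
            "n_edge_volumes": self.n_edge_volumes,
            "fwhm_mm": self.fwhm_mm,
            "band_lo_hz": self.band_lo_hz,
            "band_hi_hz": self.band_hi_hz,
            "max_lag_s": self.max_lag_s,
            "n_bottom_slices": self.n_bottom_slices,
            "min_csf_voxels": self.min_csf_voxels,
            "min_overlap": self.min_overlap,
        }


# ---------------------------------------------------------------------------
# Preprocessing stages
# ---------------------------------------------------------------------------

def discard_edge_volumes(series: Series4D, n_edge: int = 5) -> Series4D:
    """Drop the first and last ``n_edge`` volumes (magnetization steady state)."""
    if n_edge < 0:
        raise ParameterError("n_edge must be >= 0")
    n = series.n_volumes
    if n <= 2 * n_edge:
        raise InsufficientDataError(
            f"need more than {2 * n_edge} volumes to discard {n_edge} from each end; got {n}"
        )
    return Series4D(
        data=series.data[..., n_edge : n - n_edge],
        affine=series.affine,
        t_spacing=series.t_spacing,
    )


def gaussian_smooth(series: Series4D, fwhm_mm: float = 4.0) -> Series4D:
    """Per-volume 3D Gaussian smoothing with the kernel width given in mm.

    sigma_mm = FWHM / (2 sqrt(2 ln 2)) is converted to voxel units per axis,
    so anisotropic voxels get anisotropic voxel-space sigmas.  Reflective
    boundary handling.
    """
    if fwhm_mm <= 0:
        raise ParameterError("FWHM must be positive")
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / series.voxel_dims
    out = ndimage.gaussian_filter(
        series.data, sigma=tuple(sigma_vox) + (0.0,), mode="reflect"
    )
    return Series4D(data=out, affine=series.affine, t_spacing=series.t_spacing)


def _as_time_matrix(data: np.ndarray) -> np.ndarray:
    """View 1D trace or 4D series as (n_signals, n_time)."""
    if data.ndim == 1:
        return data[None, :]
    return data.reshape(-1, data.shape[-1])


def detrend_linear(data: np.ndarray) -> np.ndarray:
    """Remove per-signal OLS intercept + linear trend along the last axis."""
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    if n < 3:
        raise InsufficientDataError(f"linear detrending needs >= 3 time points, got {n}")
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])
    mat = _as_time_matrix(data)
    coef = np.linalg.lstsq(design, mat.T, rcond=None)[0]
    resid = mat - (design @ coef).T
    return resid.reshape(data.shape)


def bandpass(data: np.ndarray, lo_hz: float, hi_hz: float, dt: float) -> np.ndarray:
    """Zero-phase ideal band-pass along the last axis.

    Retains rFFT bins with lo <= f <= hi inclusive and removes DC.  Being a
    projection onto a set of Fourier bins, the filter is linear and exactly
    idempotent.
    """
    data = np.asarray(data, dtype=float)
    if dt <= 0:
        raise ParameterError("dt must be positive")
    nyquist = 0.5 / dt
    if not (0 <= lo_hz < hi_hz):
        raise ParameterError(f"need 0 <= lo < hi, got lo={lo_hz}, hi={hi_hz}")
    if hi_hz > nyquist + 1e-12:
        raise ParameterError(f"hi={hi_hz} Hz exceeds Nyquist {nyquist:g} Hz")
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=dt)
    keep = (freqs >= lo_hz) & (freqs <= hi_hz)
    keep[0] = False  # DC always removed
    spec = np.fft.rfft(data, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def zscore_voxelwise(data: np.ndarray) -> np.ndarray:
    """Per-signal temporal z-transform; zero-variance signals become zeros."""
    data = np.asarray(data, dtype=float)
    if data.shape[-1] < 2:
        raise InsufficientDataError("z-transform needs >= 2 time points")
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (data - mean) / sd
    return np.where(sd > 0, z, 0.0)


# ---------------------------------------------------------------------------
# Signal extraction
# ---------------------------------------------------------------------------

def cortical_bold_regressor(series: Series4D, gm_mask: MaskVolume) -> SignalTrace:
    """Negated, zero-clipped derivative of the mean cortical signal.

    g(t) is the mean preprocessed signal over the cortical GM mask; the
    first difference d(t) = g(t) - g(t-1) is assigned to the later timepoint
    (length n-1), and the regressor is r(t) = max(0, -d(t)), which is large
    when the global BOLD signal is falling.
    """
    if gm_mask.shape != series.grid_shape:
        raise MaskError("GM mask shape does not match series grid")
    if gm_mask.n_voxels == 0:
        raise MaskError("cortical GM mask is empty")
    if series.t_spacing is None:
        raise ValidationError("BOLD series needs a TR (t_spacing)")
    g = series.data[gm_mask.data].mean(axis=0)
    d = np.diff(g)
    r = np.maximum(0.0, -d)
    return SignalTrace(values=r, dt=series.t_spacing, t0_index=1)


def _inferior_axis(affine: np.ndarray) -> tuple[int, bool]:
    """Voxel axis closest to world inferior-superior, and whether index 0 is inferior.

    Axis = argmax |dz/di| over voxel axes; if the world-z component of that
    column is positive, increasing index moves superior, so the bottom of
    the head sits at index 0.
    """
    zrow = np.asarray(affine)[2, :3]
    axis = int(np.argmax(np.abs(zrow)))
    bottom_at_zero = zrow[axis] > 0
    return axis, bottom_at_zero


def csf_inflow_signal(
    series: Series4D,
    csf_mask: MaskVolume,
    n_bottom_slices: int = 3,
    min_csf_voxels: int = 5,
) -> tuple[SignalTrace, int]:
    """Mean CSF signal restricted to the most inferior slices.

    "Bottom" is determined from the affine: the voxel axis closest to the
    world inferior-superior direction, taking the end with the smaller world
    z.  Fewer than ``min_csf_voxels`` CSF voxels in that band is a QC error.
    """
    if csf_mask.shape != series.grid_shape:
        raise MaskError("CSF mask shape does not match series grid")
    if series.t_spacing is None:
        raise ValidationError("BOLD series needs a TR (t_spacing)")
    if n_bottom_slices < 1:
        raise ParameterError("n_bottom_slices must be >= 1")
    axis, bottom_at_zero = _inferior_axis(series.affine)
    n_slices = series.grid_shape[axis]
    n_bottom = min(n_bottom_slices, n_slices)
    band = np.zeros(series.grid_shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(0, n_bottom) if bottom_at_zero else slice(n_slices - n_bottom, n_slices)
    band[tuple(sl)] = True
    sel = csf_mask.data & band
    count = int(sel.sum())
    if count < min_csf_voxels:
        raise QcError(
            f"only {count} CSF voxels in the bottom {n_bottom_slices} slices; "
            f"need >= {min_csf_voxels}"
        )
    trace = series.data[sel].mean(axis=0)
    return SignalTrace(values=trace, dt=series.t_spacing, t0_index=0), count


# ---------------------------------------------------------------------------
# Lagged maximal correlation
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def lagged_max_correlation(
    bold: SignalTrace,
    csf: SignalTrace,
    max_lag_s: float = 20.0,
    min_overlap: int = 30,
    csf_voxel_count: int = 0,
) -> CouplingResult:
    """Maximal Pearson correlation over integer-TR lags within +/- max_lag_s.

    At lag k*dt (positive = BOLD precedes CSF), bold[i] is paired with
    csf[i+k] over the overlapping samples only — no padding or wrap-around,
    which would bias long lags toward zero.  Shifts whose overlap falls
    below ``min_overlap`` or whose segments have zero variance are recorded
    as NaN in the profile.  Ties are broken by smaller |lag|, then the
    negative lag first.
    """
    if abs(bold.dt - csf.dt) > 1e-9:
        raise ValidationError("BOLD and CSF traces must share the sampling interval")
    if len(bold) != len(csf):
        raise ValidationError(
            f"traces must be aligned to equal length, got {len(bold)} vs {len(csf)}"
        )
    if max_lag_s < 0:
        raise ParameterError("max_lag_s must be >= 0")
    x = bold.values
    y = csf.values
    n = len(x)
    dt = bold.dt
    kmax = int(np.floor(max_lag_s / dt + 1e-9))
    lags_k = np.arange(-kmax, kmax + 1)
    profile = np.full(lags_k.size, np.nan)
    for idx, k in enumerate(lags_k):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        if len(a) < min_overlap:
            continue
        profile[idx] = _pearson(a, b)
    if np.all(np.isnan(profile)):
        raise InsufficientDataError(
            "no admissible shift has enough overlapping samples with nonzero variance"
        )
    # tie-break: smaller |lag| first, then negative before positive
    order = sorted(range(lags_k.size), key=lambda i: (abs(int(lags_k[i])), int(lags_k[i])))
    best_i = None
    best_r = -np.inf
    for i in order:
        r = profile[i]
        if not np.isnan(r) and r > best_r:
            best_r = r
            best_i = i
    k = int(lags_k[best_i])
    return CouplingResult(
        coupling=float(best_r),
        lag_s=k * dt,
        profile_lags=lags_k * dt,
        profile_r=profile,
        csf_voxel_count=csf_voxel_count,
        n_samples_at_peak=n - abs(k),
    )


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

def compute_coupling(
    raw_series: Series4D,
    gm_mask: MaskVolume,
    csf_mask: MaskVolume,
    config: CouplingConfig = CouplingConfig(),
    return_traces: bool = False,
):
    """Run the full BOLD-CSF coupling pipeline on a spatially prepared series.

    Orchestrates edge-volume discarding, the smoothed BOLD path ending in
    the clipped-derivative regressor, the unsmoothed CSF path ending in the
    bottom-slice inflow signal, trace alignment (the derivative shortens the
    BOLD trace by one sample, so the CSF trace drops its first sample), and
    the lagged maximal correlation.
    """
    series = discard_edge_volumes(raw_series, config.n_edge_volumes)
    dt = series.t_spacing
    if dt is None:
        raise ValidationError("BOLD series needs a TR (t_spacing)")

    # BOLD path
    bold = gaussian_smooth(series, config.fwhm_mm)
    bold_data = detrend_linear(bold.data)
    bold_data = bandpass(bold_data, config.band_lo_hz, config.band_hi_hz, dt)
    bold_data = zscore_voxelwise(bold_data)
    bold_series = Series4D(data=bold_data, affine=series.affine, t_spacing=dt)
    regressor = cortical_bold_regressor(bold_series, gm_mask)

    # CSF path: no smoothing
    csf_data = detrend_linear(series.data)
    csf_data = bandpass(csf_data, config.band_lo_hz, config.band_hi_hz, dt)
    csf_data = zscore_voxelwise(csf_data)
    csf_series = Series4D(data=csf_data, affine=series.affine, t_spacing=dt)
    csf_trace, csf_count = csf_inflow_signal(
        csf_series, csf_mask, config.n_bottom_slices, config.min_csf_voxels
    )

    # align: regressor covers volumes 1..n-1 of the trimmed series
    csf_aligned = SignalTrace(values=csf_trace.values[1:], dt=dt, t0_index=1)
    result = lagged_max_correlation(
        regressor,
        csf_aligned,
        max_lag_s=config.max_lag_s,
        min_overlap=config.min_overlap,
        csf_voxel_count=csf_count,
    )
    if return_traces:
        return result, {"bold_regressor": regressor, "csf": csf_aligned}
    return result


def circular_shift_null(
    bold: SignalTrace,
    csf: SignalTrace,
    n_draws: int = 1000,
    seed: int = 0,
    max_lag_s: float = 20.0,
    min_overlap: int = 30,
) -> np.ndarray:
    """Permutation null for the coupling statistic by circular CSF shifts.

    Each draw circularly rotates the CSF trace by a random nonzero offset
    (destroying the lag structure while preserving the autocorrelation) and
    recomputes the maximal lagged correlation with the same admissible
    shifts and overlap rule as :func:`lagged_max_correlation`.  Returns the
    ``n_draws`` null maxima; an observed coupling is typically compared with
    their 95th percentile.
    """
    if abs(bold.dt - csf.dt) > 1e-9 or len(bold) != len(csf):
        raise ValidationError("traces must be aligned (equal dt and length)")
    rng = np.random.default_rng(seed)
    x = bold.values
    n = len(x)
    offsets = rng.integers(1, n, size=n_draws)
    rows = (np.arange(n)[None, :] + offsets[:, None]) % n
    Y = csf.values[rows]  # (n_draws, n)

    dt = bold.dt
    kmax = int(np.floor(max_lag_s / dt + 1e-9))
    best = np.full(n_draws, -np.inf)
    for k in range(-kmax, kmax + 1):
        if k >= 0:
            a = x[: n - k]
            B = Y[:, k:]
        else:
            a = x[-k:]
            B = Y[:, : n + k]
        m = a.size
        if m < min_overlap:
            continue
        ac = a - a.mean()
        an = np.linalg.norm(ac)
        Bc = B - B.mean(axis=1, keepdims=True)
        Bn = np.linalg.norm(Bc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Bc @ ac) / (an * Bn)
        valid = (an > 0) & (Bn > 0)
        r = np.where(valid, r, -np.inf)
        best = np.maximum(best, r)
    if np.all(np.isinf(best)):
        raise InsufficientDataError("no admissible shift in the permutation null")
    return best
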