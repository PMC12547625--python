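import numpy as np
import pytest
from scipy import stats

from csfdyn.boldcsf import (
    CouplingConfig,
    SignalTrace,
    bandpass,
    circular_shift_null,
    compute_coupling,
    cortical_bold_regressor,
    csf_inflow_signal,
    detrend_linear,
    discard_edge_volumes,
    gaussian_smooth,
    lagged_max_correlation,
    zscore_voxelwise,
)
from csfdyn.errors import (
    InsufficientDataError,
    MaskError,
    ParameterError,
    QcError,
)
from csfdyn.io_core import MaskVolume, Series4D
from csfdyn.phantom import FmriPhantomSpec, gen_fmri_phantom


def _series(data, tr=1.0, affine=None):
    if affine is None:
        affine = np.eye(4)
    return Series4D(data=np.asarray(data, float), affine=affine, t_spacing=tr)


class TestDiscardEdgeVolumes:
    @pytest.mark.parametrize("n_in, n_edge, n_out", [(490, 5, 480), (11, 5, 1)])
    def test_drops_both_ends(self, n_in, n_edge, n_out):
        s = _series(np.arange(n_in)[None, None, None, :] * np.ones((2, 2, 2, 1)))
        out = discard_edge_volumes(s, n_edge)
        assert out.n_volumes == n_out
        assert out.data[0, 0, 0, 0] == n_edge  # provenance: first kept volume

    def test_too_few_volumes_is_error(self):
        s = _series(np.zeros((2, 2, 2, 10)))
        with pytest.raises(InsufficientDataError):
            discard_edge_volumes(s, 5)


class TestGaussianSmooth:
    def test_impulse_response_matches_kernel(self):
        shape = (15, 15, 15)
        data = np.zeros(shape + (1,))
        data[7, 7, 7, 0] = 1.0
        out = gaussian_smooth(_series(data), fwhm_mm=4.0).data[..., 0]
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        # neighbour/centre ratio of a sampled Gaussian kernel
        expected_ratio = np.exp(-1.0 / (2 * sigma**2))
        for shifted in (out[8, 7, 7], out[6, 7, 7], out[7, 8, 7], out[7, 7, 8]):
            assert shifted / out[7, 7, 7] == pytest.approx(expected_ratio, rel=1e-3)

    def test_constant_volume_unchanged(self):
        data = np.full((10, 10, 10, 3), 42.0)
        out = gaussian_smooth(_series(data), fwhm_mm=4.0)
        np.testing.assert_allclose(out.data, 42.0, rtol=1e-12)

    def test_anisotropic_voxels_scale_sigma_per_axis(self):
        aff = np.diag([1.0, 2.0, 4.0, 1.0])
        shape = (21, 21, 21)
        data = np.zeros(shape + (1,))
        data[10, 10, 10, 0] = 1.0
        out = gaussian_smooth(_series(data, affine=aff), fwhm_mm=4.0).data[..., 0]
        sigma_mm = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        for axis, dim in enumerate([1.0, 2.0, 4.0]):
            sigma_vox = sigma_mm / dim
            idx = [10, 10, 10]
            idx[axis] += 1
            ratio = out[tuple(idx)] / out[10, 10, 10]
            assert ratio == pytest.approx(np.exp(-1 / (2 * sigma_vox**2)), rel=1e-2)


class TestDetrendLinear:
    def test_exact_line_removed(self):
        t = np.arange(100.0)
        np.testing.assert_allclose(detrend_linear(3.0 + 0.5 * t), 0.0, atol=1e-9)

    def test_oscillation_plus_line_leaves_oscillation(self):
        # full-period cosine even about the window midpoint: exactly
        # orthogonal to both the constant and the linear regressor
        n = 200
        t = np.arange(n)
        wave = np.cos(2 * np.pi * 5 * (t - (n - 1) / 2) / n)
        resid = detrend_linear(wave + 2.0 - 0.3 * t)
        np.testing.assert_allclose(resid, wave, atol=1e-9)

    def test_too_short_is_error(self):
        with pytest.raises(InsufficientDataError):
            detrend_linear(np.array([1.0, 2.0]))


class TestBandpass:
    def test_inband_sinusoid_preserved(self):
        t = np.arange(600.0)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, 0.01, 0.1, dt=1.0)
        assert np.abs(y).max() == pytest.approx(np.abs(x).max(), rel=0.01)

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(600.0)
        x = np.sin(2 * np.pi * 0.2 * t)
        y = bandpass(x, 0.01, 0.1, dt=1.0)
        assert np.sum(y**2) < 1e-6 * np.sum(x**2)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=512)
        once = bandpass(x, 0.01, 0.1, dt=1.0)
        twice = bandpass(once, 0.01, 0.1, dt=1.0)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_above_nyquist_is_parameter_error(self):
        with pytest.raises(ParameterError):
            bandpass(np.zeros(100), 0.01, 0.6, dt=1.0)


class TestZscore:
    def test_unit_moments(self):
        rng = np.random.default_rng(1)
        data = rng.normal(2.0, 3.0, (4, 4, 4, 100))
        z = zscore_voxelwise(data)
        np.testing.assert_allclose(z.mean(axis=-1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=-1), 1.0, atol=1e-9)

    def test_constant_voxel_becomes_zeros(self):
        z = zscore_voxelwise(np.full((2, 2, 2, 50), 7.0))
        np.testing.assert_array_equal(z, 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        np.testing.assert_allclose(
            zscore_voxelwise(2.0 * x + 3.0), zscore_voxelwise(x), atol=1e-9
        )


class TestCorticalRegressor:
    def _mask(self, shape):
        return MaskVolume(np.ones(shape, np.uint8), np.eye(4))

    def test_increasing_signal_clips_to_zero(self):
        data = np.tile(np.arange(50.0), (3, 3, 3, 1))
        r = cortical_bold_regressor(_series(data), self._mask((3, 3, 3)))
        np.testing.assert_array_equal(r.values, 0.0)
        assert len(r) == 49 and r.t0_index == 1

    def test_constant_negative_slope_gives_unit_rate(self):
        data = np.tile(-np.arange(50.0), (3, 3, 3, 1))
        r = cortical_bold_regressor(_series(data), self._mask((3, 3, 3)))
        np.testing.assert_allclose(r.values, 1.0)

    def test_cosine_gives_half_wave_rectified_sine(self):
        n = 400
        t = np.arange(n)
        f = 0.02
        g = np.cos(2 * np.pi * f * t)
        data = np.tile(g, (2, 2, 2, 1))
        r = cortical_bold_regressor(_series(data), self._mask((2, 2, 2)))
        # -dg/dt = 2*pi*f*sin(2*pi*f*t); discrete diff evaluated at midpoints
        analytic = 2 * np.pi * f * np.sin(2 * np.pi * f * (t[1:] - 0.5))
        np.testing.assert_allclose(
            r.values, np.maximum(0.0, analytic), atol=2 * np.pi * f * 0.01
        )

    def test_empty_mask_is_error(self):
        data = np.zeros((3, 3, 3, 20))
        with pytest.raises(MaskError):
            cortical_bold_regressor(
                _series(data), MaskVolume(np.zeros((3, 3, 3), np.uint8), np.eye(4))
            )


class TestCsfInflowSignal:
    def test_too_few_csf_voxels_is_qc_error(self):
        shape = (5, 5, 6)
        mask = np.zeros(shape, np.uint8)
        mask[0, :4, 0] = 1  # 4 voxels in the bottom slice
        with pytest.raises(QcError, match="4 CSF voxels"):
            csf_inflow_signal(
                _series(np.ones(shape + (40,))), MaskVolume(mask, np.eye(4))
            )

    def test_mask_above_bottom_slices_is_qc_error(self):
        shape = (5, 5, 10)
        mask = np.zeros(shape, np.uint8)
        mask[:, :, 7:] = 1  # plenty of voxels, none in the bottom three slices
        with pytest.raises(QcError, match="0 CSF voxels"):
            csf_inflow_signal(
                _series(np.ones(shape + (40,))), MaskVolume(mask, np.eye(4))
            )

    def test_mean_of_identical_voxels_equals_single_voxel(self):
        shape = (5, 5, 6)
        trace = np.sin(np.arange(40.0))
        data = np.zeros(shape + (40,))
        mask = np.zeros(shape, np.uint8)
        for k in range(10):
            i, j, z = k % 5, k // 5, k % 3
            data[i, j, z] = trace
            mask[i, j, z] = 1
        sig, count = csf_inflow_signal(_series(data), MaskVolume(mask, np.eye(4)))
        assert count == 10
        np.testing.assert_allclose(sig.values, trace, atol=1e-12)

    def test_inferior_end_follows_affine_orientation(self):
        # flip the z axis: superior now at index 0, bottom slices at the top
        shape = (5, 5, 10)
        aff = np.diag([1.0, 1.0, -1.0, 1.0])
        data = np.zeros(shape + (40,))
        data[:, :, 7:, :] = 5.0
        mask = np.zeros(shape, np.uint8)
        mask[2, 2, 7:] = 1
        sig, count = csf_inflow_signal(
            _series(data, affine=aff), MaskVolume(mask, aff), min_csf_voxels=3
        )
        assert count == 3
        np.testing.assert_allclose(sig.values, 5.0)


class TestLaggedMaxCorrelation:
    def test_exact_shifted_copy_peaks_at_plus_six(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=520)
        bold = SignalTrace(base[:480], dt=1.0)
        csf = SignalTrace(np.concatenate([np.zeros(6), base[:474]]), dt=1.0)
        res = lagged_max_correlation(bold, csf, max_lag_s=20.0)
        assert res.lag_s == 6.0
        assert res.coupling == pytest.approx(1.0, abs=1e-12)

    def test_boundary_saturation_at_max_lag(self):
        # a smooth signal shifted beyond the admissible window: the profile
        # rises toward the true lag, so the max saturates at the boundary
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(23)
        base = gaussian_filter1d(rng.normal(size=600), sigma=8.0)
        bold = SignalTrace(base[30:510], dt=1.0)  # true shift +30 s
        csf = SignalTrace(base[:480], dt=1.0)
        res = lagged_max_correlation(bold, csf, max_lag_s=20.0)
        assert res.lag_s == 20.0

    def test_matches_brute_force_oracle_on_noise(self):
        # independent oracle: python loop + scipy.stats.pearsonr
        rng = np.random.default_rng(99)
        for _ in range(10):
            x = rng.normal(size=120)
            y = rng.normal(size=120)
            res = lagged_max_correlation(
                SignalTrace(x, 1.0), SignalTrace(y, 1.0), max_lag_s=20.0, min_overlap=30
            )
            best_r, best_k = -np.inf, None
            for k in sorted(range(-20, 21), key=lambda k: (abs(k), k)):
                if k >= 0:
                    a, b = x[: 120 - k], y[k:]
                else:
                    a, b = x[-k:], y[: 120 + k]
                if len(a) < 30:
                    continue
                r = stats.pearsonr(a, b).statistic
                if r > best_r:
                    best_r, best_k = r, k
            assert res.coupling == pytest.approx(best_r, abs=1e-12)
            assert res.lag_s == best_k

    def test_profile_shape_and_bound(self):
        rng = np.random.default_rng(4)
        res = lagged_max_correlation(
            SignalTrace(rng.normal(size=200), 1.0),
            SignalTrace(rng.normal(size=200), 1.0),
            max_lag_s=20.0,
        )
        assert len(res.profile_lags) == 2 * 20 + 1
        assert np.nanmax(np.abs(res.profile_r)) <= 1.0 + 1e-12
        assert res.coupling == np.nanmax(res.profile_r)

    def test_overlap_too_small_everywhere_is_error(self):
        with pytest.raises(InsufficientDataError):
            lagged_max_correlation(
                SignalTrace(np.arange(10.0), 1.0),
                SignalTrace(np.arange(10.0), 1.0),
                max_lag_s=5.0,
                min_overlap=30,
            )

    def test_coupling_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        r1 = lagged_max_correlation(SignalTrace(x, 1.0), SignalTrace(y, 1.0))
        r2 = lagged_max_correlation(
            SignalTrace(5.0 * x + 2.0, 1.0), SignalTrace(0.1 * y - 7.0, 1.0)
        )
        assert r2.coupling == pytest.approx(r1.coupling, abs=1e-12)
        assert r2.lag_s == r1.lag_s


class TestComputeCoupling:
    def test_planted_lag_recovered_at_high_snr(self):
        spec = FmriPhantomSpec(seed=5, noise_sigma=0.1)
        series, gm, csf, truth = gen_fmri_phantom(spec)
        res = compute_coupling(series, gm, csf)
        assert abs(res.lag_s - truth["lag_s"]) <= spec.tr_s
        assert res.coupling > 0.9

    def test_zero_coupling_sits_inside_permutation_null(self):
        spec = FmriPhantomSpec(seed=6, coupling_strength=0.0)
        series, gm, csf, _ = gen_fmri_phantom(spec)
        res, traces = compute_coupling(series, gm, csf, return_traces=True)
        null = circular_shift_null(
            traces["bold_regressor"], traces["csf"], n_draws=200, seed=7
        )
        assert res.coupling < np.quantile(null, 0.95)

    def test_empty_gm_mask_is_error(self):
        spec = FmriPhantomSpec(seed=8)
        series, gm, csf, _ = gen_fmri_phantom(spec)
        empty = MaskVolume(np.zeros(gm.shape, np.uint8), gm.affine)
        with pytest.raises(MaskError):
            compute_coupling(series, empty, csf)

    def test_pipeline_is_deterministic(self):
        spec = FmriPhantomSpec(seed=9, noise_sigma=0.3)
        series, gm, csf, _ = gen_fmri_phantom(spec)
        r1 = compute_coupling(series, gm, csf)
        r2 = compute_coupling(series, gm, csf)
        assert r1.coupling == r2.coupling and r1.lag_s == r2.lag_s
        np.testing.assert_array_equal(r1.profile_r, r2.profile_r)
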