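"""Preprocessing chain: registration, destriping, TV denoising, Sauvola
thresholding, size and median filtering, and the assembled pipelines."""

import numpy as np
import pytest
from scipy import ndimage

from granuloscope.phantoms import DegradationConfig, degrade_stack
from granuloscope.preprocess import (
    PipelineConfig,
    RegistrationError,
    THREAD_PRESET,
    TISSUE_PRESET,
    align_stack,
    destripe,
    invert,
    median_filter_3d,
    normalize01,
    register_pair,
    run_pipeline,
    sauvola_threshold,
    size_filter,
    tv_denoise,
)
from granuloscope.stack import PhantomTruth, VolumeStack

from conftest import dice


def _textured_slice(shape=(96, 96), seed=0, sigma=2.0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _static_stack(n=24, seed=0):
    """Replicated textured scene: isolates registration accuracy from
    slice-to-slice structural change."""
    return np.repeat(_textured_slice(seed=seed)[None], n, axis=0)


class TestAlignment:
    def test_identical_slices_give_zero_shifts(self):
        vol = VolumeStack(_static_stack(), (10.5, 4.8, 4.8))
        for method in ("fourier_shift", "ecc"):
            res = align_stack(vol, method=method)
            assert np.abs(res.shifts).max() < 1e-3
            assert np.all(res.shifts[0] == 0.0)

    @pytest.mark.parametrize("method", ["fourier_shift", "ecc"])
    def test_integer_shift_recovered_within_quarter_pixel(self, method):
        data = _static_stack()
        data[10] = np.roll(np.roll(data[10], 3, axis=0), -2, axis=1)
        res = align_stack(VolumeStack(data, (10.5, 4.8, 4.8)), method=method)
        assert np.abs(res.shifts[10] - (-3.0, 2.0)).max() <= 0.25
        assert np.abs(res.shifts[11]).max() <= 0.25  # only slice 10 moved

    @pytest.mark.parametrize("method", ["fourier_shift", "ecc"])
    def test_subpixel_jitter_recovered_rms_half_pixel(self, method):
        stack = _static_stack(n=32, seed=1)
        truth = PhantomTruth(clean=VolumeStack(stack, (10.5, 4.8, 4.8)), config=None)
        deg = degrade_stack(
            truth,
            DegradationConfig(shift_sigma_px=2.0, stripe_amplitude=0.0,
                              gaussian_noise_sigma=0.05, seed=5),
        )
        res = align_stack(deg, method=method)
        resid = res.shifts - (-truth.shifts_px)
        assert np.sqrt((resid ** 2).mean()) <= 0.5

    def test_degenerate_constant_slice_warns_zero_shift(self):
        with pytest.warns(UserWarning, match="degenerate"):
            shift = register_pair(np.zeros((32, 32)), np.ones((32, 32)))
        assert np.all(shift == 0.0)

    def test_large_shift_is_registration_failure(self):
        img = _textured_slice((64, 64))
        mov = np.roll(img, 20, axis=0)  # 31% of the frame
        with pytest.raises(RegistrationError):
            register_pair(img, mov)

    def test_applying_recorded_shifts_reproduces_output(self):
        data = _static_stack(n=8, seed=2)
        data[4] = np.roll(data[4], 2, axis=1)
        vol = VolumeStack(data, (10.5, 4.8, 4.8))
        res = align_stack(vol)
        redone = np.array(
            [ndimage.shift(data[i], res.shifts[i], order=1, mode="nearest")
             for i in range(8)]
        )
        assert np.allclose(redone[1:], res.aligned.data[1:], atol=1e-5)


class TestDestripe:
    def _band_power(self, vol, band):
        f = np.fft.rfftfreq(vol.shape[-1])
        sel = (f >= band[0]) & (f <= band[1])
        spec = np.fft.rfft2(vol, axes=(-2, -1))
        return (np.abs(spec[..., 0, sel]) ** 2).sum()

    def test_near_identity_off_stripes(self):
        # content with no energy in the notch: a periodic pattern varying
        # only along rows plus circularly-smoothed coarse texture whose
        # spectrum lies below the stripe band (non-periodic content would
        # leak into every frequency and defeat the point of the check)
        rng = np.random.default_rng(3)
        y_pattern = np.sin(2 * np.pi * 3 * np.arange(96) / 96.0)[None, :, None]
        coarse = ndimage.gaussian_filter(
            rng.standard_normal((96, 96)), 12.0, mode="wrap"
        )[None]
        vol = np.repeat(y_pattern + coarse, 4, axis=0)
        out = destripe(vol, band=(0.05, 0.2))
        assert np.abs(out - vol).max() < 0.01 * np.ptp(vol)

    def test_pure_stripe_power_reduced_90_percent(self):
        x = np.arange(96)
        stripe = 0.5 * np.sin(2 * np.pi * 0.1 * x)
        vol = np.repeat(stripe[None, None, :], 96, axis=1) + _static_stack(n=1, seed=4)
        out = destripe(vol, band=(0.05, 0.2))
        assert self._band_power(out, (0.08, 0.12)) <= 0.1 * self._band_power(vol, (0.08, 0.12))

    def test_mean_preserved_and_off_notch_power_kept(self):
        vol = _static_stack(n=2, seed=5) + 3.0
        out = destripe(vol, band=(0.05, 0.2))
        assert abs(out.mean() - vol.mean()) <= 1e-3 * abs(vol.mean())
        # total power outside the notch changes by < 1%
        def off_notch_power(v):
            spec = np.abs(np.fft.rfft2(v, axes=(-2, -1))) ** 2
            spec = spec.copy()
            spec[..., 0:3, :] = 0.0
            spec[..., -2:, :] = 0.0
            return spec.sum()
        a, b = off_notch_power(vol), off_notch_power(out)
        assert abs(a - b) <= 0.01 * a

    def test_band_including_dc_rejected(self):
        with pytest.raises(ValueError, match="DC"):
            destripe(_static_stack(n=2), band=(0.0, 0.2))

    def test_destriping_improves_downstream_segmentation(self, granule_truth):
        cfg = DegradationConfig(shift_sigma_px=0.0, stripe_amplitude=0.2,
                                gaussian_noise_sigma=0.0, seed=7)
        deg = degrade_stack(granule_truth, cfg)
        v = normalize01(deg.data)

        def mask_of(vol):
            m = sauvola_threshold(invert(tv_denoise(vol, 0.07)))
            return size_filter(m, 40) & granule_truth.support_mask

        d_with = dice(mask_of(destripe(v, band=(0.05, 0.2))), granule_truth.ls_mask)
        d_without = dice(mask_of(v), granule_truth.ls_mask)
        assert d_with > d_without


class TestTVDenoise:
    def test_constant_volume_unchanged(self):
        vol = np.full((16, 16, 16), 3.5, np.float32)
        out = tv_denoise(vol, weight=0.07)
        assert np.allclose(out, vol, atol=1e-5)

    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.random((12, 12, 12)).astype(np.float32)
        assert np.array_equal(tv_denoise(vol, weight=0.0), vol)

    def test_denoises_two_level_step_and_keeps_edge(self):
        clean = np.zeros((24, 24, 24), np.float32)
        clean[:, 12:, :] = 1.0
        rng = np.random.default_rng(1)
        noisy = clean + rng.normal(0, 0.2, clean.shape).astype(np.float32)
        out = tv_denoise(noisy, weight=0.07)
        assert np.sqrt(((out - clean) ** 2).mean()) < np.sqrt(((noisy - clean) ** 2).mean())
        # edge position: along-y profile crosses 0.5 within 1 voxel of y=12
        prof = out.mean(axis=(0, 2))
        crossing = np.nonzero(prof >= 0.5)[0][0]
        assert abs(crossing - 12) <= 1

    def test_energy_non_increasing_and_maximum_principle(self):
        rng = np.random.default_rng(2)
        vol = rng.random((16, 16, 16)).astype(np.float32)
        out, energies = tv_denoise(vol, weight=0.1, eps=0.0, max_iter=400,
                                   check_every=100, return_energies=True)
        assert all(a >= b - 1e-4 * abs(a) for a, b in zip(energies, energies[1:]))
        rng_span = np.ptp(vol)
        assert out.min() >= vol.min() - 1e-6 * rng_span
        assert out.max() <= vol.max() + 1e-6 * rng_span

    def test_agrees_with_independent_chambolle_solver(self):
        # same energy, independent implementation: solutions nearly coincide
        from skimage.restoration import denoise_tv_chambolle

        rng = np.random.default_rng(3)
        vol = rng.random((16, 16, 16))
        mine = tv_denoise(vol.astype(np.float32), weight=0.1, eps=1e-6, max_iter=3000)
        ref = denoise_tv_chambolle(vol, weight=0.1, eps=1e-6, max_num_iter=3000)
        assert np.abs(mine - ref).max() < 0.02

    def test_non_finite_input_rejected(self):
        vol = np.zeros((8, 8, 8))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            tv_denoise(vol)


class TestInvertSauvola:
    def test_invert_involution_on_8bit(self):
        rng = np.random.default_rng(4)
        vol = rng.integers(0, 256, (8, 16, 16), dtype=np.uint8)
        assert np.array_equal(invert(invert(vol)), vol)
        assert np.array_equal(invert(np.full((4, 4, 4), 7, np.uint8)),
                              np.full((4, 4, 4), 248, np.uint8))

    def test_invert_reverses_phase_mean_order(self, granule_truth):
        vol = granule_truth.clean.data
        inv = invert(vol)
        ls, sup = granule_truth.ls_mask, granule_truth.support_mask
        hs = sup & ~ls
        assert vol[ls].mean() < vol[hs].mean()
        assert inv[ls].mean() > inv[hs].mean()

    @staticmethod
    def _naive_sauvola(img, window=11, k=0.005, r=1.7):
        pad = window // 2
        padded = np.pad(img.astype(np.float64), pad, mode="reflect")
        out = np.zeros(img.shape, bool)
        for y in range(img.shape[0]):
            for x in range(img.shape[1]):
                win = padded[y : y + window, x : x + window]
                m = win.mean()
                s = win.std()
                t = m * (1.0 + k * (s / r - 1.0))
                out[y, x] = img[y, x] > t
        return out

    def test_constant_slice_is_all_foreground(self):
        img = np.full((32, 32), 0.6)
        assert sauvola_threshold(img[None], window=11, k=0.005, r=1.7).all()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_integral_image_matches_naive_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((64, 64))
        fast = sauvola_threshold(img[None])[0]
        assert np.array_equal(fast, self._naive_sauvola(img))

    def test_two_level_pattern_matches_oracle_and_bright_support(self):
        img = np.full((64, 64), 50.0)
        img[16:48, 16:48] = 200.0
        img /= 255.0
        fast = sauvola_threshold(img[None])[0]
        assert np.array_equal(fast, self._naive_sauvola(img))
        # away from borders of the bright block, mask equals its support
        assert fast[22:42, 22:42].all()
        assert not fast[2:10, 2:10].any() or fast[2:10, 2:10].all()  # uniform region

    def test_window_larger_than_slice_rejected(self):
        with pytest.raises(ValueError):
            sauvola_threshold(np.zeros((1, 8, 8)), window=11)


class TestSizeAndMedianFilters:
    def test_inclusive_minimum_forty(self):
        mask = np.zeros((1, 64, 64), bool)
        # disjoint square-ish components of sizes 10, 39, 40, 100
        mask[0, 1:3, 1:6] = True                     # 10
        mask[0, 10:13, 10:23] = True                 # 39
        mask[0, 12, 22] = False
        mask[0, 20:25, 20:28] = True                 # 40
        mask[0, 40:50, 40:50] = True                 # 100
        out = size_filter(mask, 40, mode="per_slice_2d")
        lab, n = ndimage.label(out[0], structure=np.ones((3, 3), bool))
        sizes = sorted(np.bincount(lab.ravel())[1:])
        assert n == 2 and sizes == [40, 100]

    def test_empty_mask_passes_through(self):
        mask = np.zeros((2, 8, 8), bool)
        assert not size_filter(mask, 40).any()

    def test_min_one_is_identity(self):
        rng = np.random.default_rng(5)
        mask = rng.random((4, 16, 16)) > 0.5
        assert np.array_equal(size_filter(mask, 1), mask)

    def test_volume_mode_uses_3d_connectivity(self):
        mask = np.zeros((4, 8, 8), bool)
        mask[0:4, 2, 2] = True  # 4 voxels stacked in z
        assert not size_filter(mask, 4, mode="per_slice_2d").any()
        assert size_filter(mask, 4, mode="volume_3d").sum() == 4

    def test_median_removes_isolated_voxel(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        assert not median_filter_3d(mask).any()

    def test_median_keeps_solid_block_interior(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        out = median_filter_3d(mask)
        assert out[4:10, 4:10, 4:10].all()
        assert out.dtype == bool

    def test_median_repairs_salt_and_pepper(self, vesicle_truth):
        # compact vesicle bodies survive the median while speckle is removed
        rng = np.random.default_rng(6)
        truth_mask = vesicle_truth.labels.instances > 0
        flips = rng.random(truth_mask.shape) < 0.05
        noisy = truth_mask ^ flips
        out = median_filter_3d(noisy)
        before = (noisy ^ truth_mask).sum()
        after = (out ^ truth_mask).sum()
        assert after * 5 <= before

    def test_radius_1p5_neighbourhood_has_19_voxels(self):
        from granuloscope.preprocess import _ellipsoid_footprint

        assert _ellipsoid_footprint((1.5, 1.5, 1.5)).sum() == 19


class TestPipeline:
    def test_thread_preset_on_clean_phantom_recovers_ls(self):
        from granuloscope.phantoms import GranulePhantomConfig, make_granule_phantom

        truth = make_granule_phantom(GranulePhantomConfig(shape_voxels=(96, 128, 128)))
        res = run_pipeline(truth.clean, THREAD_PRESET)
        d = dice(res.mask & truth.support_mask, truth.ls_mask)
        assert d >= 0.90

    def test_tissue_preset_runs_only_alignment_and_tv(self, vesicle_truth):
        sub = VolumeStack(vesicle_truth.clean.data[:8, :64, :64],
                          vesicle_truth.clean.voxel_size_nm)
        res = run_pipeline(sub, TISSUE_PRESET)
        assert [s.name for s in res.stages] == ["normalize", "align", "tv"]
        assert res.mask is None

    def test_rerun_is_checksum_identical(self, granule_truth):
        sub = VolumeStack(granule_truth.clean.data[:8, :48, :48],
                          granule_truth.clean.voxel_size_nm)
        cfg = PipelineConfig(stages=("align", "tv", "invert", "sauvola"))
        a = run_pipeline(sub, cfg)
        b = run_pipeline(sub, cfg)
        assert [s.checksum for s in a.stages] == [s.checksum for s in b.stages]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(sauvola_window=10).validate()
        with pytest.raises(ValueError):
            PipelineConfig(stages=("align", "frobnicate")).validate()
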