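"""Phantom generators: determinism, fidelity of requested structure, and
the injected imaging degradations."""

import dataclasses

import numpy as np
import pytest

from granuloscope.phantoms import (
    CompositionConfig,
    DegradationConfig,
    GranulePhantomConfig,
    NATIVE_CUTICLE_EDS,
    PackingError,
    VESICLE_GLAND_EDS,
    VesiclePhantomConfig,
    degrade_stack,
    make_eds_phantom,
    make_granule_phantom,
    make_vesicle_phantom,
    preset,
)


class TestGranulePhantom:
    def test_determinism_bit_identical(self):
        cfg = GranulePhantomConfig(shape_voxels=(24, 48, 48), granule_radius_nm=200.0)
        a = make_granule_phantom(cfg)
        b = make_granule_phantom(cfg)
        assert np.array_equal(a.clean.data, b.clean.data)
        assert np.array_equal(a.ls_mask, b.ls_mask)

    def test_realized_ls_fraction_close_to_request(self, granule_truth):
        cfg = granule_truth.config
        assert abs(granule_truth.realized["ls_fraction"] - cfg.ls_volume_fraction) <= 0.01

    def test_unresolvable_thickness_rejected(self):
        cfg = GranulePhantomConfig(layer_thickness_nm=5.0)  # < 2 x 4.8 nm
        with pytest.raises(ValueError, match="unresolvable"):
            make_granule_phantom(cfg)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_granule_phantom(GranulePhantomConfig(ls_volume_fraction=1.0))

    def test_ls_mask_confined_to_granule_support(self, granule_truth):
        assert not (granule_truth.ls_mask & ~granule_truth.support_mask).any()

    def test_isotropic_config_has_isotropic_directional_acf(self):
        # anisotropy 1: the two-point correlation along each axis must agree
        cfg = GranulePhantomConfig(
            shape_voxels=(64, 64, 64),
            voxel_size_nm=(4.8, 4.8, 4.8),
            anisotropy=1.0,
            granule_radius_nm=1e6,  # fill the box
            seed=11,
        )
        mask = make_granule_phantom(cfg).ls_mask
        g = mask.astype(float) - mask.mean()
        lag = 3
        cors = [
            (g * np.roll(g, lag, axis=ax)).mean() / (g * g).mean() for ax in range(3)
        ]
        assert np.ptp(cors) < 0.05

    def test_directional_anisotropy_increases_with_parameter(self):
        # tilt 0: layer normal along y; correlation along z (an in-layer
        # direction) minus along y (across layers) grows with anisotropy
        scores = []
        for a in (1.0, 2.0, 4.0):
            cfg = GranulePhantomConfig(
                shape_voxels=(64, 64, 64),
                voxel_size_nm=(4.8, 4.8, 4.8),
                anisotropy=a,
                lamellar_tilt_deg=0.0,
                granule_radius_nm=1e6,
                seed=11,
            )
            mask = make_granule_phantom(cfg).ls_mask
            g = mask.astype(float) - mask.mean()
            var = (g * g).mean()
            lag = 4
            c_inplane = (g * np.roll(g, lag, axis=0)).mean() / var
            c_normal = (g * np.roll(g, lag, axis=1)).mean() / var
            scores.append(c_inplane - c_normal)
        assert scores[0] < scores[1] < scores[2]


class TestVesiclePhantom:
    def test_single_vesicle_pure_proto_granule(self):
        cfg = VesiclePhantomConfig(
            n_vesicles=1,
            vesicle_radius_nm=200.0,
            phase_fractions=(1.0, 0.0, 0.0),
            shape_voxels=(48, 64, 64),
            seed=1,
        )
        truth = make_vesicle_phantom(cfg)
        inside = truth.labels.instances > 0
        assert (truth.labels.phases[inside] == 1).all()  # 1 = pg

    def test_mean_realized_fractions_match_request(self, vesicle_truth):
        per = vesicle_truth.realized["vesicles"]
        req = vesicle_truth.config.phase_fractions
        for i, phase in enumerate(("pg", "pm", "cp")):
            mean = np.mean([v[phase] for v in per])
            assert abs(mean - req[i]) <= 0.02

    def test_intensity_ordering_pm_heaviest_cp_lightest(self, vesicle_truth):
        vol = vesicle_truth.clean.data
        ph = vesicle_truth.labels.phases
        means = {name: vol[ph == code].mean() for code, name in ((1, "pg"), (2, "pm"), (3, "cp"))}
        assert means["pm"] > means["pg"] > means["cp"]

    def test_vesicles_pairwise_disjoint(self, vesicle_truth):
        # every labelled voxel belongs to exactly one instance by construction;
        # check no instance voxel count exceeds its sphere volume bound
        inst = vesicle_truth.labels.instances
        per = vesicle_truth.realized["vesicles"]
        counts = np.bincount(inst.ravel())
        for v in per:
            assert counts[v["vesicle_id"]] == v["n_voxels"]

    def test_packing_failure_names_achievable_count(self):
        cfg = VesiclePhantomConfig(
            n_vesicles=50,
            vesicle_radius_nm=300.0,
            shape_voxels=(32, 64, 64),
            max_placement_tries=200,
            seed=1,
        )
        with pytest.raises(PackingError, match=r"could only place \d+ of 50"):
            make_vesicle_phantom(cfg)

    def test_determinism(self):
        cfg = VesiclePhantomConfig(n_vesicles=3, vesicle_radius_nm=200.0,
                                   shape_voxels=(32, 96, 96), seed=5)
        a = make_vesicle_phantom(cfg)
        b = make_vesicle_phantom(cfg)
        assert np.array_equal(a.clean.data, b.clean.data)
        assert np.array_equal(a.labels.phases, b.labels.phases)


class TestDegradation:
    def test_zero_degradation_is_identity(self, granule_truth):
        cfg = DegradationConfig(
            shift_sigma_px=0.0, stripe_amplitude=0.0, gaussian_noise_sigma=0.0,
            shot_noise=False, invert_contrast=False, seed=0,
        )
        out = degrade_stack(granule_truth, cfg)
        assert np.array_equal(out.data, granule_truth.clean.data.astype(np.float32))

    def test_recorded_shifts_reproduce_on_rerun(self):
        cfg = GranulePhantomConfig(shape_voxels=(24, 48, 48), granule_radius_nm=200.0)
        d = DegradationConfig(shift_sigma_px=2.0, seed=42)
        t1 = make_granule_phantom(cfg)
        v1 = degrade_stack(t1, d)
        s1 = t1.shifts_px.copy()
        t2 = make_granule_phantom(cfg)
        v2 = degrade_stack(t2, d)
        assert np.array_equal(s1, t2.shifts_px)
        assert np.array_equal(v1.data, v2.data)
        assert np.all(s1[0] == 0.0)

    def test_stripes_raise_band_power_tenfold(self, granule_truth):
        band = (0.05, 0.20)
        cfg = DegradationConfig(
            shift_sigma_px=0.0, stripe_amplitude=0.15, stripe_frequency_band=band,
            gaussian_noise_sigma=0.0, seed=7,
        )
        clean = granule_truth.clean.data
        striped = degrade_stack(granule_truth, cfg).data

        def band_power(vol):
            f = np.fft.rfftfreq(vol.shape[2])
            sel = (f >= band[0]) & (f <= band[1])
            spec = np.fft.rfft2(vol, axes=(1, 2))
            # stripe energy lives on the near-zero row-frequency line
            return (np.abs(spec[:, 0, sel]) ** 2).sum()

        assert band_power(striped) >= 10.0 * band_power(clean)

    def test_inversion_flag_recorded(self, granule_truth):
        cfg = DegradationConfig(shift_sigma_px=0.0, stripe_amplitude=0.0,
                                gaussian_noise_sigma=0.0, invert_contrast=True, seed=0)
        out = degrade_stack(granule_truth, cfg)
        assert out.meta["inverted_contrast"] is True
        # inversion reverses the rank order of phase means
        ls = granule_truth.ls_mask
        hs = granule_truth.support_mask & ~ls
        assert out.data[ls].mean() > out.data[hs].mean()  # ls was darker


class TestEDSPhantom:
    def _labels(self, n=64):
        lab = np.ones((n, n), np.uint8)
        lab[:, n // 2:] = 2
        return lab

    def test_large_exposure_means_converge_to_rates(self):
        cfg = dataclasses.replace(NATIVE_CUTICLE_EDS, exposure=200.0, seed=1)
        ms = make_eds_phantom(self._labels(96), {1: "pg", 2: "pm"}, cfg)
        for el in ("N", "S"):
            for code, name in ((1, "pg"), (2, "pm")):
                want = (cfg.rates[name][el] + cfg.background_rate) * cfg.exposure
                got = ms.maps[el][ms.labels == code].mean()
                assert abs(got - want) / want < 0.01

    def test_poisson_variance_matches_mean(self):
        cfg = dataclasses.replace(NATIVE_CUTICLE_EDS, seed=2)
        ms = make_eds_phantom(self._labels(128), {1: "pg", 2: "pm"}, cfg)
        vals = ms.maps["S"][ms.labels == 2].astype(float)
        mean, var = vals.mean(), vals.var()
        # sampling error of the variance ~ sqrt(2/n) relative
        assert abs(var - mean) / mean < 5.0 * np.sqrt(2.0 / vals.size) + 0.02

    def test_iron_absent_from_proto_granule(self):
        cfg = dataclasses.replace(NATIVE_CUTICLE_EDS, seed=3)
        ms = make_eds_phantom(self._labels(128), {1: "pg", 2: "pm"}, cfg)
        fe_pg = ms.maps["Fe"][ms.labels == 1].mean()
        bg = cfg.background_rate * cfg.exposure
        assert abs(fe_pg - bg) < 3.0 * np.sqrt(bg / (ms.labels == 1).sum())

    def test_vesicle_preset_has_no_transition_metals(self):
        for ph in ("pg", "pm", "cp"):
            assert VESICLE_GLAND_EDS.rates[ph]["Fe"] == 0.0
            assert VESICLE_GLAND_EDS.rates[ph]["V"] == 0.0

    def test_undefined_phase_rate_rejected(self):
        cfg = CompositionConfig(rates={"pg": {"S": 10.0}}, seed=0)
        with pytest.raises(ValueError, match="rates"):
            make_eds_phantom(self._labels(), {1: "pg", 2: "pm"}, cfg)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset("no-such-preset")
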