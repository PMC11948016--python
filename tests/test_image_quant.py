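"""Segmentation chain and per-feature metrics against closed-form oracles."""

import numpy as np
import pytest

from helpers import HIGH_SNR, SPARSE_PARAMS, measured_truth_table, quantify_scene
from lipoclust import image_quant as iq
from lipoclust import synthetic_data as sd


def _frame(raster, **kw):
    return iq.ImageFrame(raster=np.asarray(raster, float), **kw)


class TestPreprocessLiposome:
    def test_constant_raster_flattens_to_zero(self):
        out = iq.preprocess_liposome_channel(_frame(np.full((64, 64), 7.0)),
                                             iq.PreprocessParams())
        assert np.allclose(out.raster, 0.0)

    def test_single_pixel_peak_location_and_gaussian_attenuation(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1000.0
        params = iq.PreprocessParams(tophat_radius=5, gaussian_sigma=1.0)
        out = iq.preprocess_liposome_channel(_frame(img), params).raster
        assert np.unravel_index(out.argmax(), out.shape) == (32, 32)
        # Gaussian smoothing preserves the integral and attenuates the
        # peak by the kernel's central mass, 1/(2 pi sigma^2) for sigma=1
        assert out.sum() == pytest.approx(1000.0, rel=1e-6)
        assert out[32, 32] == pytest.approx(1000.0 / (2 * np.pi), rel=0.05)

    def test_slow_ramp_background_is_removed(self):
        rng = np.random.default_rng(0)
        spot = np.zeros((96, 96))
        spot[48, 48] = 500.0
        ramp = np.linspace(0, 30, 96)[None, :] * np.ones((96, 96))
        params = iq.PreprocessParams(tophat_radius=5, gaussian_sigma=1.0)
        a = iq.preprocess_liposome_channel(_frame(spot), params).raster
        b = iq.preprocess_liposome_channel(_frame(spot + ramp), params).raster
        assert np.max(np.abs(a - b)) < 0.05 * a.max()

    def test_raster_smaller_than_footprint_rejected(self):
        with pytest.raises(ValueError):
            iq.preprocess_liposome_channel(_frame(np.zeros((8, 8))),
                                           iq.PreprocessParams(tophat_radius=5))


class TestPreprocessRna:
    def test_constant_raster_flattens(self):
        out = iq.preprocess_rna_channel(_frame(np.full((64, 64), 500.0)),
                                        iq.PreprocessParams())
        assert np.max(np.abs(out.raster)) < 1.0

    def test_offset_invariance_of_spot_integral(self):
        scene = sd.scene_from_sizes([1], field_shape=(96, 96),
                                    flux_liposome=0.0, flux_rna=5000.0, seed=0)
        params = iq.PreprocessParams()
        f0 = sd.render_frame(scene, "rna", sd.NoiseModel.noiseless(background=0.0))
        f500 = sd.render_frame(scene, "rna", sd.NoiseModel.noiseless(background=500.0))
        a = iq.preprocess_rna_channel(f0, params).raster.sum()
        b = iq.preprocess_rna_channel(f500, params).raster.sum()
        assert b == pytest.approx(a, rel=0.02)

    def test_output_non_negative(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (64, 64))
        out = iq.preprocess_rna_channel(_frame(img), iq.PreprocessParams())
        assert np.all(out.raster >= 0.0)


class TestSegment:
    def test_blank_frame_yields_no_features(self):
        labels = iq.segment(_frame(np.zeros((64, 64))), iq.PreprocessParams())
        assert labels.max() == 0

    def test_well_separated_spots_resolve(self):
        scene = sd.scene_from_sizes([1, 1, 1], field_shape=(256, 256),
                                    flux_liposome=20000, seed=2)
        feats, _ = quantify_scene(scene, seed=0)
        assert len(feats) == 3

    def test_nearby_spots_merge(self):
        # two PSF-width-separated spots form one connected component
        sigma_px = 0.3 / 0.325
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[:64, :64]
        for c0 in (32.0, 32.0 + sigma_px):
            img += 1000 * np.exp(-((rr - 32) ** 2 + (cc - c0) ** 2)
                                 / (2 * sigma_px ** 2))
        labels = iq.segment(_frame(img), iq.PreprocessParams())
        assert labels.max() == 1


class TestMeasureFeature:
    def test_single_pixel_rg_is_zero(self):
        img = np.zeros((9, 9))
        img[4, 4] = 10.0
        rec = iq.measure_feature((img > 0).astype(int), _frame(img), 1)
        assert rec.rg_um == 0.0
        assert rec.circularity == 1.0

    def test_two_equal_pixels_rg_is_half_distance(self):
        img = np.zeros((9, 9))
        img[4, 2] = 5.0
        img[4, 6] = 5.0
        rec = iq.measure_feature((img > 0).astype(int),
                                 _frame(img, pixel_size=0.5), 1)
        assert rec.rg_um == pytest.approx(0.5 * 4 / 2, rel=1e-12)

    def test_uniform_disk_rg_approaches_R_over_sqrt2(self):
        R = 20
        rr, cc = np.mgrid[:101, :101]
        disk = (((rr - 50) ** 2 + (cc - 50) ** 2) <= R * R).astype(float) * 100
        rec = iq.measure_feature((disk > 0).astype(int),
                                 _frame(disk, pixel_size=1.0), 1)
        assert rec.rg_um == pytest.approx(R / np.sqrt(2), rel=0.03)
        assert rec.circularity >= 0.85

    def test_zero_intensity_feature_flagged(self):
        img = np.zeros((9, 9))
        labels = np.zeros((9, 9), int)
        labels[3:5, 3:5] = 1
        rec = iq.measure_feature(labels, _frame(img), 1)
        assert not rec.valid
        assert np.isnan(rec.rg_um)

    def test_intensity_scale_invariance(self):
        scene = sd.scene_from_sizes([1, 4], field_shape=(256, 256),
                                    flux_liposome=10000, seed=3)
        params = iq.PreprocessParams()
        frame = sd.render_frame(scene, "liposome", sd.NoiseModel.noiseless())
        for c in (1.0, 7.0):
            scaled = frame.with_raster(c * frame.raster)
            filt = iq.preprocess_liposome_channel(scaled, params)
            labels = iq.segment(filt, params)
            feats = iq.measure_all(labels, scaled)
            if c == 1.0:
                ref = feats
                ref_labels = labels
            else:
                assert np.array_equal(labels, ref_labels)
                for fa, fb in zip(ref, feats):
                    assert fb.rg_um == pytest.approx(fa.rg_um, rel=1e-9)
                    assert fb.total_intensity == pytest.approx(
                        c * fa.total_intensity, rel=1e-9)


class TestParticlesPerCluster:
    def test_monomer_intensity_maps_to_one(self):
        assert iq.particles_per_cluster(350.0, 350.0) == pytest.approx(1.0)

    def test_estimator_is_ratio_of_intensities(self):
        # k_hat = cluster intensity / mean single-liposome intensity
        assert iq.particles_per_cluster(5 * 350.0, 350.0) == pytest.approx(5.0)

    def test_integerized_variant_floors_at_one(self):
        assert iq.particles_per_cluster(10.0, 350.0, integer=True) == 1

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            iq.particles_per_cluster(10.0, 0.0)

    def test_recovery_on_rendered_clusters(self):
        table = measured_truth_table(
            [[1, 1, 2, 3, 4, 5], [1, 1, 6, 7, 8, 10]], "compact", seed0=5,
            field=(448, 448))
        mono = table.loc[table["k"] == 1, "total_intensity"].mean()
        k_hat = table["total_intensity"] / mono
        rel = np.abs(k_hat - table["k"]) / table["k"]
        assert np.median(rel) <= 0.15


class TestFitFractalDimension:
    def test_exact_square_law(self):
        rg = np.linspace(1.0, 10.0, 20)
        fit = iq.fit_fractal_dimension(rg, rg ** 2)
        assert fit.d_f == pytest.approx(2.0, abs=1e-12)
        assert fit.monomer_scale == pytest.approx(1.0, rel=1e-9)

    def test_insufficient_dynamic_range_diagnosed(self):
        rg = np.linspace(1.0, 2.0, 20)
        with pytest.raises(ValueError, match="dynamic range"):
            iq.fit_fractal_dimension(rg, rg ** 2)

    def test_rendered_chains_scale_linearly(self):
        sizes = [[1, 1] + list(range(2, 13, 2)), list(range(12, 31, 4))]
        table = measured_truth_table(sizes, "chain", seed0=6)
        mono = table.loc[table["k"] == 1, "total_intensity"].mean()
        fit = iq.fit_fractal_dimension(table["rg_um"],
                                       table["total_intensity"] / mono,
                                       kmin=1.5, psf_sigma_um=0.3)
        assert 0.9 <= fit.d_f <= 1.2

    def test_rendered_disks_scale_quadratically(self):
        sizes = [[1, 1, 8, 16, 32, 64], [1, 8, 16, 32, 64, 120, 250]]
        table = measured_truth_table(sizes, "compact", seed0=7)
        mono = table.loc[table["k"] == 1, "total_intensity"].mean()
        fit = iq.fit_fractal_dimension(table["rg_um"],
                                       table["total_intensity"] / mono,
                                       kmin=5, psf_sigma_um=0.3)
        assert 1.8 <= fit.d_f <= 2.1


class TestRgAccuracyInvariant:
    def test_measured_rg_matches_psf_broadened_truth(self):
        # PSF adds sigma^2 per axis: rg_meas^2 ~ rg_true^2 + 2 sigma^2
        table = measured_truth_table([[1, 2, 4, 8, 16, 32]], "fractal", seed0=8)
        pred = np.sqrt(table["rg_true_um"] ** 2 + 2 * 0.3 ** 2)
        tol = np.maximum(0.05 * pred, 0.325)
        assert np.all(np.abs(table["rg_um"] - pred) <= tol)


class TestCircularity:
    def test_disks_round_chains_elongated(self):
        # default (Otsu) masks: tight outlines for isolated bright objects
        params = iq.PreprocessParams()
        disks = measured_truth_table([[40, 60]], "compact", seed0=9,
                                     params=params)
        chains = measured_truth_table([[20, 20]], "chain", seed0=10,
                                      params=params)
        assert (disks["circularity"] >= 0.85).all()
        assert (chains["circularity"] <= 0.5).all()


class TestColocalization:
    def _two_level(self, seed, shape=(64, 64)):
        # flat-topped objects on zero background: all signal intensity
        # sits above any between-modes threshold
        rng = np.random.default_rng(seed)
        img = np.zeros(shape)
        for _ in range(4):
            r, c = rng.integers(4, shape[0] - 12, size=2)
            img[r:r + 6, c:c + 6] = 100.0
        return _frame(img)

    def test_identical_channels_fully_colocalize(self):
        a = self._two_level(0)
        res = iq.colocalization(a, a)
        assert res.pearson == pytest.approx(1.0, abs=1e-12)
        assert res.manders_a == pytest.approx(1.0, abs=1e-9)
        assert res.manders_b == pytest.approx(1.0, abs=1e-9)

    def test_inverted_channel_anticorrelates(self):
        a = self._two_level(1)
        b = a.with_raster(a.raster.max() - a.raster)
        res = iq.colocalization(a, b)
        assert res.pearson == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = _frame(rng.poisson(100, (256, 256)).astype(float))
        b = _frame(rng.poisson(100, (256, 256)).astype(float))
        res = iq.colocalization(a, b)
        assert abs(res.pearson) < 0.05

    def test_constant_channel_flagged(self):
        a = self._two_level(3)
        b = a.with_raster(np.full_like(a.raster, 5.0))
        res = iq.colocalization(a, b)
        assert res.flagged
        assert np.isnan(res.pearson)


class TestQuantifyTimeseries:
    def test_blank_frame_summary(self):
        frame = _frame(np.zeros((64, 64)))
        features, summary = iq.quantify_timeseries([frame])
        assert features.empty
        assert summary.loc[0, "n_features"] == 0

    def test_summaries_recompute_exactly_from_feature_table(self):
        scene = sd.scene_from_sizes([1, 2, 4, 8], field_shape=(256, 256),
                                    flux_liposome=20000, seed=4)
        frame = sd.render_frame(scene, "liposome", HIGH_SNR, seed=0)
        features, summary = iq.quantify_timeseries([frame], params=SPARSE_PARAMS)
        redo = iq.summarize_features(features,
                                     [(frame.frame_index, frame.timestamp)])
        assert redo.equals(summary)

    def test_feature_count_tracks_truth_at_high_snr(self):
        scene = sd.scene_from_sizes([1] * 6 + [2, 3, 4, 5], morphology="compact",
                                    field_shape=(448, 448), flux_liposome=20000,
                                    seed=5)
        frame = sd.render_frame(scene, "liposome", HIGH_SNR, seed=1)
        features, summary = iq.quantify_timeseries([frame], params=SPARSE_PARAMS)
        n_true = len(scene.clusters)
        assert abs(summary.loc[0, "n_features"] - n_true) <= 0.1 * n_true

    def test_co_channel_intensity_measured_under_liposome_mask(self):
        scene = sd.scene_from_sizes([2, 3], field_shape=(256, 256),
                                    flux_liposome=20000, flux_rna=5000,
                                    coloc_fraction=1.0, seed=6)
        lipo = sd.render_frame(scene, "liposome", HIGH_SNR, seed=0)
        rna = sd.render_frame(scene, "rna", HIGH_SNR, seed=1)
        features, _ = iq.quantify_timeseries([lipo], params=SPARSE_PARAMS,
                                             rna_frames=[rna])
        assert (features["co_channel_intensity"] > 0).all()
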