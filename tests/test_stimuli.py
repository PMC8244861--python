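import numpy as np
import pytest

from colorform import color_math as cm
from colorform import stimuli as st
from colorform.errors import DegenerateInputError, InputDomainError


class TestBackgroundMask:
    def test_black_square_on_white(self):
        raster = np.full((20, 20, 3), 255, dtype=np.uint8)
        raster[5:10, 5:10] = 0
        mask = st.background_mask(raster)
        expected = np.zeros((20, 20), dtype=bool)
        expected[5:10, 5:10] = True
        assert np.array_equal(mask, expected)

    def test_threshold_rule(self):
        raster = np.array([[[252, 251, 255], [249, 255, 255]]], dtype=np.uint8)
        mask = st.background_mask(raster, threshold=250)
        assert not mask[0, 0]  # all channels >= 250 -> background
        assert mask[0, 1]  # one channel below threshold -> object

    def test_recovers_known_mask_under_speckle(self, rng):
        truth = np.zeros((40, 40), dtype=bool)
        truth[10:30, 8:25] = True
        raster = np.full((40, 40, 3), 255, dtype=np.int64)
        # simulated compression speckle: +-3 around white in the background
        raster[~truth] = 255 - rng.integers(0, 4, size=((~truth).sum(), 3))
        raster[truth] = rng.integers(0, 240, size=(truth.sum(), 3))
        assert np.array_equal(st.background_mask(raster.astype(np.uint8)), truth)

    def test_all_background_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.background_mask(np.full((5, 5, 3), 255, dtype=np.uint8))


class TestCalibrateAndRecolor:
    def test_uniform_disc_closed_form(self, disc_source, calibration):
        """A uniform gray disc must calibrate to the 12 rotations of the
        single LUV point (target_L, target_sat at each hue angle)."""
        images = st.calibrate_and_recolor(disc_source, calibration)
        assert len(images) == 12
        for i, im in enumerate(images):
            masked = im.raster[disc_source.mask]
            assert len(np.unique(masked, axis=0)) == 1  # still uniform
            theta = np.deg2rad(30.0 * i)
            expected_luv = np.array(
                [60.0, 40.0 * np.cos(theta), 40.0 * np.sin(theta)]
            )
            expected_rgb = cm.luv_to_srgb(expected_luv)
            assert np.array_equal(masked[0].astype(float), expected_rgb)

    def test_masked_means_hit_targets(self, disc_source, calibration):
        for im in st.calibrate_and_recolor(disc_source, calibration):
            audit = st.audit_calibration(im)
            assert audit["mean_lum"] == pytest.approx(60.0, abs=1.0)
            assert audit["mean_sat"] == pytest.approx(40.0, abs=1.0)

    def test_opposite_hues_antiparallel(self, disc_source, calibration):
        images = st.calibrate_and_recolor(disc_source, calibration)
        uv0 = cm.srgb_to_luv(images[0].raster[disc_source.mask].astype(float))[:, 1:]
        uv6 = cm.srgb_to_luv(images[6].raster[disc_source.mask].astype(float))[:, 1:]
        # 180 degree rotation: anti-parallel up to quantization
        assert np.allclose(uv0, -uv6, atol=1.5)

    def test_background_untouched_and_L_stable(self, disc_source, calibration):
        images = st.calibrate_and_recolor(disc_source, calibration)
        lums = []
        for im in images:
            assert np.all(im.raster[~disc_source.mask] == 255)
            lums.append(st.audit_calibration(im)["mean_lum"])
        assert max(lums) - min(lums) <= 1.0

    def test_textured_object_preserves_pattern(self, rng, calibration):
        """Relative luminance ordering within the object survives
        calibration (up to the single shrink factor)."""
        raster = np.full((30, 30, 3), 255, dtype=np.uint8)
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        raster[mask] = rng.integers(40, 200, size=(mask.sum(), 1))
        src = st.SourceObjectImage("tex", raster, mask)
        im = st.calibrate_and_recolor(src, calibration, n_hues=1)[0]
        before = cm.srgb_to_luv(raster[mask].astype(float))[:, 0]
        after = cm.srgb_to_luv(im.raster[mask].astype(float))[:, 0]
        assert np.corrcoef(before, after)[0, 1] > 0.99

    def test_synthetic_hsv_space(self, disc_source):
        target = st.CalibrationTarget("synthetic_hsv", 120.0, 40.0)
        images = st.calibrate_and_recolor(disc_source, target)
        for im in images:
            audit = st.audit_calibration(im)
            assert audit["mean_lum"] == pytest.approx(120.0, abs=1.0)
            assert audit["mean_sat"] == pytest.approx(40.0, abs=1.0)


class TestSilhouetteAndGrayscale:
    def test_silhouette_single_fill(self, disc_source, calibration):
        im = st.make_silhouette(disc_source, 3, calibration)
        masked = im.raster[disc_source.mask]
        assert len(np.unique(masked, axis=0)) == 1
        assert np.all(im.raster[~disc_source.mask] == 255)

    def test_fill_independent_of_object(self, disc_source, rng, calibration):
        raster = np.full((16, 16, 3), 255, dtype=np.uint8)
        raster[2:9, 3:12] = rng.integers(0, 200, size=(7, 9, 3))
        other = st.SourceObjectImage("blob", raster)
        a = st.make_silhouette(disc_source, 5, calibration)
        b = st.make_silhouette(other, 5, calibration)
        assert np.array_equal(
            a.raster[disc_source.mask][0], b.raster[other.mask][0]
        )

    def test_fill_matches_disc_closed_form(self, disc_source, calibration):
        im = st.calibrate_and_recolor(disc_source, calibration)[4]
        sil = st.make_silhouette(disc_source, 4, calibration)
        assert np.array_equal(
            im.raster[disc_source.mask][0], sil.raster[disc_source.mask][0]
        )

    def test_grayscale_achromatic(self, disc_source, calibration):
        im = st.make_grayscale(disc_source, calibration)
        pixels = im.raster[disc_source.mask].astype(float)
        assert np.all(cm.chroma(cm.srgb_to_luv(pixels)) < 1.0)
        assert np.abs(np.diff(pixels, axis=-1)).max() <= 1  # R=G=B up to a step
        assert st.audit_calibration(im)["mean_lum"] == pytest.approx(60.0, abs=1.0)


class TestSyntheticHSVTargets:
    def test_derived_from_reddest_cieluv_hue(self, calibration):
        derived = st.synthetic_hsv_targets_from_cieluv(calibration)
        assert derived.space == "synthetic_hsv"
        fills = [st.silhouette_fill_color(calibration, h) for h in range(12)]
        reddest = max(fills, key=lambda rgb: rgb[0])
        assert derived.mean_luminance == pytest.approx(reddest.mean())
        # the derived targets must themselves be composable at every hue
        for h in range(12):
            st.silhouette_fill_color(derived, h)


class TestBars:
    def test_default_orientations(self):
        assert np.allclose(
            st.default_bar_orientations(), np.arange(0, 180, 15.0)
        )

    def test_grid_size_and_manifest(self, bar_set):
        assert len(bar_set) == 144
        m = bar_set.manifest
        assert len(m) == 144
        assert m.groupby("object_id").size().eq(12).all()

    def test_axis_aligned_symmetry(self):
        m0 = st.bar_mask(st.BarSpec(0.0))
        m90 = st.bar_mask(st.BarSpec(90.0))
        assert m0.sum() == m90.sum()
        assert np.array_equal(m90, m0.T)

    def test_area_equated_within_1pct(self):
        counts = [st.bar_mask(st.BarSpec(o)).sum() for o in st.default_bar_orientations()]
        base = counts[0]
        assert all(abs(c - base) / base < 0.01 for c in counts)
        # discretization stays close to the analytic area
        assert base == pytest.approx(300 * 60, rel=0.02)

    def test_bar_outside_canvas_rejected(self):
        with pytest.raises(InputDomainError):
            st.BarSpec(0.0, length_px=400, width_px=60, canvas_px=400)

    def test_deterministic(self, calibration):
        a = st.make_bars(calibration, template=st.BarSpec(0.0, 96, 20, 128))
        b = st.make_bars(calibration, template=st.BarSpec(0.0, 96, 20, 128))
        assert all(
            np.array_equal(x.raster, y.raster) for x, y in zip(a.images, b.images)
        )


class TestSubsetSelection:
    def test_k_equals_n_identity(self):
        m = np.eye(4) + 0.1
        assert st.select_dissimilar_subset(m, 4) == [0, 1, 2, 3]

    def test_drops_the_similar_one_and_matches_exhaustive(self):
        m = np.array(
            [
                [1.0, 0.9, 0.9, 0.9],
                [0.9, 1.0, 0.1, 0.2],
                [0.9, 0.1, 1.0, 0.15],
                [0.9, 0.2, 0.15, 1.0],
            ]
        )
        greedy = st.select_dissimilar_subset(m, 3)
        exhaustive = st.select_dissimilar_subset(m, 3, method="exhaustive")
        assert 0 not in greedy
        assert sorted(greedy) == sorted(exhaustive)

    def test_never_increases_mean_similarity(self, rng):
        for _ in range(20):
            x = rng.normal(size=(10, 30))
            m = np.corrcoef(x)
            sub = st.select_dissimilar_subset(m, 5)
            assert st.mean_pairwise(m, sub) <= st.mean_pairwise(m) + 1e-12

    def test_near_exhaustive_small_n(self):
        """Greedy elimination is a heuristic: it must stay within a small
        optimality gap of brute force on random 6x6 RSMs and match it
        exactly on most draws."""
        exact = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=(6, 12))
            m = np.corrcoef(x)
            g = st.mean_pairwise(m, st.select_dissimilar_subset(m, 3))
            e = st.mean_pairwise(m, st.select_dissimilar_subset(m, 3, method="exhaustive"))
            assert g <= e + 0.1
            exact += g == pytest.approx(e, abs=1e-12)
        assert exact >= 5

    def test_k_too_small_rejected(self):
        with pytest.raises(InputDomainError):
            st.select_dissimilar_subset(np.eye(4), 1)


class TestStimulusSetIO:
    def test_write_and_audit_from_disk(self, tmp_path, calibration):
        from PIL import Image

        sset = st.make_bars(
            calibration, n_orientations=2, n_hues=3,
            template=st.BarSpec(0.0, 60, 14, 80),
        )
        manifest = sset.write(tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        for _, row in manifest.iterrows():
            raster = np.asarray(Image.open(tmp_path / row["path"]))
            mask = st.background_mask(raster)
            luv = cm.srgb_to_luv(raster[mask].astype(float))
            assert luv[:, 0].mean() == pytest.approx(row["target_mean_lum"], abs=1.0)
            assert cm.chroma(luv).mean() == pytest.approx(row["target_mean_sat"], abs=1.0)
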