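import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from colorform import color_math as cm
from colorform.errors import DegenerateInputError, GamutError, InputDomainError


class TestSrgbLuv:
    def test_white_is_achromatic_L100(self):
        luv = cm.srgb_to_luv([255, 255, 255])
        assert luv[0] == pytest.approx(100.0, abs=1e-9)
        assert abs(luv[1]) < 1e-6 and abs(luv[2]) < 1e-6

    def test_grays_are_achromatic(self):
        for g in (0, 1, 64, 128, 200, 254):
            luv = cm.srgb_to_luv([g, g, g])
            assert cm.chroma(luv) < 1e-6

    def test_black_round_trip(self):
        assert np.allclose(cm.luv_to_srgb([0.0, 0.0, 0.0]), [0, 0, 0])
        assert np.allclose(cm.luv_to_srgb([100.0, 0.0, 0.0]), [255, 255, 255])

    def test_round_trip_10000_random_pixels(self, rng):
        rgb = rng.integers(0, 256, size=(10000, 3))
        back = cm.luv_to_srgb(cm.srgb_to_luv(rgb))
        assert np.abs(back - rgb).max() <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(InputDomainError):
            cm.srgb_to_luv([256, 0, 0])
        with pytest.raises(InputDomainError):
            cm.srgb_to_luv([-1, 0, 0])

    def test_matches_skimage_oracle(self, rng):
        # independent reference implementation (different white-point rounding)
        from skimage import color as skcolor

        rgb = rng.integers(0, 256, size=(500, 1, 3))
        ours = cm.srgb_to_luv(rgb)
        theirs = skcolor.rgb2luv(rgb / 255.0)
        assert np.allclose(ours, theirs, atol=0.2)

    def test_gamut_clip_count(self):
        # a wildly out-of-gamut chroma at low L must be counted
        luv = np.array([[10.0, 300.0, 0.0], [50.0, 0.0, 0.0]])
        _, n = cm.luv_to_srgb(luv, return_clip_count=True)
        assert n == 1

    def test_deterministic(self, rng):
        rgb = rng.integers(0, 256, size=(64, 64, 3))
        a = cm.srgb_to_luv(rgb)
        b = cm.srgb_to_luv(rgb)
        assert np.array_equal(a, b)


class TestChromaRotation:
    def test_chroma_values(self):
        assert cm.chroma(0.0, 0.0) == 0.0
        assert cm.chroma(3.0, 4.0) == pytest.approx(5.0)

    def test_rotation_zero_is_identity(self, rng):
        luv = rng.normal(50, 20, size=(8, 8, 3))
        assert np.allclose(cm.rotate_hue(luv, 0.0), luv)

    def test_rotation_90(self):
        out = cm.rotate_hue(np.array([50.0, 13.0, 0.0]), 90.0)
        assert np.allclose(out, [50.0, 0.0, 13.0], atol=1e-9)

    def test_rotation_preserves_chroma_and_L(self, rng):
        luv = rng.normal(0, 30, size=(100, 3)) + [50, 0, 0]
        for angle in (17.3, 90.0, 222.2):
            rot = cm.rotate_hue(luv, angle)
            assert np.allclose(cm.chroma(rot), cm.chroma(luv), atol=1e-9)
            assert np.array_equal(rot[..., 0], luv[..., 0])

    def test_twelve_rotations_compose_to_identity(self, rng):
        luv = rng.normal(50, 20, size=(16, 3))
        out = luv.copy()
        for _ in range(12):
            out = cm.rotate_hue(out, 30.0)
        assert np.allclose(out, luv, atol=1e-6)

    @given(angle=hst.floats(0, 360, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_rotation_chroma_invariant_property(self, angle):
        luv = np.array([40.0, 12.5, -7.25])
        assert cm.chroma(cm.rotate_hue(luv, angle)) == pytest.approx(
            cm.chroma(luv), abs=1e-9
        )


class TestDesaturate:
    def test_chroma_zero_everywhere(self, rng):
        luv = rng.normal(0, 40, size=(10, 10, 3)) + [50, 0, 0]
        out = cm.desaturate(luv)
        assert np.all(cm.chroma(out) == 0.0)

    def test_L_bitwise_preserved(self, rng):
        luv = rng.normal(0, 40, size=(10, 10, 3)) + [50, 0, 0]
        out = cm.desaturate(luv)
        assert np.array_equal(out[..., 0], luv[..., 0])

    def test_idempotent(self, rng):
        luv = rng.normal(0, 40, size=(5, 3))
        once = cm.desaturate(luv)
        assert np.array_equal(cm.desaturate(once), once)


class TestEquateChannelMean:
    def test_pure_shift(self):
        out, s = cm.equate_channel_mean(np.array([10.0, 20.0, 30.0]), 25.0, (0, 100))
        assert np.allclose(out, [15, 25, 35])
        assert s == 1.0

    def test_identity_when_already_at_target(self):
        vals = np.array([10.0, 20.0, 30.0])
        out, s = cm.equate_channel_mean(vals, 20.0, (0, 100))
        assert np.allclose(out, vals)
        assert s == 1.0

    def test_shrink_matches_bisection_oracle(self):
        vals = np.array([90.0, 100.0])
        out, s = cm.equate_channel_mean(vals, 98.0, (0, 100))
        assert out.mean() == pytest.approx(98.0, abs=1e-9)
        assert out.max() <= 100.0

        # independent bisection on the shrink factor
        dev = vals - vals.mean()
        lo_s, hi_s = 0.0, 1.0
        for _ in range(60):
            mid = (lo_s + hi_s) / 2
            cand = 98.0 + mid * dev
            if cand.min() >= 0.0 and cand.max() <= 100.0:
                lo_s = mid
            else:
                hi_s = mid
        assert s == pytest.approx(lo_s, abs=1e-6)
        assert np.allclose(out, 98.0 + lo_s * dev, atol=1e-6)

    def test_mask_respected(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, False, False])
        out, _ = cm.equate_channel_mean(vals, 10.0, (0, 100), mask=mask)
        assert np.allclose(out[~mask], vals[~mask])
        assert out[mask].mean() == pytest.approx(10.0, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            cm.equate_channel_mean(np.array([1.0]), 5.0, (0, 10), mask=np.array([False]))

    def test_target_outside_bounds_rejected(self):
        with pytest.raises(InputDomainError):
            cm.equate_channel_mean(np.array([1.0, 2.0]), 200.0, (0, 100))

    @given(
        target=hst.floats(5, 95),
        scale=hst.floats(0.1, 80),
    )
    @settings(max_examples=100, deadline=None)
    def test_property_mean_and_bounds(self, target, scale):
        vals = np.array([10.0, 30.0, 50.0, 80.0]) * scale / 80.0
        out, s = cm.equate_channel_mean(vals, target, (0.0, 100.0))
        assert out.mean() == pytest.approx(target, abs=1e-9)
        assert out.min() >= -1e-9 and out.max() <= 100.0 + 1e-9
        assert 0.0 <= s <= 1.0


class TestSyntheticHSV:
    def test_gray_decomposition(self):
        for g in (0, 100, 255):
            c = cm.synthetic_hsv_decompose(np.array([g, g, g], dtype=float))
            assert c.lum == g and c.sat == 0.0 and not c.hue_defined

    def test_lum_is_channel_mean(self):
        c = cm.synthetic_hsv_decompose(np.array([60.0, 120.0, 180.0]))
        assert c.lum == pytest.approx(120.0)

    def test_round_trip_grid(self):
        hues = np.arange(0, 360, 17.0)
        for lum in (60.0, 128.0, 180.0):
            max_sat = cm.synthetic_hsv_max_sat(lum)
            for sat in (0.5, 10.0, 0.9 * max_sat):
                for hue in hues:
                    rgb = cm.synthetic_hsv_compose(lum, sat, hue)
                    c = cm.synthetic_hsv_decompose(rgb)
                    assert c.lum == pytest.approx(lum, abs=1e-6)
                    assert c.sat == pytest.approx(sat, abs=1e-6)
                    wrapped = (c.hue - hue + 180.0) % 360.0 - 180.0
                    assert wrapped == pytest.approx(0.0, abs=1e-6)

    def test_compose_sat_zero_is_gray(self):
        assert np.allclose(cm.synthetic_hsv_compose(77.0, 0.0, 0.0), [77, 77, 77])

    def test_hue_0_120_240_are_cyclic_permutations(self):
        # cube symmetry about the gray axis
        lum, sat = 100.0, 40.0
        r0 = cm.synthetic_hsv_compose(lum, sat, 0.0)
        r120 = cm.synthetic_hsv_compose(lum, sat, 120.0)
        r240 = cm.synthetic_hsv_compose(lum, sat, 240.0)
        assert np.allclose(np.roll(r0, 1), r120, atol=1e-9)
        assert np.allclose(np.roll(r0, 2), r240, atol=1e-9)

    def test_hue0_maximizes_R(self):
        lum, sat = 100.0, 40.0
        r_at = [
            cm.synthetic_hsv_compose(lum, sat, h)[0] for h in np.arange(0, 360, 5.0)
        ]
        assert np.argmax(r_at) == 0

    def test_mean_constraint_exact(self, rng):
        for _ in range(50):
            lum = rng.uniform(20, 230)
            sat = rng.uniform(0, cm.synthetic_hsv_max_sat(lum))
            hue = rng.uniform(0, 360)
            rgb = cm.synthetic_hsv_compose(lum, sat, hue)
            assert abs(rgb.mean() - lum) < 1e-9

    def test_gamut_error_reports_max_sat(self):
        with pytest.raises(GamutError) as exc:
            cm.synthetic_hsv_compose(10.0, 50.0, 0.0)
        assert exc.value.max_admissible == pytest.approx(
            cm.synthetic_hsv_max_sat(10.0)
        )
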