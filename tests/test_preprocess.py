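"""Resampling, registration, masking and Amide I band-ratio normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specseg.preprocess import (
    BandImage,
    ChannelStats,
    DegenerateInputError,
    ParameterError,
    assemble_stack,
    normalize_to_amide1,
    read_band_tiff,
    register_translation,
    resample,
    tissue_mask,
    write_band_tiff,
)


# ---------------------------------------------------------------------------
# resample
# ---------------------------------------------------------------------------

class TestResample:
    def test_identity_when_pitch_unchanged(self, rng):
        img = rng.random((17, 23)).astype(np.float32)
        out = resample(img, 2.0, 2.0, mode="intensity")
        assert np.array_equal(out, img)

    def test_upsample_2um_to_1um_shape_and_constancy(self):
        img = np.full((40, 60), 3.25, dtype=np.float32)
        out = resample(img, 2.0, 1.0, mode="intensity")
        assert out.shape == (80, 120)
        assert np.allclose(out, 3.25)

    def test_label_downsample_matches_bruteforce_index_map(self, rng):
        lab = rng.choice([0, 1, 3], size=(30, 34)).astype(np.uint8)
        out = resample(lab, 1.0, 2.0, mode="label")
        assert set(np.unique(out)) <= {0, 1, 3}
        # brute-force nearest-neighbor oracle: output center (i+0.5)*2 um,
        # nearest source index round((i+0.5)*2 - 0.5)
        h, w = out.shape
        expect = np.empty_like(out)
        for i in range(h):
            for j in range(w):
                si = int(np.clip(np.round((i + 0.5) * 2.0 - 0.5), 0, lab.shape[0] - 1))
                sj = int(np.clip(np.round((j + 0.5) * 2.0 - 0.5), 0, lab.shape[1] - 1))
                expect[i, j] = lab[si, sj]
        assert np.array_equal(out, expect)

    @settings(max_examples=25, deadline=None)
    @given(
        st.integers(2, 5),
        st.integers(0, 2**31 - 1),
    )
    def test_label_resample_never_invents_values(self, factor, seed):
        r = np.random.default_rng(seed)
        lab = r.choice([0, 2, 3], size=(24, 24)).astype(np.uint8)
        down = resample(lab, 1.0, float(factor), mode="label")
        up = resample(lab, float(factor), 1.0, mode="label")
        assert set(np.unique(down)) <= set(np.unique(lab))
        assert set(np.unique(up)) <= set(np.unique(lab))

    def test_errors(self):
        with pytest.raises(ParameterError):
            resample(np.zeros((4, 4)), -1.0, 1.0)
        with pytest.raises(ParameterError):
            resample(np.zeros((4, 4), dtype=np.float32), 1.0, 2.0, mode="label")


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class TestRegisterTranslation:
    def test_identity(self, rng):
        img = rng.random((64, 64))
        dy, dx, reg = register_translation(img, img)
        assert (dy, dx) == (0, 0)
        assert np.allclose(reg, img)

    def test_recovers_injected_roll_exactly(self, rng):
        fixed = rng.random((96, 96))
        moving = np.roll(fixed, (3, -5), axis=(0, 1))
        dy, dx, reg = register_translation(moving, fixed)
        assert (dy, dx) == (-3, 5)
        # interior agrees exactly after the zero-filled shift
        assert np.array_equal(reg[5:-5, 5:-5], fixed[5:-5, 5:-5])

    @pytest.mark.parametrize("shift", [(7, 0), (0, -9), (-11, 13)])
    def test_recovers_shifts_up_to_quarter_frame(self, rng, shift):
        fixed = rng.random((80, 80))
        moving = np.roll(fixed, shift, axis=(0, 1))
        dy, dx, _ = register_translation(moving, fixed)
        assert (dy, dx) == (-shift[0], -shift[1])

    def test_constant_raster_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            register_translation(np.ones((32, 32)), np.random.default_rng(0).random((32, 32)))


# ---------------------------------------------------------------------------
# tissue mask
# ---------------------------------------------------------------------------

class TestTissueMask:
    def test_mask_area_matches_phantom_tissue(self, small_section):
        from specseg.pipeline import preprocess_section

        _, _, _, mask, lab = preprocess_section(small_section)
        truth_frac = (lab.labels > 0).mean()
        assert abs(mask.mean() - truth_frac) < 0.01

    def test_fixed_threshold_saturated(self):
        img = np.full((16, 16), 0.5)
        mask = tissue_mask(img, method="fixed", threshold=0.1)
        assert mask.all()

    def test_all_zero_otsu_errors(self):
        with pytest.raises(DegenerateInputError):
            tissue_mask(np.zeros((16, 16)))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalizeToAmide1:
    def test_identity_ratio(self):
        a = np.full((8, 8), 0.4)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        res = normalize_to_amide1(a, a, a, mask)
        assert np.allclose(res.r1238[mask], 1.0)
        assert np.all(res.r1238[~mask] == 0.0)

    def test_hand_worked_2x2_case(self):
        a1238 = np.array([[0.2, 0.4], [0.1, 0.0]])
        a1658 = np.full((2, 2), 0.4)
        res = normalize_to_amide1(a1238, a1658, a1658, np.ones((2, 2), bool))
        assert np.allclose(res.r1238, [[0.5, 1.0], [0.25, 0.0]])

    def test_scale_invariance_to_multiplicative_field(self, rng):
        shape = (64, 64)
        mask = np.ones(shape, bool)
        a1238 = 0.2 + rng.random(shape)
        a1546 = 0.2 + rng.random(shape)
        a1658 = 0.2 + rng.random(shape)
        t = np.exp(rng.normal(0, 0.3, shape))  # arbitrary positive field
        base = normalize_to_amide1(a1238, a1546, a1658, mask)
        scaled = normalize_to_amide1(t * a1238, t * a1546, t * a1658, mask)
        assert np.allclose(base.r1238, scaled.r1238, atol=1e-12, rtol=0)
        assert np.allclose(base.r1546, scaled.r1546, atol=1e-12, rtol=0)

    def test_low_amide1_pixels_removed_and_reported(self):
        a1658 = np.full((4, 4), 0.5)
        a1658[0, :2] = 1e-5  # below the division floor
        ones = np.ones((4, 4))
        res = normalize_to_amide1(ones, ones, a1658, np.ones((4, 4), bool))
        assert res.n_floor_removed == 2
        assert not res.mask[0, 0] and not res.mask[0, 1]
        assert np.all(np.isfinite(res.r1238))

    def test_clipping_bounds_ratios(self):
        a = np.full((4, 4), 10.0)
        a1658 = np.full((4, 4), 1.0)
        res = normalize_to_amide1(a, a, a1658, np.ones((4, 4), bool), clip_max=3.0)
        assert res.r1238.max() == 3.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ParameterError):
            normalize_to_amide1(
                np.ones((4, 4)), np.ones((4, 4)), np.ones((4, 5)), np.ones((4, 4), bool)
            )


# ---------------------------------------------------------------------------
# stack assembly and I/O
# ---------------------------------------------------------------------------

class TestAssembleStack:
    def test_constant_channels_standardize_to_zero(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        c = np.full((16, 16), 2.0)
        stack, _ = assemble_stack(c, c, c, mask)
        z = stack.standardized()
        assert np.allclose(z[:, mask], 0.0)

    def test_stored_stats_reused_on_shifted_test_section(self):
        mask = np.ones((32, 32), bool)
        rng = np.random.default_rng(0)
        train = rng.random((32, 32))
        train_stack, _ = assemble_stack(train, train, train, mask)
        stats = train_stack.stats
        shifted = train + 1.0  # test section deliberately offset by +1
        test_stack, _ = assemble_stack(shifted, shifted, shifted, mask, stats=stats)
        z = test_stack.standardized()
        expect = 1.0 / stats.sd
        got = z.mean(axis=(1, 2))
        assert np.allclose(got, expect + (train.mean() - stats.mean) / stats.sd, atol=1e-4)

    def test_grid_mismatch_errors(self):
        with pytest.raises(ParameterError):
            assemble_stack(
                np.ones((4, 4)), np.ones((4, 4)), np.ones((4, 5)), np.ones((4, 4), bool)
            )

    def test_tiff_roundtrip_preserves_bits_and_pixel_size(self, tmp_path, rng):
        img = rng.random((20, 30)).astype(np.float32)
        path = tmp_path / "band.tif"
        write_band_tiff(path, img, pixel_size_um=2.0)
        back, px = read_band_tiff(path)
        assert np.array_equal(back, img)
        assert px == pytest.approx(2.0)

    def test_stats_json_roundtrip(self, tmp_path):
        stats = ChannelStats(mean=np.array([0.1, 0.2, 0.3]), sd=np.array([1.0, 2.0, 3.0]))
        stats.to_json(tmp_path / "stats.json")
        back = ChannelStats.from_json(tmp_path / "stats.json")
        assert np.allclose(back.mean, stats.mean)
        assert np.allclose(back.sd, stats.sd)


def test_band_image_validation():
    with pytest.raises(ParameterError):
        BandImage(np.ones((4, 4)), 1658.0, pixel_size=-2.0)
    with pytest.raises(ParameterError):
        BandImage(np.full((4, 4), np.nan), 1658.0, pixel_size=2.0)
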