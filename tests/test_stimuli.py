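"""Synthetic stimulus generators."""

import numpy as np
import pytest

from inrf.stimuli import (
    DISPLAY_BLACK,
    DISPLAY_WHITE,
    BrightnessDisplayConfig,
    OnOffConfig,
    WhiteStimulusConfig,
    add_bandpass_noise,
    display_circle_centers,
    make_brightness_display,
    make_irradiation_signal,
    make_onoff_stimulus,
    make_white_stimulus,
    white_patch_masks,
)


class TestOnOff:
    def test_center_segment_replaces_background(self):
        s = make_onoff_stimulus(OnOffConfig(bar_width=128, center_value=0.0)).values
        assert np.all(s[224:288] == 0.0)
        assert s[0] == 1.0  # white bar starts the signal

    def test_balanced_bars_have_mean_half(self):
        s = make_onoff_stimulus(OnOffConfig(bar_width=128, center_value=0.5)).values
        assert s.mean() == pytest.approx(0.5, abs=1e-15)

    def test_deterministic(self):
        cfg = OnOffConfig(bar_width=32, center_value=0.3)
        assert np.array_equal(make_onoff_stimulus(cfg).values,
                              make_onoff_stimulus(cfg).values)

    def test_degenerate_bar_width_rejected(self):
        with pytest.raises(ValueError):
            OnOffConfig(bar_width=256)
        with pytest.raises(ValueError):
            OnOffConfig(center_value=1.5)


class TestBrightnessDisplay:
    def test_uniform_with_matching_circles_is_constant(self):
        cfg = BrightnessDisplayConfig(background_kind="uniform",
                                      background_level=37.83,
                                      circle_luminances=(37.83,) * 11)
        img = make_brightness_display(cfg).values
        assert np.all(img == 37.83)

    def test_salt_pepper_limit_fractions(self):
        cfg = BrightnessDisplayConfig(background_kind="salt_pepper",
                                      background_level=0.0)
        img = make_brightness_display(cfg).values
        centers = display_circle_centers(cfg)
        mask = np.zeros(img.shape, bool)
        rows, cols = np.ogrid[:img.shape[0], :img.shape[1]]
        for (r, c) in centers:
            mask |= (rows - r) ** 2 + (cols - c) ** 2 < 32 ** 2
        assert np.all(img[~mask] == DISPLAY_WHITE)

    def test_salt_pepper_mean_near_binomial_expectation(self):
        cfg = BrightnessDisplayConfig(background_kind="salt_pepper",
                                      background_level=0.5, seed=7)
        img = make_brightness_display(cfg).values
        expected = 0.5 * (DISPLAY_BLACK + DISPLAY_WHITE)
        assert img.mean() == pytest.approx(expected, rel=0.01)

    def test_seeded_reproducibility(self):
        cfg = BrightnessDisplayConfig(background_kind="salt_pepper",
                                      background_level=0.3, seed=42)
        assert np.array_equal(make_brightness_display(cfg).values,
                              make_brightness_display(cfg).values)

    def test_layout_and_config_validation(self):
        with pytest.raises(ValueError):
            BrightnessDisplayConfig(circle_luminances=(10.0,) * 10)
        with pytest.raises(ValueError):
            BrightnessDisplayConfig(background_level=100.0)
        with pytest.raises(ValueError):
            display_circle_centers(BrightnessDisplayConfig(gap_px=64))  # 1344 > 1280
        centers = display_circle_centers(BrightnessDisplayConfig())
        assert len(centers) == 11
        assert centers[0][1] - 32 >= 0
        assert centers[-1][1] + 32 <= 1280


class TestWhite:
    def test_patches_share_identical_gray(self):
        cfg = WhiteStimulusConfig()
        img = make_white_stimulus(cfg).values
        a, b = white_patch_masks(cfg)
        assert np.all(img[a] == cfg.test_gray)
        assert np.all(img[b] == cfg.test_gray)
        # the patches sit on opposite bar polarities
        col_a = np.flatnonzero(a.any(axis=0))[0]
        col_b = np.flatnonzero(b.any(axis=0))[0]
        top = img[0]
        assert top[col_a] == 1.0 and top[col_b] == 0.0

    def test_noise_free_and_seeded_determinism(self):
        cfg = WhiteStimulusConfig(noise_center_cpd=3.0, noise_rms=0.1, seed=9)
        assert np.array_equal(make_white_stimulus(cfg).values,
                              make_white_stimulus(cfg).values)

    def test_patch_geometry_validation(self):
        with pytest.raises(ValueError):
            WhiteStimulusConfig(patch_bars=(2, 9))  # outside the canvas
        with pytest.raises(ValueError):
            WhiteStimulusConfig(patch_bars=(1, 2))  # wrong polarities


class TestBandpassNoise:
    def _base(self):
        return make_white_stimulus(WhiteStimulusConfig())

    def test_zero_rms_is_identity(self):
        base = self._base()
        out = add_bandpass_noise(base, 3.0, 0.0, seed=1)
        assert np.array_equal(out.values, base.values)

    def test_mean_and_rms_normalization(self):
        base = self._base()
        out = add_bandpass_noise(base, 3.0, 0.25, seed=3)
        noise = out.values - base.values
        assert abs(noise.mean()) < 1e-6
        assert np.sqrt(np.mean(noise ** 2)) == pytest.approx(0.25, rel=0.02)

    def test_power_concentrates_at_requested_band(self):
        base = self._base()
        f0 = 4.0
        noise = add_bandpass_noise(base, f0, 0.2, seed=5).values - base.values
        spec = np.abs(np.fft.fft2(noise)) ** 2
        ppd = base.pixels_per_degree
        fy = np.fft.fftfreq(noise.shape[0], d=1 / ppd)
        fx = np.fft.fftfreq(noise.shape[1], d=1 / ppd)
        f = np.hypot(fy[:, None], fx[None, :])
        bins = np.geomspace(0.25, 16, 25)
        power = [spec[(f >= lo) & (f < hi)].sum() for lo, hi in zip(bins, bins[1:])]
        peak = np.sqrt(bins[np.argmax(power)] * bins[np.argmax(power) + 1])
        assert abs(np.log2(peak / f0)) < 0.5

    def test_requires_angular_metadata(self):
        from inrf.core import Raster

        with pytest.raises(ValueError):
            add_bandpass_noise(Raster(np.zeros((8, 8))), 3.0, 0.1)


class TestIrradiation:
    def test_step_counts_and_complement(self):
        w = make_irradiation_signal("white_on_black").values
        b = make_irradiation_signal("black_on_white").values
        assert w.size == 1024
        assert w.sum() == 400
        assert np.array_equal(b, 1.0 - w)
        # the step is centered
        assert np.all(w[312:712] == 1.0)

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValueError):
            make_irradiation_signal("sideways")
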