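"""Intensity-profile morphometry: extraction, extrema, widths, ratios."""

import numpy as np
import pytest

from cmquant.errors import ProfileError
from cmquant.morphometry import (actin_shift, band_length, detect_extrema,
                                 extract_profile, normalized_intensity,
                                 zdisk_width)
from cmquant.presets import StriationGeometry
from cmquant.records import IntensityProfile, MultiChannelImage
from cmquant.synth import simulate_striation_image

PX = 0.1  # um/px used throughout


def _profile_from(y, pixel_size=PX, channels=None):
    arr = np.atleast_2d(y) if channels is None else np.stack(channels)
    pos = np.arange(arr.shape[1]) * pixel_size
    labels = [f"ch{i}" for i in range(arr.shape[0])]
    return IntensityProfile(positions=pos, intensity=arr,
                            channel_labels=labels, line=((0, 0), (0, 1)),
                            pixel_size=pixel_size)


def _mid_profile(img):
    rows, cols = img.channels.shape[1:]
    return extract_profile(img, ((rows // 2, 0), (rows // 2, cols - 1)))


class TestExtractProfile:
    def test_constant_image_gives_flat_profile(self):
        img = MultiChannelImage(channels=np.full((1, 10, 30), 7.0),
                                pixel_size=PX, channel_labels=["a"])
        prof = extract_profile(img, ((5, 0), (5, 29)))
        np.testing.assert_allclose(prof.intensity, 7.0)

    def test_axis_aligned_line_reproduces_row(self):
        rng = np.random.default_rng(0)
        data = rng.random((1, 8, 40))
        img = MultiChannelImage(channels=data, pixel_size=PX,
                                channel_labels=["a"])
        prof = extract_profile(img, ((3, 0), (3, 39)))
        np.testing.assert_allclose(prof.intensity[0], data[0, 3, :])

    def test_diagonal_line_stretches_period_by_cos_theta(self):
        geom = StriationGeometry(period=2.0, image_size=(200, 200))
        img = simulate_striation_image(geom)
        diag = extract_profile(img, ((0, 0), (199, 199)))  # 45 degrees
        maxima = detect_extrema(diag, 0, "max")
        spacing = float(np.median(np.diff(maxima)))
        assert spacing == pytest.approx(2.0 * np.sqrt(2.0), rel=0.02)

    def test_line_outside_image_rejected(self):
        img = MultiChannelImage(channels=np.zeros((1, 10, 10)),
                                pixel_size=PX, channel_labels=["a"])
        with pytest.raises(ProfileError):
            extract_profile(img, ((0, 0), (12, 5)))


class TestDetectExtrema:
    def test_single_gaussian_subpixel(self):
        x = np.arange(100) * PX
        y = np.exp(-0.5 * ((x - 5.0) / 0.3) ** 2)
        prof = _profile_from(y)
        peaks = detect_extrema(prof, 0, "max")
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(5.0, abs=0.25 * PX)

    def test_cosine_maxima_spacing(self):
        period = 1.7
        x = np.arange(300) * PX
        prof = _profile_from(np.cos(2 * np.pi * x / period))
        peaks = detect_extrema(prof, 0, "max")
        assert np.allclose(np.diff(peaks), period, atol=0.02)

    def test_monotone_ramp_has_no_extrema(self):
        prof = _profile_from(np.linspace(0, 1, 120))
        assert detect_extrema(prof, 0, "max").size == 0
        assert detect_extrema(prof, 0, "min").size == 0


class TestActinShift:
    def test_zero_shift(self):
        geom = StriationGeometry(actin_shift=0.0)
        res = actin_shift(_mid_profile(simulate_striation_image(geom)))
        assert res.value == pytest.approx(0.0, abs=0.25 * geom.pixel_size)

    def test_known_shift_recovered(self):
        geom = StriationGeometry(actin_shift=0.20)
        res = actin_shift(_mid_profile(simulate_striation_image(geom)))
        assert res.value == pytest.approx(0.20, abs=0.02)
        assert not res.ambiguous

    def test_half_period_shift_flagged_ambiguous(self):
        geom = StriationGeometry(period=1.9, actin_shift=0.94)
        res = actin_shift(_mid_profile(simulate_striation_image(geom)))
        assert res.ambiguous

    def test_noisy_subpixel_recovery(self):
        geom = StriationGeometry(actin_shift=0.20, photons=100.0)
        res = actin_shift(_mid_profile(simulate_striation_image(geom,
                                                                seed=6)))
        assert res.value == pytest.approx(0.20, abs=0.25 * geom.pixel_size)

    def test_requires_minima(self):
        x = np.arange(300) * PX
        ridges = np.cos(2 * np.pi * x / 1.9) + 1.0
        flat = np.full(x.size, 2.0)
        prof = _profile_from(None, channels=[ridges, flat])
        with pytest.raises(ProfileError):
            actin_shift(prof)


class TestWidths:
    def test_gaussian_fwhm(self):
        geom = StriationGeometry(zdisk_sigma=0.15)
        res = zdisk_width(_mid_profile(simulate_striation_image(geom)))
        assert res.value == pytest.approx(2.3548 * 0.15, abs=PX)

    def test_doubling_sigma_doubles_fwhm(self):
        w = []
        for sigma in (0.12, 0.24):
            geom = StriationGeometry(zdisk_sigma=sigma, period=2.4,
                                     image_size=(32, 240))
            w.append(zdisk_width(_mid_profile(
                simulate_striation_image(geom))).value)
        assert w[1] == pytest.approx(2.0 * w[0], rel=0.05)

    def test_rectangular_ridge_width(self):
        x = np.arange(400) * PX
        y = np.zeros(x.size)
        width = 0.6
        for c in (5.0, 15.0, 25.0, 35.0):
            y[(x >= c - width / 2) & (x < c + width / 2)] = 1.0
        res = zdisk_width(_profile_from(y))
        assert res.value == pytest.approx(width, abs=PX)

    def test_offset_invariance(self):
        geom = StriationGeometry()
        prof = _mid_profile(simulate_striation_image(geom))
        shifted = IntensityProfile(positions=prof.positions,
                                   intensity=prof.intensity + 3.5,
                                   channel_labels=prof.channel_labels,
                                   line=prof.line,
                                   pixel_size=prof.pixel_size)
        assert zdisk_width(shifted).value == pytest.approx(
            zdisk_width(prof).value, abs=1e-9)

    def test_band_channel_length(self):
        geom = StriationGeometry(period=2.4, band_length=0.8,
                                 image_size=(32, 240),
                                 channel_kinds=("zdisk", "band"),
                                 channel_labels=("z", "band"),
                                 channel_gains=(1.0, 1.0))
        prof = _mid_profile(simulate_striation_image(geom))
        assert band_length(prof, 1).value == pytest.approx(0.8, abs=PX)

    def test_merged_gaussians_widen_band(self):
        x = np.arange(600) * PX
        sigma = 0.2
        single = np.zeros(x.size)
        merged = np.zeros(x.size)
        for c in (10.0, 20.0, 30.0, 40.0):
            single += np.exp(-0.5 * ((x - c) / sigma) ** 2)
            merged += (np.exp(-0.5 * ((x - c + 0.2) / sigma) ** 2)
                       + np.exp(-0.5 * ((x - c - 0.2) / sigma) ** 2))
        w_single = zdisk_width(_profile_from(single)).value
        w_merged = zdisk_width(_profile_from(merged)).value
        assert w_merged > w_single

    def test_length_scales_with_pixel_size(self):
        x = np.arange(400)
        y = np.zeros(x.size)
        for c in (50, 150, 250, 350):
            y += np.exp(-0.5 * ((x - c) / 5.0) ** 2)
        w1 = zdisk_width(_profile_from(y, pixel_size=0.1)).value
        w2 = zdisk_width(_profile_from(y, pixel_size=0.2)).value
        assert w2 == pytest.approx(2.0 * w1, rel=1e-9)


class TestNormalizedIntensity:
    def test_identity_and_scaling(self):
        geom = StriationGeometry()
        img = simulate_striation_image(geom)
        assert normalized_intensity(img, 0, 0) == pytest.approx(1.0)
        doubled = MultiChannelImage(
            channels=np.stack([2.0 * img.channels[0], img.channels[0]]),
            pixel_size=img.pixel_size, channel_labels=["t", "r"])
        assert normalized_intensity(doubled, 0, 1) == pytest.approx(2.0)

    def test_generator_gains_recovered(self):
        geom = StriationGeometry(channel_kinds=("zdisk", "zdisk"),
                                 channel_labels=("a", "b"),
                                 channel_gains=(3.0, 1.5), photons=500.0)
        img = simulate_striation_image(geom, seed=3)
        assert normalized_intensity(img, 0, 1) == pytest.approx(2.0,
                                                                abs=0.05)

    def test_zero_reference_rejected(self):
        img = MultiChannelImage(channels=np.stack([np.ones((10, 10)),
                                                   np.zeros((10, 10))]),
                                pixel_size=PX, channel_labels=["t", "r"])
        with pytest.raises(ProfileError):
            normalized_intensity(img, 0, 1)

    def test_gain_invariance_of_ratio(self):
        geom = StriationGeometry()
        img = simulate_striation_image(geom)
        scaled = MultiChannelImage(channels=img.channels * 4.0,
                                   pixel_size=img.pixel_size,
                                   channel_labels=img.channel_labels)
        assert normalized_intensity(scaled, 0, 1) == pytest.approx(
            normalized_intensity(img, 0, 1), rel=1e-9)
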