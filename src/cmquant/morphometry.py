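"""Striation intensity-profile morphometry.

Measurements on two-channel line profiles through striated cells: the shift
between Z-disk-channel maxima and the nearest minima of the actin channel,
ridge/band widths as full width at half maximum above the local trough
level, and background-corrected intensity ratios between channels.

Width is read as FWHM above the local trough (offset-invariant); extremum
positions are refined by 3-point parabolic interpolation after 3-point
moving-average smoothing; the prominence threshold for extremum detection is
10% of the channel's dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .errors import ProfileError
from .records import IntensityProfile, MorphometryResult, MultiChannelImage

__all__ = [
    "extract_profile",
    "detect_extrema",
    "actin_shift",
    "zdisk_width",
    "band_length",
    "normalized_intensity",
    "ActinShiftResult",
    "WidthResult",
    "analyze_profile",
]

PROMINENCE_FRACTION = 0.10
BACKGROUND_PERCENTILE = 5.0


@dataclass
class ActinShiftResult:
    """Mean absolute shift with per-period values and an ambiguity flag."""

    value: float                  # um, mean |shift|
    per_period: np.ndarray        # um, signed per-maximum shifts
    ambiguous: bool = False       # nearest minimum ill-defined (tie)

    def __float__(self) -> float:
        return self.value


@dataclass
class WidthResult:
    """Mean FWHM with per-ridge widths and an overlap flag."""

    value: float                  # um, mean FWHM
    per_ridge: np.ndarray         # um
    flagged: bool = False         # some width exceeded the ridge spacing

    def __float__(self) -> float:
        return self.value


def extract_profile(image: MultiChannelImage, line: tuple) -> IntensityProfile:
    """Bilinearly sample all channels along a line at 1 px spacing.

    ``line`` is ((r0, c0), (r1, c1)) in pixel coordinates; both endpoints
    must lie inside the image.
    """
    (r0, c0), (r1, c1) = line
    rows, cols = image.channels.shape[1:]
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise ProfileError(f"line endpoint ({r}, {c}) outside image "
                               f"{rows}x{cols}")
    length = float(np.hypot(r1 - r0, c1 - c0))
    n = int(np.floor(length)) + 1
    frac = np.arange(n) / max(length, 1e-12)
    rr = r0 + frac * (r1 - r0)
    cc = c0 + frac * (c1 - c0)
    samples = np.stack([
        map_coordinates(ch, np.vstack([rr, cc]), order=1, mode="nearest")
        for ch in image.channels])
    positions = np.arange(n) * image.pixel_size
    return IntensityProfile(positions=positions, intensity=samples,
                            channel_labels=list(image.channel_labels),
                            line=line, pixel_size=image.pixel_size)


def _smooth3(y: np.ndarray) -> np.ndarray:
    pad = np.pad(y, 1, mode="edge")
    return (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0


def _refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-pixel extremum position by 3-point parabolic interpolation."""
    if i <= 0 or i >= y.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    d = 0.5 * (y[i - 1] - y[i + 1]) / denom
    if abs(d) > 1.0:
        return float(x[i])
    return float(x[i] + d * (x[i + 1] - x[i]))


def detect_extrema(profile: IntensityProfile, channel: int | str,
                   kind: str = "max") -> np.ndarray:
    """Sub-pixel positions (um) of local maxima or minima of one channel.

    The channel is smoothed with a 3-point moving average; extrema must have
    a prominence of at least 10% of the channel's dynamic range.
    """
    if kind not in ("max", "min"):
        raise ValueError("kind must be 'max' or 'min'")
    y = profile.channel(channel)
    ys = _smooth3(y)
    span = float(ys.max() - ys.min())
    if span <= 0:
        return np.array([])
    signal = ys if kind == "max" else -ys
    idx, _ = find_peaks(signal, prominence=PROMINENCE_FRACTION * span)
    return np.array([_refine(profile.positions, signal, i) for i in idx])


def actin_shift(profile: IntensityProfile, zdisk_channel: int | str = 0,
                actin_channel: int | str = 1,
                tie_tolerance_px: float = 0.25) -> ActinShiftResult:
    """Mean distance from each Z-disk maximum to the nearest actin minimum.

    Raises if fewer than 3 Z-disk maxima or no actin minima are found.  When
    the two nearest minima of some maximum are equidistant within
    ``tie_tolerance_px`` pixels, the result is flagged ambiguous.
    """
    maxima = detect_extrema(profile, zdisk_channel, "max")
    minima = detect_extrema(profile, actin_channel, "min")
    if maxima.size < 3:
        raise ProfileError(f"need >= 3 Z-disk maxima, found {maxima.size}")
    if minima.size == 0:
        raise ProfileError("no actin-channel minima found")

    shifts, ambiguous = [], False
    tol = tie_tolerance_px * profile.pixel_size
    for m in maxima:
        d = minima - m
        order = np.argsort(np.abs(d))
        if order.size > 1 and (np.abs(d[order[1]]) - np.abs(d[order[0]])) < tol:
            ambiguous = True
        shifts.append(d[order[0]])
    shifts = np.array(shifts)
    return ActinShiftResult(value=float(np.mean(np.abs(shifts))),
                            per_period=shifts, ambiguous=ambiguous)


def _fwhm(x: np.ndarray, y: np.ndarray, i_peak: int, trough: float
          ) -> float | None:
    """FWHM of the ridge around sample ``i_peak`` above ``trough`` level."""
    half = trough + 0.5 * (y[i_peak] - trough)
    left = None
    for i in range(i_peak, 0, -1):
        if y[i - 1] <= half < y[i]:
            frac = (y[i] - half) / (y[i] - y[i - 1])
            left = x[i] - frac * (x[i] - x[i - 1])
            break
    right = None
    for i in range(i_peak, y.size - 1):
        if y[i + 1] <= half < y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def _ridge_widths(profile: IntensityProfile, channel: int | str
                  ) -> WidthResult:
    y = profile.channel(channel)
    x = profile.positions
    ys = _smooth3(y)
    span = float(ys.max() - ys.min())
    if span <= 0:
        raise ProfileError("flat channel; no ridges")
    peaks, _ = find_peaks(ys, prominence=PROMINENCE_FRACTION * span)
    if peaks.size < 3:
        raise ProfileError(f"need >= 3 ridges, found {peaks.size}")

    spacing = float(np.median(np.diff(x[peaks])))
    widths, flagged = [], False
    for j, p in enumerate(peaks):
        lo = peaks[j - 1] if j > 0 else 0
        hi = peaks[j + 1] if j + 1 < peaks.size else y.size - 1
        left_trough = float(y[lo:p + 1].min())
        right_trough = float(y[p:hi + 1].min())
        trough = 0.5 * (left_trough + right_trough)
        w = _fwhm(x, y, int(p), trough)
        if w is None:
            continue
        if w > spacing:
            flagged = True
        widths.append(w)
    if not widths:
        raise ProfileError("no measurable ridge widths")
    widths = np.array(widths)
    return WidthResult(value=float(widths.mean()), per_ridge=widths,
                       flagged=flagged)


def zdisk_width(profile: IntensityProfile,
                channel: int | str = 0) -> WidthResult:
    """Mean FWHM of the Z-disk-channel ridges above their local troughs."""
    return _ridge_widths(profile, channel)


def band_length(profile: IntensityProfile,
                channel: int | str = 0) -> WidthResult:
    """Mean FWHM of the stained bands of a labeled channel (same machinery
    as :func:`zdisk_width`)."""
    return _ridge_widths(profile, channel)


def normalized_intensity(image: MultiChannelImage,
                         target_channel: int | str,
                         reference_channel: int | str,
                         mask: np.ndarray | None = None) -> float:
    """Background-corrected mean-intensity ratio of target over reference.

    Background per channel is its 5th percentile within the mask.
    """
    tgt = image.channel(target_channel)
    ref = image.channel(reference_channel)
    if mask is not None:
        tgt, ref = tgt[mask], ref[mask]
    bg_t = float(np.percentile(tgt, BACKGROUND_PERCENTILE))
    bg_r = float(np.percentile(ref, BACKGROUND_PERCENTILE))
    denom = float(ref.mean()) - bg_r
    if denom <= 0:
        raise ProfileError("reference channel carries no signal above "
                           "background")
    return (float(tgt.mean()) - bg_t) / denom


def analyze_profile(profile: IntensityProfile,
                    image: MultiChannelImage | None = None,
                    zdisk_channel: int | str = 0,
                    actin_channel: int | str | None = 1,
                    band_channels: list | None = None,
                    intensity_channels: tuple | None = None
                    ) -> MorphometryResult:
    """Run all profile measurements and bundle them per profile."""
    flags: list[str] = []
    result = MorphometryResult(flags=flags)

    zw = zdisk_width(profile, zdisk_channel)
    result.zdisk_width = zw.value
    result.n_periods_used = int(zw.per_ridge.size)
    if zw.flagged:
        flags.append("overlapping_ridges")

    if actin_channel is not None:
        sh = actin_shift(profile, zdisk_channel, actin_channel)
        result.actin_shift = sh.value
        if sh.ambiguous:
            flags.append("ambiguous_nearest_minimum")

    for ch in band_channels or []:
        label = ch if isinstance(ch, str) else profile.channel_labels[ch]
        result.band_lengths[label] = band_length(profile, ch).value

    if intensity_channels is not None and image is not None:
        result.normalized_intensity = normalized_intensity(
            image, intensity_channels[0], intensity_channels[1])
    return result
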