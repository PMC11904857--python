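"""Generator for two-channel striated (sarcomere-like) test images."""

from __future__ import annotations

import numpy as np

from ..errors import UndersampledImageError
from ..presets import StriationGeometry
from ..records import MultiChannelImage

__all__ = ["ridge_positions", "simulate_striation_image"]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def ridge_positions(geom: StriationGeometry) -> np.ndarray:
    """Ground-truth Z-disk (ridge) centers along the column axis, in um."""
    width_um = geom.image_size[1] * geom.pixel_size
    n = int(np.floor(width_um / geom.period))
    return geom.period * (np.arange(n) + 0.5)


def _gauss_comb(x_um: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    prof = np.zeros_like(x_um)
    for c in centers:
        prof += np.exp(-0.5 * ((x_um - c) / sigma) ** 2)
    return prof


def simulate_striation_image(geom: StriationGeometry,
                             seed: int | None = None) -> MultiChannelImage:
    """Render a striated multi-channel image with known geometry.

    Channel kinds:
      * ``zdisk`` - periodic Gaussian ridges (sigma ``zdisk_sigma``) at the
        ground-truth ridge positions; phalloidin/alpha-actinin-like.
      * ``actin`` - complementary pattern ``1 - comb(x - actin_shift)`` whose
        minima sit at the ridge positions translated by ``actin_shift``.
      * ``band``  - Gaussian bands of FWHM ``band_length`` centered halfway
        between ridges; troponin/tropomyosin-like.

    Intensity is constant along rows.  If ``geom.photons`` is set, per-pixel
    Poisson noise is applied at that photon gain; otherwise the image is
    noiseless.
    """
    if geom.pixel_size > geom.period / 4.0:
        raise UndersampledImageError(
            f"pixel_size {geom.pixel_size} um > period/4 "
            f"({geom.period / 4.0:g} um)")

    rows, cols = geom.image_size
    x = (np.arange(cols) + 0.5) * geom.pixel_size
    centers = ridge_positions(geom)

    channels = []
    for kind, gain in zip(geom.channel_kinds, geom.channel_gains):
        if kind == "zdisk":
            prof = _gauss_comb(x, centers, geom.zdisk_sigma)
        elif kind == "actin":
            comb = _gauss_comb(x, centers + geom.actin_shift, geom.zdisk_sigma)
            peak = comb.max() if comb.max() > 0 else 1.0
            prof = 1.0 - 0.8 * comb / peak  # minima at shifted ridge centers
        elif kind == "band":
            sigma = geom.band_length / _FWHM
            prof = _gauss_comb(x, centers + geom.period / 2.0, sigma)
        else:
            raise ValueError(f"unknown channel kind {kind!r}")
        channels.append(gain * np.tile(prof, (rows, 1)))
    img = np.stack(channels)

    if geom.photons is not None:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.maximum(img, 0.0) * geom.photons) / geom.photons

    return MultiChannelImage(channels=img, pixel_size=geom.pixel_size,
                             channel_labels=list(geom.channel_labels),
                             meta={"geometry": geom.to_dict(), "seed": seed,
                                   "ridge_positions_um": centers.tolist(),
                                   "modality": "image"})
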