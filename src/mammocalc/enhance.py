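"""Contrast stretching and band-pass enhancement of microcalcification-scale objects.

Microcalcifications are among the brightest objects in the breast, so the
upper gray levels are spread out (and the lower ones contracted) with a
cosine intensity transform, after which a Difference-of-Gaussians band-pass
filter selects structures in the 0.1-1 mm size band.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import BreastMask, EnhancedImage, MammogramImage

__all__ = ["cosine_stretch", "dog_filter"]


def cosine_stretch(img: MammogramImage, mask: BreastMask) -> MammogramImage:
    """Apply the cosine intensity transform ``T(x) = 1 - cos(pi x / 2)``.

    Intensities are min-max normalised within the breast mask to [0, 1] and
    mapped through ``T``, which is strictly increasing with T(0)=0, T(1)=1
    and increasing derivative: low gray levels are contracted, high gray
    levels (where the calcifications live) are spread out. Pixels outside the
    mask are set to 0.
    """
    if not mask.mask.any():
        raise ValueError("empty breast mask")
    pixels = np.asarray(img.pixels, dtype=float)
    vals = pixels[mask.mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        norm = np.zeros_like(pixels)
    else:
        norm = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)
    out = 1.0 - np.cos(np.pi * norm / 2.0)
    out[~mask.mask] = 0.0
    return MammogramImage(pixels=out, spacing_mm=img.spacing_mm, bit_depth=img.bit_depth)


def dog_filter(
    img: MammogramImage,
    sigma_low_px: float = 1.0,
    sigma_high_px: float = 8.0,
    mask: BreastMask | None = None,
) -> EnhancedImage:
    """Difference-of-Gaussians band-pass filter for bright small objects.

    Returns ``G(sigma_low) * I - G(sigma_high) * I`` clipped at zero (bright
    response only) and rescaled to [0, 1] over the mask (or the whole image
    when no mask is given). The default scales correspond to speck diameters
    of roughly 2-20 px, i.e. 0.1-1.0 mm at 0.05 mm/pixel.
    """
    if not 0 < sigma_low_px < sigma_high_px:
        raise ValueError("require 0 < sigma_low_px < sigma_high_px")
    pixels = np.asarray(img.pixels, dtype=float)
    response = ndimage.gaussian_filter(pixels, sigma_low_px) - ndimage.gaussian_filter(
        pixels, sigma_high_px
    )
    response = np.maximum(response, 0.0)
    if mask is not None:
        response[~mask.mask] = 0.0
        peak = response[mask.mask].max() if mask.mask.any() else 0.0
    else:
        peak = response.max()
    if peak > 0:
        response = response / peak
    return EnhancedImage(
        pixels=response,
        dog_sigma_low_px=sigma_low_px,
        dog_sigma_high_px=sigma_high_px,
        spacing_mm=img.spacing_mm,
    )
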