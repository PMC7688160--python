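"""RGB <-> HSL conversion (bi-hexcone model), vectorised.

Hue is in degrees [0, 360); saturation and lightness in [0, 1].
scikit-image ships HSV but not HSL, and the histology stain windows used
here are specified in HSL, so the conversion is implemented directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsl", "hsl_to_rgb"]


def _as_unit_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim < 1 or img.shape[-1] != 3:
        raise ValueError(f"expected an RGB array with last axis 3, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    out = img.astype(np.float64)
    if out.min() < 0 or out.max() > 1:
        raise ValueError("float RGB input must lie in [0, 1]")
    return out


def rgb_to_hsl(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image (uint8, uint16 or float in [0,1]) to HSL.

    Returns a float array of the same leading shape with last axis
    (H, S, L): H in [0, 360) degrees, S and L in [0, 1].
    """
    rgb = _as_unit_float(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.max(rgb, axis=-1)
    minc = np.min(rgb, axis=-1)
    chroma = maxc - minc
    lum = (maxc + minc) / 2.0

    sat = np.zeros_like(lum)
    nz = chroma > 0
    # 1 - |2L - 1| written without cancellation so tiny values stay finite
    denom = np.where(lum[nz] <= 0.5, maxc[nz] + minc[nz], 2.0 - maxc[nz] - minc[nz])
    sat[nz] = np.clip(chroma[nz] / denom, 0.0, 1.0)

    hue = np.zeros_like(lum)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = ((g - b) / chroma) % 6.0
        hg = (b - r) / chroma + 2.0
        hb = (r - g) / chroma + 4.0
    hue = np.where(maxc == r, hr, np.where(maxc == g, hg, hb))
    hue = np.where(nz, hue * 60.0, 0.0) % 360.0

    return np.stack([hue, sat, lum], axis=-1)


def hsl_to_rgb(hsl: np.ndarray) -> np.ndarray:
    """Convert HSL (degrees, [0,1], [0,1]) to float RGB in [0, 1]."""
    hsl = np.asarray(hsl, dtype=np.float64)
    h = np.mod(hsl[..., 0], 360.0) / 60.0
    s = hsl[..., 1]
    lum = hsl[..., 2]
    c = (1.0 - np.abs(2.0 * lum - 1.0)) * s
    x = c * (1.0 - np.abs(np.mod(h, 2.0) - 1.0))
    m = lum - c / 2.0
    sext = np.floor(h).astype(int) % 6
    zeros = np.zeros_like(c)
    r = np.choose(sext, [c, x, zeros, zeros, x, c])
    g = np.choose(sext, [x, c, c, x, zeros, zeros])
    b = np.choose(sext, [zeros, zeros, x, c, c, x])
    return np.clip(np.stack([r + m, g + m, b + m], axis=-1), 0.0, 1.0)
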