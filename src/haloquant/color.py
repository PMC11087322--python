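"""sRGB <-> CIELAB conversion for 8-bit plate photographs.

The pipeline's signal channel is b* (blue-yellow): enzymatic hydrolysis of
the chromogenic substrate releases a blue dye, and blue pixels have b* < 0.
Conversions use the IEC 61966-2-1 sRGB transfer function, the sRGB->XYZ
matrix for the D65 illuminant, and the CIE 1976 L*a*b* formulas with the
D65 2-degree-observer white point (Xn=95.047, Yn=100.000, Zn=108.883) --
the standard pairing for phone JPEG/PNG output tagged sRGB.  No ICC-profile
handling or chromatic adaptation is attempted: inputs are assumed to be
plain sRGB, as delivered by the acquisition described in the docs.
"""

from __future__ import annotations

import warnings

import numpy as np
import imageio.v3 as iio

__all__ = [
    "srgb_to_lab",
    "lab_to_srgb",
    "lab_to_srgb_image",
    "load_rgb_image",
    "D65_WHITE",
]

# D65 white point, 2-degree observer, on the Y=100 scale.
D65_WHITE = (95.047, 100.000, 108.883)

# sRGB -> XYZ (D65) matrix, IEC 61966-2-1 / sRGB specification.
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ2RGB = np.linalg.inv(_RGB2XYZ)

# CIE 1976 f(t) threshold as exact rationals: delta = 6/29.
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3          # (6/29)^3
_KAPPA = 1.0 / (3.0 * _DELTA**2)  # 1/(3*(6/29)^2)


def _srgb_decode(u: np.ndarray) -> np.ndarray:
    """IEC 61966-2-1 electro-optical transfer: encoded [0,1] -> linear."""
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA3, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > _DELTA, ft**3, (ft - 4.0 / 29.0) / _KAPPA)


def srgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIELAB.

    Parameters
    ----------
    image : ndarray
        ``(H, W, 3)`` uint8 array (or an ``(..., 3)`` uint8 array of
        triplets).  Values are sRGB-encoded in [0, 255].

    Returns
    -------
    ndarray
        Float64 array of the same leading shape with the last axis holding
        ``(L*, a*, b*)``.  For in-gamut input, L* lies in [0, 100].

    Raises
    ------
    ValueError
        If the input is not an 8-bit array with a trailing axis of 3.
    """
    arr = np.asarray(image)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of length 3, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit (uint8) sRGB input, got dtype {arr.dtype}")
    rgb_lin = _srgb_decode(arr.astype(np.float64) / 255.0)
    xyz = rgb_lin @ _RGB2XYZ.T  # on the Y=1 scale
    fx = _f(xyz[..., 0] * 100.0 / D65_WHITE[0])
    fy = _f(xyz[..., 1] * 100.0 / D65_WHITE[1])
    fz = _f(xyz[..., 2] * 100.0 / D65_WHITE[2])
    lab = np.empty(arr.shape, dtype=np.float64)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def lab_to_srgb(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert CIELAB values to 8-bit sRGB, flagging out-of-gamut pixels.

    Inverse of :func:`srgb_to_lab`.  Out-of-gamut results are clipped to
    [0, 255]; clipping is reported, not fatal, because the synthetic plate
    generator may legitimately request colors near the gamut boundary.

    Parameters
    ----------
    lab : ndarray
        ``(..., 3)`` float array of ``(L*, a*, b*)`` triplets.

    Returns
    -------
    rgb : ndarray
        uint8 array of the same shape.
    clipped : ndarray
        Boolean array (leading shape) marking pixels whose linear RGB fell
        outside [0, 1] before clipping.
    """
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError(f"expected trailing Lab axis of length 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("Lab values must be finite")
    fy = (arr[..., 0] + 16.0) / 116.0
    fx = fy + arr[..., 1] / 500.0
    fz = fy - arr[..., 2] / 200.0
    xyz = np.stack(
        [
            _f_inv(fx) * D65_WHITE[0] / 100.0,
            _f_inv(fy) * D65_WHITE[1] / 100.0,
            _f_inv(fz) * D65_WHITE[2] / 100.0,
        ],
        axis=-1,
    )
    rgb_lin = xyz @ _XYZ2RGB.T
    # tolerance absorbs matrix roundoff at the gamut boundary (the sRGB
    # matrix rows are printed to 7 decimals, so white lands ~1e-7 off 1.0)
    tol = 1e-6
    clipped = np.any((rgb_lin < -tol) | (rgb_lin > 1.0 + tol), axis=-1)
    rgb_lin = np.clip(rgb_lin, 0.0, 1.0)
    enc = np.where(
        rgb_lin <= 0.0031308,
        12.92 * rgb_lin,
        1.055 * rgb_lin ** (1.0 / 2.4) - 0.055,
    )
    rgb = np.clip(np.rint(enc * 255.0), 0, 255).astype(np.uint8)
    return rgb, clipped


def lab_to_srgb_image(lab: np.ndarray) -> np.ndarray:
    """Convenience wrapper returning only the uint8 image."""
    return lab_to_srgb(lab)[0]


def load_rgb_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG plate photograph as an (H, W, 3) uint8 array.

    Grayscale input is promoted to three channels; an alpha channel is
    dropped with a warning (the assay carries no transparency information).
    """
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image, got dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    if arr.shape[-1] == 4:
        warnings.warn(f"{path}: alpha channel dropped", stacklevel=2)
        arr = arr[..., :3]
    return arr
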