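"""Color-space primitives: sRGB <-> CIELUV, hue rotation, mean equating,
and the network-oriented "synthetic HSV" parameterization of RGB.

All rasters are numpy arrays whose last axis holds the three channels.
RGB is interpreted as sRGB (D65 white point, standard transfer function)
with channel values in [0, 255]; CIELUV rasters hold (L*, u*, v*).

The forward/inverse transforms are implemented directly (rather than via a
library) so that (a) the white point is derived exactly from the RGB->XYZ
matrix, making (255,255,255) map to precisely (100, 0, 0), and (b)
out-of-gamut pixels can be counted before clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GamutError, InputDomainError

__all__ = [
    "srgb_to_luv",
    "luv_to_srgb",
    "chroma",
    "hue_angle",
    "rotate_hue",
    "desaturate",
    "equate_channel_mean",
    "SyntheticHSV",
    "synthetic_hsv_decompose",
    "synthetic_hsv_compose",
    "synthetic_hsv_max_sat",
]

# sRGB (IEC 61966-2-1) linear RGB -> XYZ, D65.
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)

# White point derived from the matrix itself so white round-trips exactly.
_WHITE_XYZ = _M_RGB2XYZ @ np.ones(3)
_XN, _YN, _ZN = _WHITE_XYZ
_UN = 4.0 * _XN / (_XN + 15.0 * _YN + 3.0 * _ZN)
_VN = 9.0 * _YN / (_XN + 15.0 * _YN + 3.0 * _ZN)

_EPS_CUBED = (6.0 / 29.0) ** 3  # CIE lightness threshold on Y/Yn
_KAPPA = (29.0 / 3.0) ** 3


def _srgb_transfer_inverse(c: np.ndarray) -> np.ndarray:
    """Gamma-expand sRGB values in [0, 1] to linear light."""
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_transfer(c: np.ndarray) -> np.ndarray:
    """Gamma-compress linear light to sRGB in [0, 1]."""
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def srgb_to_luv(rgb: np.ndarray) -> np.ndarray:
    """Convert an sRGB raster (channels 0-255) to CIE L*u*v*.

    Parameters
    ----------
    rgb : array, shape (..., 3)
        sRGB channel values in [0, 255] (integer or real).

    Returns
    -------
    array, shape (..., 3)
        L* in [0, 100], u* and v* unbounded.

    Raises
    ------
    InputDomainError
        If any channel lies outside [0, 255].
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise InputDomainError("last axis must hold 3 channels")
    if rgb.min() < 0 or rgb.max() > 255:
        raise InputDomainError("RGB channels must lie in [0, 255]")

    linear = _srgb_transfer_inverse(rgb / 255.0)
    xyz = linear @ _M_RGB2XYZ.T
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]

    yr = y / _YN
    big = yr > _EPS_CUBED
    lum = np.where(big, 116.0 * np.cbrt(yr) - 16.0, _KAPPA * yr)

    denom = x + 15.0 * y + 3.0 * z
    safe = denom > 0
    up = np.where(safe, 4.0 * x / np.where(safe, denom, 1.0), _UN)
    vp = np.where(safe, 9.0 * y / np.where(safe, denom, 1.0), _VN)

    out = np.empty_like(rgb)
    out[..., 0] = lum
    out[..., 1] = 13.0 * lum * (up - _UN)
    out[..., 2] = 13.0 * lum * (vp - _VN)
    return out


def luv_to_srgb(
    luv: np.ndarray,
    *,
    quantize: bool = True,
    return_clip_count: bool = False,
):
    """Convert a CIE L*u*v* raster back to sRGB.

    Out-of-gamut pixels are clipped channel-wise; their count is available
    via ``return_clip_count`` (a pixel counts once however many channels
    overflow).

    Parameters
    ----------
    luv : array, shape (..., 3)
    quantize : bool
        Round to integer channel values (returned as float array of
        integers so downstream math stays exact).
    return_clip_count : bool
        Also return the number of out-of-gamut pixels.
    """
    luv = np.asarray(luv, dtype=np.float64)
    lum, u, v = luv[..., 0], luv[..., 1], luv[..., 2]

    pos = lum > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(pos, u / (13.0 * np.where(pos, lum, 1.0)) + _UN, _UN)
        vp = np.where(pos, v / (13.0 * np.where(pos, lum, 1.0)) + _VN, _VN)

    y = np.where(lum > 8.0, _YN * ((lum + 16.0) / 116.0) ** 3, _YN * lum / _KAPPA)
    vp_safe = np.where(vp > 0, vp, 1.0)
    x = y * 9.0 * up / (4.0 * vp_safe)
    z = y * (12.0 - 3.0 * up - 20.0 * vp) / (4.0 * vp_safe)

    xyz = np.stack([x, y, z], axis=-1)
    linear = xyz @ _M_XYZ2RGB.T
    clipped = np.any((linear < -1e-9) | (linear > 1.0 + 1e-9), axis=-1)
    rgb = _srgb_transfer(np.clip(linear, 0.0, 1.0)) * 255.0
    rgb = np.clip(rgb, 0.0, 255.0)
    if quantize:
        rgb = np.round(rgb)
    if return_clip_count:
        return rgb, int(np.count_nonzero(clipped))
    return rgb


def chroma(u, v=None):
    """Chroma sqrt(u^2 + v^2): distance from the achromatic axis.

    Accepts either ``chroma(u, v)`` or a LUV raster ``chroma(luv)``.
    """
    if v is None:
        luv = np.asarray(u, dtype=np.float64)
        return np.hypot(luv[..., 1], luv[..., 2])
    return np.hypot(np.asarray(u, dtype=np.float64), np.asarray(v, dtype=np.float64))


def hue_angle(u, v=None):
    """Hue angle in degrees in [0, 360), counterclockwise in the (u, v) plane."""
    if v is None:
        luv = np.asarray(u, dtype=np.float64)
        u, v = luv[..., 1], luv[..., 2]
    return np.degrees(np.arctan2(v, u)) % 360.0


def rotate_hue(luv: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate the (u, v) coordinates of every pixel by ``angle_deg``
    (counterclockwise); L* is untouched."""
    luv = np.asarray(luv, dtype=np.float64)
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    out = luv.copy()
    out[..., 1] = c * luv[..., 1] - s * luv[..., 2]
    out[..., 2] = s * luv[..., 1] + c * luv[..., 2]
    return out


def desaturate(luv: np.ndarray) -> np.ndarray:
    """Zero the chromaticity channels, preserving L* exactly."""
    out = np.asarray(luv, dtype=np.float64).copy()
    out[..., 1] = 0.0
    out[..., 2] = 0.0
    return out


def equate_channel_mean(
    values: np.ndarray,
    target: float,
    bounds: tuple[float, float],
    mask: np.ndarray | None = None,
):
    """Shift values so their (masked) mean equals ``target``, shrinking the
    deviations about the mean when the shift would push any value out of
    ``bounds``.

    The shrink is a single multiplicative factor ``s`` in (0, 1] applied to
    the deviations: ``adjusted = target + s * (v - mean(v))``, with the
    largest admissible ``s`` computed in closed form. Unmasked entries are
    returned untouched.

    Returns
    -------
    adjusted : array, same shape as ``values``
    shrink : float
        The factor applied (1.0 when no shrink was needed).
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo <= target <= hi:
        raise InputDomainError(f"target {target} outside bounds [{lo}, {hi}]")
    if mask is None:
        sel = np.ones(values.shape, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
    if not sel.any():
        raise DegenerateInputError("mask selects no pixels")

    v = values[sel]
    dev = v - v.mean()
    s = 1.0
    pos = dev > 0
    neg = dev < 0
    if pos.any():
        s = min(s, float(np.min((hi - target) / dev[pos])))
    if neg.any():
        s = min(s, float(np.min((lo - target) / dev[neg])))
    adjusted = np.clip(target + s * dev, lo, hi)

    out = values.copy()
    out[sel] = adjusted
    return out, s


# --------------------------------------------------------------------------
# Synthetic HSV: a luminance/saturation/hue parameterization built on raw
# RGB geometry (no psychophysics). Luminance is the channel mean; saturation
# the Euclidean distance to the equal-luminance gray; hue the angle on the
# iso-(lum, sat) circle, with 0 deg at the point of maximal R and increasing
# toward G.

# Orthonormal basis of the constant-sum plane in RGB space.
_E1 = np.array([2.0, -1.0, -1.0]) / np.sqrt(6.0)  # direction of max R
_E2 = np.array([0.0, 1.0, -1.0]) / np.sqrt(2.0)  # R -> G direction


@dataclass(frozen=True)
class SyntheticHSV:
    """Coordinates in the synthetic HSV space (hue is NaN when undefined)."""

    lum: float
    sat: float
    hue: float

    @property
    def hue_defined(self) -> bool:
        return not np.isnan(self.hue)


def synthetic_hsv_max_sat(lum) -> np.ndarray | float:
    """Largest saturation whose full hue circle stays inside the RGB cube
    at this luminance."""
    lum = np.asarray(lum, dtype=np.float64)
    # each channel moves by at most sat * sqrt(2/3) around the circle
    out = np.minimum(lum, 255.0 - lum) * np.sqrt(1.5)
    return float(out) if out.ndim == 0 else out


def synthetic_hsv_decompose(rgb: np.ndarray):
    """Decompose RGB (0-255, any leading shape) into synthetic HSV.

    Returns ``(lum, sat, hue_deg)`` arrays; hue is NaN where sat == 0.
    Scalar input returns a :class:`SyntheticHSV`.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    scalar = arr.ndim == 1
    lum = arr.mean(axis=-1)
    dev = arr - lum[..., None]
    sat = np.linalg.norm(dev, axis=-1)
    a = dev @ _E1
    b = dev @ _E2
    with np.errstate(invalid="ignore"):
        hue = np.where(sat > 1e-12, np.degrees(np.arctan2(b, a)) % 360.0, np.nan)
    if scalar:
        return SyntheticHSV(float(lum), float(sat), float(hue))
    return lum, sat, hue


def synthetic_hsv_compose(lum, sat, hue_deg, *, check_gamut: bool = True) -> np.ndarray:
    """Compose real-valued (pre-quantization) RGB from synthetic HSV.

    By construction the channel mean equals ``lum`` and the distance to the
    equal-luminance gray equals ``sat`` exactly; hue 0 maximizes R.

    Raises
    ------
    GamutError
        If the full hue circle at (lum, sat) exits the RGB cube; the
        maximal admissible saturation is attached to the error.
    """
    lum = np.asarray(lum, dtype=np.float64)
    sat = np.asarray(sat, dtype=np.float64)
    hue = np.deg2rad(np.asarray(hue_deg, dtype=np.float64))
    if check_gamut:
        limit = synthetic_hsv_max_sat(lum)
        if np.any(sat > np.asarray(limit) + 1e-9):
            raise GamutError(
                "iso-luminance/saturation circle exits the RGB cube",
                max_admissible=float(np.min(np.asarray(limit))),
            )
    direction = (
        np.cos(hue)[..., None] * _E1 + np.sin(hue)[..., None] * _E2
    )
    return lum[..., None] + sat[..., None] * direction
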