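"""Calibrated stimulus construction.

Builds color/form stimulus grids: textured recolorings of source object
images, uniform silhouettes, grayscale versions, and analytically drawn
oriented bars -- all equated in mean luminance and mean saturation over
their non-background pixels, in either CIELUV or synthetic-HSV coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import color_math as cm
from .errors import DegenerateInputError, InputDomainError

__all__ = [
    "CalibrationTarget",
    "SourceObjectImage",
    "StimulusImage",
    "StimulusSet",
    "BarSpec",
    "background_mask",
    "calibrate_and_recolor",
    "make_silhouette",
    "silhouette_fill_color",
    "make_grayscale",
    "make_bars",
    "bar_mask",
    "select_dissimilar_subset",
    "audit_calibration",
]

BACKGROUND_THRESHOLD = 250  # all channels >= this => near-white background
N_HUES_DEFAULT = 12


@dataclass(frozen=True)
class CalibrationTarget:
    """Target masked-mean luminance and saturation in a named color space.

    ``space`` is ``"cieluv"`` (L* / chroma units) or ``"synthetic_hsv"``
    (mean-RGB / RGB-distance units).
    """

    space: str = "cieluv"
    mean_luminance: float = 60.0
    mean_saturation: float = 40.0

    def __post_init__(self):
        if self.space not in ("cieluv", "synthetic_hsv"):
            raise InputDomainError(f"unknown color space {self.space!r}")
        if self.mean_luminance < 0 or self.mean_saturation < 0:
            raise InputDomainError("calibration targets must be non-negative")


@dataclass
class SourceObjectImage:
    """A raw object image on a near-white background."""

    object_id: str
    raster: np.ndarray  # (H, W, 3) uint8-valued
    mask: np.ndarray | None = None  # True on object (non-background) pixels

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        if self.mask is None:
            self.mask = background_mask(self.raster)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class StimulusImage:
    """One calibrated stimulus plus its calibration record."""

    object_id: str
    hue_index: int  # 0..11, or -1 for the grayscale variant
    variant: str  # textured | silhouette | bar | grayscale
    raster: np.ndarray  # (H, W, 3) uint8
    calibration: CalibrationTarget
    mask: np.ndarray
    achieved_mean_lum: float = np.nan
    achieved_mean_sat: float = np.nan
    shrink_lum: float = 1.0
    shrink_sat: float = 1.0
    gamut_clip_count: int = 0

    @property
    def key(self) -> tuple:
        return (self.object_id, self.hue_index, self.variant)


@dataclass
class StimulusSet:
    """An ordered collection of stimuli with a tabular manifest."""

    images: list[StimulusImage] = field(default_factory=list)

    def __len__(self):
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "object_id": im.object_id,
                "hue_index": im.hue_index,
                "variant": im.variant,
                "path": f"{im.variant}_{im.object_id}_h{im.hue_index:02d}.png",
                "space": im.calibration.space,
                "target_mean_lum": im.calibration.mean_luminance,
                "target_mean_sat": im.calibration.mean_saturation,
                "achieved_mean_lum": im.achieved_mean_lum,
                "achieved_mean_sat": im.achieved_mean_sat,
                "shrink_lum": im.shrink_lum,
                "shrink_sat": im.shrink_sat,
                "gamut_clip_count": im.gamut_clip_count,
            }
            for im in self.images
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir) -> pd.DataFrame:
        """Write PNGs plus ``manifest.csv``; returns the manifest."""
        from pathlib import Path

        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest
        for im, path in zip(self.images, manifest["path"]):
            Image.fromarray(im.raster.astype(np.uint8)).save(out / path)
        manifest.to_csv(out / "manifest.csv", index=False, float_format="%.6f")
        return manifest


def background_mask(raster: np.ndarray, threshold: int = BACKGROUND_THRESHOLD) -> np.ndarray:
    """True on object pixels; background = all channels >= ``threshold``.

    The near-white threshold (rather than exact 255) tolerates JPEG
    speckle around the background.
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[-1] != 3:
        raise InputDomainError("expected an (H, W, 3) RGB raster")
    mask = ~np.all(raster >= threshold, axis=-1)
    if not mask.any():
        raise DegenerateInputError("image is entirely background")
    return mask


# --------------------------------------------------------------------------
# Calibration cores. Both return, for the masked pixels only, the
# pre-quantization per-pixel (luminance, saturation, hue-direction) after
# mean-equating, so recoloring is a pure hue manipulation.


def _calibrated_base_cieluv(pixels_rgb, target):
    luv = cm.srgb_to_luv(pixels_rgb)
    lum, s_lum = cm.equate_channel_mean(luv[:, 0], target.mean_luminance, (0.0, 100.0))
    sat0 = cm.chroma(luv)
    sat, s_sat = cm.equate_channel_mean(sat0, target.mean_saturation, (0.0, np.inf))
    # unit hue direction; achromatic pixels point along +u (hue 0)
    dirs = np.stack([np.ones_like(sat0), np.zeros_like(sat0)], axis=-1)
    nz = sat0 > 1e-9
    dirs[nz] = luv[nz, 1:] / sat0[nz, None]
    return lum, sat, dirs, s_lum, s_sat


def _calibrated_base_shsv(pixels_rgb, target):
    lum0, sat0, hue0 = cm.synthetic_hsv_decompose(np.asarray(pixels_rgb, dtype=float))
    lum, s_lum = cm.equate_channel_mean(lum0, target.mean_luminance, (0.0, 255.0))
    cap = float(np.min(cm.synthetic_hsv_max_sat(lum)))
    sat, s_sat = cm.equate_channel_mean(sat0, target.mean_saturation, (0.0, cap))
    hue = np.where(np.isnan(hue0), 0.0, hue0)
    return lum, sat, hue, s_lum, s_sat


def _render_cieluv(lum, sat, dirs, rotation_deg):
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    uv = sat[:, None] * (dirs @ rot.T)
    luv = np.concatenate([lum[:, None], uv], axis=-1)
    return cm.luv_to_srgb(luv, return_clip_count=True)


def _render_shsv(lum, sat, hue, rotation_deg):
    rgb = cm.synthetic_hsv_compose(lum, sat, (hue + rotation_deg) % 360.0, check_gamut=False)
    clipped = int(np.count_nonzero(np.any((rgb < -0.5) | (rgb > 255.5), axis=-1)))
    return np.round(np.clip(rgb, 0.0, 255.0)), clipped


def _finish(source, pixels, mask, hue_index, variant, target):
    out = np.asarray(source, dtype=np.uint8).copy()
    out[mask] = pixels.astype(np.uint8)
    im = StimulusImage(
        object_id="",
        hue_index=hue_index,
        variant=variant,
        raster=out,
        calibration=target,
        mask=mask,
    )
    audit = audit_calibration(im)
    im.achieved_mean_lum = audit["mean_lum"]
    im.achieved_mean_sat = audit["mean_sat"]
    return im


def calibrate_and_recolor(
    source: SourceObjectImage,
    calibration: CalibrationTarget,
    n_hues: int = N_HUES_DEFAULT,
) -> list[StimulusImage]:
    """Produce ``n_hues`` textured recolorings of one object.

    The object's pixels are mean-equated in luminance and saturation (with
    overflow shrinkage about the mean), then the hue of every pixel is
    rotated to ``n_hues`` evenly spaced angles. Background pixels are
    untouched. Relative within-object luminance/saturation patterns are
    preserved up to the shrink factors.
    """
    mask = source.mask
    pixels = source.raster[mask].astype(np.float64)
    step = 360.0 / n_hues
    images = []
    if calibration.space == "cieluv":
        lum, sat, dirs, s_lum, s_sat = _calibrated_base_cieluv(pixels, calibration)
        for i in range(n_hues):
            rgb, clipped = _render_cieluv(lum, sat, dirs, i * step)
            im = _finish(source.raster, rgb, mask, i, "textured", calibration)
            im.object_id = source.object_id
            im.shrink_lum, im.shrink_sat, im.gamut_clip_count = s_lum, s_sat, clipped
            images.append(im)
    else:
        lum, sat, hue, s_lum, s_sat = _calibrated_base_shsv(pixels, calibration)
        for i in range(n_hues):
            rgb, clipped = _render_shsv(lum, sat, hue, i * step)
            im = _finish(source.raster, rgb, mask, i, "textured", calibration)
            im.object_id = source.object_id
            im.shrink_lum, im.shrink_sat, im.gamut_clip_count = s_lum, s_sat, clipped
            images.append(im)
    return images


def silhouette_fill_color(
    calibration: CalibrationTarget, hue_index: int, n_hues: int = N_HUES_DEFAULT
) -> np.ndarray:
    """The single quantized RGB triplet whose luminance/saturation hit the
    calibration targets at the given hue angle (global: independent of the
    object)."""
    angle = hue_index * 360.0 / n_hues
    if calibration.space == "cieluv":
        theta = np.deg2rad(angle)
        luv = np.array(
            [
                calibration.mean_luminance,
                calibration.mean_saturation * np.cos(theta),
                calibration.mean_saturation * np.sin(theta),
            ]
        )
        return cm.luv_to_srgb(luv)
    rgb = cm.synthetic_hsv_compose(
        calibration.mean_luminance, calibration.mean_saturation, angle
    )
    return np.round(np.clip(rgb, 0.0, 255.0))


def synthetic_hsv_targets_from_cieluv(
    cieluv_target: CalibrationTarget, n_hues: int = N_HUES_DEFAULT
) -> CalibrationTarget:
    """Synthetic-HSV calibration targets matched to a CIELUV calibration:
    the mean-RGB luminance and RGB-distance saturation of whichever of the
    n CIELUV-calibrated hues has the highest red channel."""
    fills = [
        silhouette_fill_color(cieluv_target, h, n_hues) for h in range(n_hues)
    ]
    reddest = max(fills, key=lambda rgb: rgb[0])
    coords = cm.synthetic_hsv_decompose(reddest.astype(float))
    return CalibrationTarget("synthetic_hsv", coords.lum, coords.sat)


def make_silhouette(
    source: SourceObjectImage,
    hue_index: int,
    calibration: CalibrationTarget,
    n_hues: int = N_HUES_DEFAULT,
) -> StimulusImage:
    """Replace every object pixel with one uniform calibrated color."""
    fill = silhouette_fill_color(calibration, hue_index, n_hues)
    pixels = np.tile(fill, (int(source.mask.sum()), 1))
    im = _finish(source.raster, pixels, source.mask, hue_index, "silhouette", calibration)
    im.object_id = source.object_id
    return im


def make_grayscale(
    source: SourceObjectImage, calibration: CalibrationTarget
) -> StimulusImage:
    """Achromatic version: saturation zeroed, luminance pattern preserved
    (masked mean luminance still equated to the target)."""
    mask = source.mask
    pixels = source.raster[mask].astype(np.float64)
    if calibration.space == "cieluv":
        lum, _, _, s_lum, _ = _calibrated_base_cieluv(pixels, calibration)
        luv = np.stack([lum, np.zeros_like(lum), np.zeros_like(lum)], axis=-1)
        rgb, clipped = cm.luv_to_srgb(luv, return_clip_count=True)
    else:
        lum, _, _, s_lum, _ = _calibrated_base_shsv(pixels, calibration)
        rgb = np.round(np.repeat(lum[:, None], 3, axis=-1))
        clipped = 0
    im = _finish(source.raster, rgb, mask, -1, "grayscale", calibration)
    im.object_id = source.object_id
    im.shrink_lum, im.gamut_clip_count = s_lum, clipped
    return im


# --------------------------------------------------------------------------
# Oriented bars


@dataclass(frozen=True)
class BarSpec:
    """An oriented bar drawn analytically on a square canvas."""

    orientation_deg: float = 0.0  # in [0, 180)
    length_px: int = 300
    width_px: int = 60
    canvas_px: int = 400

    def __post_init__(self):
        half_diag = 0.5 * np.hypot(self.length_px, self.width_px)
        if 2.0 * half_diag > self.canvas_px:
            raise InputDomainError("bar does not fit inside the canvas at all orientations")


def bar_mask(spec: BarSpec) -> np.ndarray:
    """Boolean raster of the rotated-rectangle bar (point-in-rectangle test
    on pixel centers -- no raster rotation, so area is stable across
    orientations)."""
    n = spec.canvas_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x = xx - c
    y = yy - c
    theta = np.deg2rad(spec.orientation_deg)
    along = x * np.cos(theta) + y * np.sin(theta)
    across = -x * np.sin(theta) + y * np.cos(theta)
    return (np.abs(along) <= spec.length_px / 2.0) & (np.abs(across) <= spec.width_px / 2.0)


def default_bar_orientations(n: int = 12) -> np.ndarray:
    """Evenly spaced orientations on the 180-degree circle (endpoint excluded)."""
    return np.arange(n) * (180.0 / n)


def make_bars(
    calibration: CalibrationTarget,
    n_orientations: int = 12,
    n_hues: int = N_HUES_DEFAULT,
    template: BarSpec = BarSpec(),
) -> StimulusSet:
    """The oriented-bar grid: ``n_orientations`` x ``n_hues`` uniformly
    colored bars on a white canvas."""
    images = []
    for ori in default_bar_orientations(n_orientations):
        spec = BarSpec(ori, template.length_px, template.width_px, template.canvas_px)
        mask = bar_mask(spec)
        canvas = np.full((spec.canvas_px, spec.canvas_px, 3), 255, dtype=np.uint8)
        object_id = f"bar{int(round(ori * 100)):05d}"
        for h in range(n_hues):
            fill = silhouette_fill_color(calibration, h, n_hues)
            pixels = np.tile(fill, (int(mask.sum()), 1))
            im = _finish(canvas, pixels, mask, h, "bar", calibration)
            im.object_id = object_id
            images.append(im)
    return StimulusSet(images)


# --------------------------------------------------------------------------
# Subset selection


def select_dissimilar_subset(
    matrix: np.ndarray,
    k: int,
    ids: list | None = None,
    method: str = "greedy",
):
    """Pick ``k`` candidates minimizing mean pairwise similarity.

    ``greedy`` repeatedly drops the candidate with the highest mean
    similarity to the remaining set; ``exhaustive`` searches all C(n, k)
    subsets (oracle for small n).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-9):
        raise InputDomainError("similarity matrix must be square and symmetric")
    if k < 2 or k > n:
        raise InputDomainError(f"k must lie in [2, {n}]")
    if ids is None:
        ids = list(range(n))

    if method == "exhaustive":
        iu = np.triu_indices(k, 1)
        best, best_mean = None, np.inf
        for combo in itertools.combinations(range(n), k):
            sub = matrix[np.ix_(combo, combo)]
            m = sub[iu].mean()
            if m < best_mean:
                best, best_mean = combo, m
        return [ids[i] for i in best]

    keep = list(range(n))
    while len(keep) > k:
        sub = matrix[np.ix_(keep, keep)]
        mean_sim = (sub.sum(axis=1) - np.diag(sub)) / (len(keep) - 1)
        keep.pop(int(np.argmax(mean_sim)))
    return [ids[i] for i in keep]


def mean_pairwise(matrix: np.ndarray, indices=None) -> float:
    """Mean of the strict upper triangle, optionally restricted to a subset."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if indices is not None:
        matrix = matrix[np.ix_(indices, indices)]
    iu = np.triu_indices(matrix.shape[0], 1)
    return float(matrix[iu].mean())


def audit_calibration(image: StimulusImage) -> dict:
    """Recompute masked mean luminance/saturation from the quantized raster
    (the independent check that calibration survived 8-bit output)."""
    pixels = image.raster[image.mask].astype(np.float64)
    if image.calibration.space == "cieluv":
        luv = cm.srgb_to_luv(pixels)
        return {
            "mean_lum": float(luv[:, 0].mean()),
            "mean_sat": float(cm.chroma(luv).mean()),
        }
    lum, sat, _ = cm.synthetic_hsv_decompose(pixels)
    return {"mean_lum": float(lum.mean()), "mean_sat": float(sat.mean())}
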