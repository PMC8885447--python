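"""Illumination estimation and subtractive correction.

Plate imagers vignette: brightness falls off smoothly toward field edges.  An
illumination function is estimated per channel from all fields of an imaging
session by averaging them pixelwise and smoothing heavily (default smoothing
scale 500 px, read as an artifact-diameter / FWHM scale, i.e. Gaussian sigma =
scale / 2.355).  The function is then subtracted from each field, with a
min-preserving offset so a flat set corrects to zero residual *variation*
rather than zero signal, and the result clamped at zero.

Subtractive correction of a physically multiplicative vignette is a first-
order approximation that is accurate at this smoothing scale; see the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .plateio import FieldImage

__all__ = ["IlluminationFunction", "estimate_illumination", "apply_correction"]

#: conversion between a full-width smoothing scale and Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.355


@dataclass
class IlluminationFunction:
    """Smooth per-channel illumination surface for one imaging session."""

    channel: str
    surface: np.ndarray
    smoothing_scale_px: float = 500.0

    def __post_init__(self) -> None:
        self.surface = np.asarray(self.surface, dtype=np.float64)
        if self.surface.ndim != 2:
            raise ValueError("illumination surface must be 2-D")
        if np.any(self.surface < 0) or not np.all(np.isfinite(self.surface)):
            raise ValueError("illumination surface must be finite and nonnegative")

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.surface.astype(np.float32))

    @classmethod
    def from_tiff(cls, path: str | Path, channel: str,
                  smoothing_scale_px: float = 500.0) -> "IlluminationFunction":
        return cls(channel=channel, surface=np.asarray(tifffile.imread(path), dtype=float),
                   smoothing_scale_px=smoothing_scale_px)


def estimate_illumination(
    images: Sequence[FieldImage],
    smoothing_scale_px: float = 500.0,
    statistic: str = "median",
    n_iter: int = 15,
) -> IlluminationFunction:
    """Estimate the illumination function of a single-channel image set.

    The pixelwise *statistic* across all fields is smoothed with a Gaussian
    of sigma = smoothing_scale_px / 2.355.  The default statistic is the
    pixelwise median: cells are sparse and bright, so the median tracks the
    background illumination while the mean (available via
    ``statistic="mean"``) absorbs a lumpy average-cell-signal term that
    contaminates the surface.  A single smoothing pass attenuates the very
    trend it should capture (smoothing a smooth surface flattens it further),
    so the low-frequency component is extracted by iterated refinement,
    S <- S + G*(aggregate - S), which converges to the smoothing operator's
    low-pass fixed point: re-estimating on a corrected set then yields a
    near-flat function.  Deterministic; raises on mixed shapes or channels.
    """
    if len(images) == 0:
        raise ValueError("need at least one image to estimate illumination")
    channels = {img.key.channel for img in images}
    if len(channels) > 1:
        raise ValueError(f"mixed channels in illumination set: {sorted(channels)}")
    shapes = {img.shape for img in images}
    if len(shapes) > 1:
        raise ValueError(f"mixed image shapes in illumination set: {sorted(shapes)}")

    stack_agg = (
        np.mean([img.pixels for img in images], axis=0)
        if statistic == "mean"
        else np.median([img.pixels for img in images], axis=0)
    )
    sigma = smoothing_scale_px * FWHM_TO_SIGMA
    surface = np.zeros_like(stack_agg)
    for _ in range(max(1, n_iter)):
        surface = surface + ndimage.gaussian_filter(stack_agg - surface, sigma,
                                                    mode="nearest")
    return IlluminationFunction(channel=channels.pop(), surface=np.clip(surface, 0, None),
                                smoothing_scale_px=smoothing_scale_px)


def apply_correction(image: FieldImage, fn: IlluminationFunction) -> FieldImage:
    """Subtract the illumination function from a field, preserving brightness.

    output = clamp(image − surface + min(surface), 0): the min-preserving
    offset removes the spatial trend without nulling genuine signal in dim
    fields.  Raises on shape mismatch.
    """
    if image.shape != fn.surface.shape:
        raise ValueError(f"image shape {image.shape} != illumination shape {fn.surface.shape}")
    offset = float(fn.surface.min())
    corrected = np.clip(image.pixels - fn.surface + offset, 0.0, None)
    return FieldImage(key=image.key, pixels=corrected, bit_depth=image.bit_depth)


def correct_set(images: Sequence[FieldImage], fn: IlluminationFunction) -> list[FieldImage]:
    return [apply_correction(img, fn) for img in images]
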