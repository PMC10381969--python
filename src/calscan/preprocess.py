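"""Optional bilateral smoothing and spatial slicing of the ROI.

The bilateral filter averages each pixel with its neighbourhood, weighting
neighbours by both geometric proximity (Gaussian in pixel distance) and
photometric similarity (Gaussian in intensity difference). Edges — here,
the sharp upstroke of each transient — are therefore preserved while
shot noise is suppressed. A kernel size or sigma of zero disables
filtering entirely (exact no-op).

Slicing partitions the ROI into contiguous fixed-width spatial bands for
subcellular analysis; 2 um is the biologically motivated default width
because RyR2 release clusters are spaced roughly 2 um apart and can fire
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .io import LineScanImage, Roi

__all__ = [
    "SmoothingParams",
    "SliceSet",
    "bilateral_smooth",
    "slice_roi",
    "um_to_pixels",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Bilateral filter controls.

    ``kernel_size`` is the diameter (pixels) of the circular neighbourhood;
    ``sigma`` is used for both the spatial scale (pixels) and the range
    scale (intensity units) unless the advanced overrides are given.
    Intensity is in native units, so 8-bit and 16-bit images need very
    different sigmas.
    """

    kernel_size: int = 0
    sigma: float = 0.0
    sigma_spatial: float | None = None
    sigma_range: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_size < 0:
            raise ParameterError(f"kernel_size must be >= 0, got {self.kernel_size}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        for name in ("sigma_spatial", "sigma_range"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")

    @property
    def is_noop(self) -> bool:
        ss = self.sigma if self.sigma_spatial is None else self.sigma_spatial
        sr = self.sigma if self.sigma_range is None else self.sigma_range
        return self.kernel_size == 0 or ss == 0 or sr == 0


@dataclass(frozen=True)
class SliceSet:
    """Ordered, contiguous spatial slices tiling an ROI left to right."""

    slice_width: int
    slices: tuple[Roi, ...]
    has_partial: bool

    def __len__(self) -> int:
        return len(self.slices)


def bilateral_smooth(img: LineScanImage, params: SmoothingParams) -> LineScanImage:
    """Bilateral-filter the raster; identical shape and calibration.

    Every output value is a convex combination of input values within the
    neighbourhood, so the output stays inside the input's min-max envelope.
    With ``kernel_size == 0`` or either sigma zero the input raster is
    returned unchanged (value-identical copy).
    """
    if params.is_noop:
        return replace(img, intensity=img.intensity.copy())

    a = img.intensity
    r = params.kernel_size // 2
    if r == 0:
        return replace(img, intensity=a.copy())
    ss = params.sigma if params.sigma_spatial is None else params.sigma_spatial
    sr = params.sigma if params.sigma_range is None else params.sigma_range

    padded = np.pad(a, r, mode="reflect")
    num = np.zeros_like(a)
    den = np.zeros_like(a)
    h, w = a.shape
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di * di + dj * dj > r * r:
                continue  # circular neighbourhood of the given diameter
            shifted = padded[r + di : r + di + h, r + dj : r + dj + w]
            w_spatial = np.exp(-(di * di + dj * dj) / (2.0 * ss * ss))
            w_range = np.exp(-((shifted - a) ** 2) / (2.0 * sr * sr))
            weight = w_spatial * w_range
            num += weight * shifted
            den += weight
    return replace(img, intensity=num / den)


def slice_roi(roi: Roi, slice_width: int, *, drop_partial: bool = False) -> SliceSet:
    """Tile *roi* into spatial slices of ``slice_width`` pixels.

    Slices span the full time extent of the ROI. A narrower last slice
    (when the width does not divide the ROI) is kept by default and
    flagged via :attr:`SliceSet.has_partial`; ``drop_partial`` discards it.
    """
    if slice_width < 1:
        raise ParameterError(f"slice_width must be >= 1, got {slice_width}")
    slices: list[Roi] = []
    has_partial = False
    start = roi.pixel_start
    while start < roi.pixel_end:
        end = min(start + slice_width, roi.pixel_end)
        if end - start < slice_width:
            has_partial = True
            if drop_partial:
                break
        slices.append(Roi(start, end, roi.line_start, roi.line_end))
        start = end
    return SliceSet(slice_width=slice_width, slices=tuple(slices), has_partial=has_partial)


def um_to_pixels(width_um: float, img: LineScanImage) -> int:
    """Convert a physical slice width to pixels via the spatial calibration.

    Rounded to the nearest pixel, floored at 1 so a sub-pixel request still
    yields a usable slice.
    """
    if not width_um > 0:
        raise ParameterError(f"width_um must be > 0, got {width_um}")
    return max(1, round(width_um / img.um_per_pixel))
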