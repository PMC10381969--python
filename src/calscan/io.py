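"""Reading, writing and cropping of confocal line-scan rasters.

A line-scan recording repeatedly scans one spatial line across a cell;
stacking successive scans produces a space x time intensity image. The
in-memory convention throughout the package is

    rows    = time  (scan lines, line 0 at 0 ms)
    columns = space (pixels along the scanned line)

Images stored the other way round can be transposed at load time.
Intensities are kept in native units; no rescaling happens on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .errors import BoundsError, FormatError, ParameterError

__all__ = [
    "LineScanImage",
    "Roi",
    "load_image",
    "crop",
    "time_axis",
    "write_tiff",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PIL_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class LineScanImage:
    """A calibrated space x time fluorescence raster.

    Parameters
    ----------
    intensity:
        2-D array indexed ``(line, pixel)``; finite, non-negative.
    ms_per_line:
        Milliseconds per scan line (> 0). Line ``t`` was acquired at
        ``t * ms_per_line`` ms.
    um_per_pixel:
        Micrometers per spatial pixel (> 0). Only needed to convert
        physical slice widths (e.g. 2 um RyR2 cluster spacing) to pixels.
    source_name:
        Identifier of the originating file or generator.
    """

    intensity: np.ndarray
    ms_per_line: float
    um_per_pixel: float = 1.0
    source_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise BoundsError(
                f"intensity raster must be a non-empty 2-D array, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ParameterError("intensity raster contains non-finite values")
        if arr.min() < 0:
            raise ParameterError("intensity raster contains negative values")
        if not self.ms_per_line > 0:
            raise ParameterError(f"ms_per_line must be > 0, got {self.ms_per_line}")
        if not self.um_per_pixel > 0:
            raise ParameterError(f"um_per_pixel must be > 0, got {self.um_per_pixel}")
        object.__setattr__(self, "intensity", arr)

    @property
    def n_lines(self) -> int:
        """Number of time samples (rows)."""
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        """Number of spatial positions along the scanned line (columns)."""
        return self.intensity.shape[1]

    def time_axis(self) -> np.ndarray:
        """Acquisition time of each line in ms (line 0 -> 0 ms)."""
        return np.arange(self.n_lines) * self.ms_per_line

    def full_roi(self) -> "Roi":
        return Roi(0, self.n_pixels, 0, self.n_lines)


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest, 0-based half-open in both axes."""

    pixel_start: int
    pixel_end: int
    line_start: int
    line_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.pixel_start < self.pixel_end):
            raise BoundsError(
                f"invalid pixel bounds [{self.pixel_start}, {self.pixel_end})"
            )
        if not (0 <= self.line_start < self.line_end):
            raise BoundsError(
                f"invalid line bounds [{self.line_start}, {self.line_end})"
            )

    @property
    def width(self) -> int:
        return self.pixel_end - self.pixel_start

    @property
    def n_lines(self) -> int:
        return self.line_end - self.line_start

    def validate_against(self, img: LineScanImage) -> None:
        if self.pixel_end > img.n_pixels or self.line_end > img.n_lines:
            raise BoundsError(
                f"ROI pixels [{self.pixel_start},{self.pixel_end}) x "
                f"lines [{self.line_start},{self.line_end}) exceeds image "
                f"{img.n_lines} lines x {img.n_pixels} pixels"
            )


def load_image(
    path: str | os.PathLike,
    *,
    ms_per_line: float = 1.0,
    um_per_pixel: float = 1.0,
    channel_policy: str | int = "mean",
    transpose: bool = False,
) -> LineScanImage:
    """Read a TIFF / PNG / JPG line-scan image from disk.

    Multi-channel (RGB) inputs are reduced to a scalar intensity per
    ``channel_policy``: ``"mean"`` averages channels, an integer selects
    one channel. Values are preserved as stored.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    suffix = os.path.splitext(path)[1].lower()
    try:
        if suffix in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        elif suffix in _PIL_SUFFIXES:
            with Image.open(path) as im:
                arr = np.asarray(im)
        else:
            raise FormatError(f"unsupported image format '{suffix}' for {path}")
    except FormatError:
        raise
    except (UnidentifiedImageError, ValueError, OSError) as exc:
        raise FormatError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel_policy == "mean":
            arr = arr.astype(np.float64).mean(axis=-1)
        elif isinstance(channel_policy, int):
            if not 0 <= channel_policy < arr.shape[-1]:
                raise ParameterError(
                    f"channel index {channel_policy} out of range for "
                    f"{arr.shape[-1]} channels"
                )
            arr = arr[..., channel_policy]
        else:
            raise ParameterError(f"unknown channel_policy {channel_policy!r}")
    elif arr.ndim != 2:
        raise BoundsError(f"image {path} has unsupported dimensionality {arr.ndim}")
    if arr.size == 0:
        raise BoundsError(f"image {path} is empty")
    if transpose:
        arr = arr.T
    return LineScanImage(
        intensity=arr.astype(np.float64),
        ms_per_line=ms_per_line,
        um_per_pixel=um_per_pixel,
        source_name=os.path.basename(path),
    )


def crop(img: LineScanImage, roi: Roi) -> LineScanImage:
    """Return the sub-raster covered by *roi*; calibration is unchanged."""
    roi.validate_against(img)
    sub = img.intensity[
        roi.line_start : roi.line_end, roi.pixel_start : roi.pixel_end
    ].copy()
    return replace(img, intensity=sub)


def time_axis(img: LineScanImage) -> np.ndarray:
    """Time in ms of each scan line: ``t * ms_per_line``."""
    return img.time_axis()


def write_tiff(img: LineScanImage, path: str | os.PathLike) -> str:
    """Write the raster as a single-page 16-bit grayscale TIFF.

    Values are rounded and clipped to the uint16 range; this is the only
    place the package quantizes intensities.
    """
    path = os.fspath(path)
    data = np.clip(np.rint(img.intensity), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    return path
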