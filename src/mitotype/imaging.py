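"""Micrograph I/O, rotation to the contraction axis, binarization, cleanup.

The pipeline mirrors the standard light-microscopy workflow for muscle
mitochondrial networks: the raw channel is rotated so the muscle contraction
axis lies along the image horizontal, binarized (Otsu by default), and
optionally despeckled with a local-median outlier filter before orientation
or content analysis.

Angle convention: degrees, counterclockwise positive as displayed,
0 deg = image horizontal; orientation values live on (-90, 90].
Coordinates are 0-based, row-major; rotation is about the image center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage as ndi
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "Image2D",
    "BinaryMask",
    "read_image",
    "write_image",
    "write_mask",
    "rotate_to_axis",
    "binarize",
    "otsu_threshold",
    "remove_outliers",
]


@dataclass
class Image2D:
    """A 2D grayscale raster with acquisition metadata.

    Parameters
    ----------
    pixels : (H, W) ndarray
        Nonnegative finite intensities. Stored as float64 internally.
    bit_depth : {8, 16, "float"}
        Nominal depth of the source data; used when writing to disk.
    pixel_size_um : float, optional
        Physical pixel size in micrometers per pixel.
    contraction_axis_deg : float
        Angle of the muscle contraction axis relative to the image
        horizontal (CCW positive).
    """

    pixels: np.ndarray
    bit_depth: int | str = "float"
    pixel_size_um: float | None = None
    contraction_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a 2D H x W array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0:
            raise ValueError("pixel intensities must be >= 0")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean foreground mask plus a record of how it was produced."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


def _select_channel(arr: np.ndarray, channel_index: int) -> np.ndarray:
    if arr.ndim == 2:
        if channel_index not in (0, None):
            raise IndexError(
                f"channel {channel_index} requested but image has a single channel"
            )
        return arr
    if arr.ndim == 3:
        # channels-first (C, H, W) for multi-page TIFF, channels-last for RGB(A)
        axis = 0 if arr.shape[0] <= 8 else 2
        n = arr.shape[axis]
        if not 0 <= channel_index < n:
            raise IndexError(f"channel {channel_index} out of range for {n}-channel image")
        return np.take(arr, channel_index, axis=axis)
    raise ValueError(f"unsupported image dimensionality: {arr.ndim}")


def read_image(
    path: str | Path,
    channel_index: int = 0,
    *,
    pixel_size_um: float | None = None,
    contraction_axis_deg: float = 0.0,
) -> Image2D:
    """Read a single- or multi-channel TIFF/PNG and return one grayscale channel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    channel = _select_channel(arr, channel_index)
    if np.issubdtype(channel.dtype, np.integer):
        bit_depth: int | str = 16 if channel.dtype.itemsize >= 2 else 8
    else:
        bit_depth = "float"
    return Image2D(
        pixels=channel.astype(np.float64),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        contraction_axis_deg=contraction_axis_deg,
    )


def write_image(path: str | Path, image: Image2D) -> None:
    """Write an image as 16-bit grayscale TIFF (or PNG by extension)."""
    path = Path(path)
    px = image.pixels
    if image.bit_depth == 8:
        data = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    else:
        data = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Store a binary mask as 8-bit TIFF with values {0, 255}."""
    tifffile.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))


def rotate_to_axis(image: Image2D) -> Image2D:
    """Rotate so the contraction axis is horizontal (axis angle becomes 0).

    The image is rotated by ``-contraction_axis_deg`` about its center.
    Multiples of 90 deg are pixel-exact index permutations; other angles use
    bilinear interpolation with background fill 0.
    """
    angle = -float(image.contraction_axis_deg)
    if angle % 360 == 0:
        rotated = image.pixels.copy()
    elif angle % 90 == 0:
        rotated = np.rot90(image.pixels, k=int(angle // 90) % 4).copy()
    else:
        rotated = _sk_rotate(
            image.pixels, angle, resize=False, order=1, mode="constant", cval=0.0,
            preserve_range=True,
        )
        rotated = np.clip(rotated, 0.0, None)
    return replace(image, pixels=rotated, contraction_axis_deg=0.0)


def otsu_threshold(pixels: np.ndarray) -> float:
    """Otsu's threshold by exhaustive between-class variance maximization.

    Candidate thresholds are the distinct observed intensity levels (float
    images are first quantized onto 256 levels spanning the intensity range).
    The returned value t partitions pixels into background (< t) and
    foreground (>= t); among ties the lowest t is returned.
    """
    px = np.asarray(pixels, dtype=np.float64).ravel()
    levels = np.unique(px)
    if levels.size < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    if levels.size > 256:
        edges = np.linspace(px.min(), px.max(), 257)
        counts, _ = np.histogram(px, bins=edges)
        levels = edges[:-1]
    else:
        counts = np.array([(px == v).sum() for v in levels], dtype=np.int64)

    total = counts.sum()
    w_bg = np.cumsum(counts)[:-1]                      # pixels strictly below candidate
    w_fg = total - w_bg
    csum = np.cumsum(counts * levels)[:-1]
    mu_bg = np.divide(csum, w_bg, out=np.zeros_like(csum, dtype=float), where=w_bg > 0)
    mu_fg = (counts * levels).sum() - csum
    mu_fg = np.divide(mu_fg, w_fg, out=np.zeros_like(csum, dtype=float), where=w_fg > 0)
    between = w_bg * w_fg * (mu_bg - mu_fg) ** 2
    # candidate i corresponds to threshold = levels[i + 1] (mask = px >= t)
    best = int(np.argmax(between))
    return float(levels[best + 1])


def binarize(
    image: Image2D | np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Threshold an image; a pixel is foreground iff intensity >= threshold.

    ``method="otsu"`` selects the threshold maximizing between-class variance;
    a constant image is flagged degenerate (all-false mask plus a warning).
    ``method="fixed"`` uses the supplied threshold.
    """
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    if method == "otsu":
        try:
            t = otsu_threshold(px)
        except ValueError:
            warnings.warn("constant image: returning empty mask", stacklevel=2)
            return BinaryMask(
                np.zeros(px.shape, dtype=bool),
                provenance={"method": "otsu", "value": None, "degenerate": True},
            )
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        t = float(threshold)
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    return BinaryMask(px >= t, provenance={"method": method, "value": t})


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx * xx + yy * yy) <= radius * radius


def remove_outliers(data, radius_px: int = 3, n_sd: float = 2.0, *, abs_threshold: float | None = None):
    """Replace pixels deviating from their local median by that median.

    A pixel is replaced by the median of its radius-``radius_px`` disk
    neighborhood iff it deviates from that median by more than
    ``n_sd`` x the global standard deviation of the input (or by more than
    ``abs_threshold`` when given, matching the absolute-threshold despeckle
    convention of common image-analysis tools). Accepts and returns
    Image2D, BinaryMask, or a bare ndarray.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if n_sd <= 0:
        raise ValueError("n_sd must be > 0")

    if isinstance(data, Image2D):
        arr, kind = data.pixels, "image"
    elif isinstance(data, BinaryMask):
        arr, kind = data.pixels.astype(np.float64), "mask"
    else:
        arr, kind = np.asarray(data, dtype=np.float64), "array"
    if radius_px >= min(arr.shape):
        raise ValueError("radius_px must be smaller than the image extent")

    med = ndi.median_filter(arr, footprint=_disk_footprint(radius_px), mode="reflect")
    cutoff = abs_threshold if abs_threshold is not None else n_sd * float(arr.std())
    out = np.where(np.abs(arr - med) > cutoff, med, arr)

    if kind == "image":
        return replace(data, pixels=out)
    if kind == "mask":
        return BinaryMask(out >= 0.5, provenance={**data.provenance, "remove_outliers": radius_px})
    return out
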