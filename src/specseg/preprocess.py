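"""Co-registration, resampling, band-ratio normalization and tissue masking.

Raw inputs are single-wavenumber IR absorbance rasters (1238, 1546 and
1658 cm^-1, acquired at 2 um/pixel) and a darkfield visible raster at a finer
pixel pitch.  This module brings everything onto a common 1 um analysis grid,
normalizes the Amide III (1238) and Amide II (1546) bands to the Amide I band
(1658) to cancel section thickness/density, and assembles the resulting
two-ratio + darkfield channel stack together with a tissue mask.

Conventions: grids are row-major, 0-based; pixel (i, j) of a raster with pixel
size ``s`` is centered at physical coordinate ((i + 0.5) s, (j + 0.5) s) um.
Intensity resampling is bilinear, label/mask resampling nearest-neighbor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes

__all__ = [
    "BandImage",
    "MultimodalStack",
    "LabelMap",
    "ChannelStats",
    "NormalizationResult",
    "CLASS_NAMES",
    "resample",
    "register_translation",
    "shift_raster",
    "tissue_mask",
    "normalize_to_amide1",
    "assemble_stack",
]

#: Semantic class scheme shared across the pipeline.  0 is non-tissue
#: background and is never annotated or scored.
CLASS_NAMES = {
    0: "background",
    1: "non-epithelium",
    2: "dysplastic epithelium",
    3: "non-dysplastic epithelium",
}

KNOWN_WAVENUMBERS = (1238.0, 1546.0, 1658.0)

#: Amide I absorbance floor below which the band ratio is considered
#: unreliable (detector-noise amplification); such pixels leave the mask.
A1658_FLOOR = 1e-3


class ParameterError(ValueError):
    """Invalid argument to a preprocessing operation."""


class DegenerateInputError(ValueError):
    """Input on which the operation is mathematically undefined."""


@dataclass(frozen=True)
class BandImage:
    """One single-wavenumber IR absorbance raster.

    Parameters
    ----------
    pixels : 2-D float array of non-negative absorbance (AU).
    wavenumber : band position in cm^-1.
    pixel_size : pixel pitch in um.
    """

    pixels: np.ndarray
    wavenumber: float
    pixel_size: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError("BandImage.pixels must be 2-D")
        if not np.all(np.isfinite(px)):
            raise ParameterError("BandImage.pixels must be finite")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px.astype(np.float32, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def resampled(self, target_pixel_size: float) -> "BandImage":
        out = resample(self.pixels, self.pixel_size, target_pixel_size, mode="intensity")
        return BandImage(out, self.wavenumber, target_pixel_size)


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class raster of {0, 1, 2, 3} on the 1 um grid."""

    labels: np.ndarray
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ParameterError("labels must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ParameterError("labels must be an integer raster")
        vals = np.unique(lab)
        if not np.all(np.isin(vals, [0, 1, 2, 3])):
            raise ParameterError(f"illegal label values: {vals}")
        object.__setattr__(self, "labels", lab.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ChannelStats:
    """Per-channel standardization statistics over masked training pixels."""

    mean: np.ndarray  # (C,)
    sd: np.ndarray  # (C,)
    channel_names: tuple[str, ...] = ("r1238", "r1546", "df")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "channel_names": list(self.channel_names),
                    "mean": [float(m) for m in self.mean],
                    "sd": [float(s) for s in self.sd],
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelStats":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            sd=np.asarray(d["sd"], dtype=np.float64),
            channel_names=tuple(d["channel_names"]),
        )


@dataclass
class MultimodalStack:
    """Co-registered channel stack on a shared 1 um grid.

    channels are ordered (r1238, r1546, df) where r_b = A_b / A_1658.  Ratio
    channels are exactly 0 outside ``tissue_mask`` and clipped to a configured
    range inside it.  ``stats`` holds the standardization statistics to apply
    at train/inference time (computed on training sections, reused verbatim on
    test sections).
    """

    channels: np.ndarray  # (3, H, W) float32
    tissue_mask: np.ndarray  # (H, W) bool
    section_id: str = ""
    channel_names: tuple[str, ...] = ("r1238", "r1546", "df")
    stats: ChannelStats | None = None
    lineage: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.channels.ndim != 3:
            raise ParameterError("channels must be (C, H, W)")
        if self.channels.shape[1:] != self.tissue_mask.shape:
            raise ParameterError("channels and tissue_mask grid mismatch")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.tissue_mask.shape

    def standardized(self) -> np.ndarray:
        """Channels standardized with the *stored* statistics (z-scores)."""
        if self.stats is None:
            raise ParameterError("stack has no standardization stats")
        mean = self.stats.mean.astype(np.float32)[:, None, None]
        sd = self.stats.sd.astype(np.float32)[:, None, None]
        return (self.channels - mean) / sd


@dataclass
class NormalizationResult:
    r1238: np.ndarray
    r1546: np.ndarray
    mask: np.ndarray  # mask after removal of low-Amide-I pixels
    n_floor_removed: int


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _target_shape(shape: tuple[int, int], src: float, tgt: float) -> tuple[int, int]:
    return (int(round(shape[0] * src / tgt)), int(round(shape[1] * src / tgt)))


def resample(
    image: np.ndarray,
    pixel_size: float,
    target_pixel_size: float,
    mode: str = "intensity",
) -> np.ndarray:
    """Resample a raster to a new pixel pitch, preserving physical extent.

    mode="intensity" interpolates bilinearly; mode="label" picks the
    nearest-neighbor source pixel (never creating new label values) and is
    only valid for integer rasters.
    """
    image = np.asarray(image)
    if pixel_size <= 0 or target_pixel_size <= 0:
        raise ParameterError("pixel sizes must be positive")
    if mode not in ("intensity", "label"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "label" and not np.issubdtype(image.dtype, np.integer):
        raise ParameterError("label mode requires an integer raster")
    if pixel_size == target_pixel_size:
        return image.copy()

    h, w = image.shape
    ho, wo = _target_shape(image.shape, pixel_size, target_pixel_size)
    # output pixel centers in source fractional-index coordinates
    ci = (np.arange(ho) + 0.5) * target_pixel_size / pixel_size - 0.5
    cj = (np.arange(wo) + 0.5) * target_pixel_size / pixel_size - 0.5
    if mode == "label":
        ii = np.clip(np.round(ci).astype(np.int64), 0, h - 1)
        jj = np.clip(np.round(cj).astype(np.int64), 0, w - 1)
        return image[np.ix_(ii, jj)]
    grid = np.meshgrid(ci, cj, indexing="ij")
    out = ndimage.map_coordinates(
        image.astype(np.float32), np.stack(grid), order=1, mode="nearest"
    )
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def shift_raster(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer-pixel shift with zero fill (no wrap-around)."""
    dy, dx = int(shift[0]), int(shift[1])
    out = np.zeros_like(image)
    h, w = image.shape
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = image[ys_src, xs_src]
    return out


def register_translation(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[int, int, np.ndarray]:
    """Recover the integer translation aligning ``moving`` onto ``fixed``.

    Returns (shift_y, shift_x, registered) where applying the shift (with zero
    fill at the exposed edges) maximizes the cross-correlation with ``fixed``.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape:
        raise ParameterError("moving and fixed must share a pixel grid")
    if moving.std() == 0 or fixed.std() == 0:
        raise DegenerateInputError("correlation undefined for a constant raster")
    f = np.fft.fft2(fixed - fixed.mean())
    m = np.fft.fft2(moving - moving.mean())
    corr = np.fft.ifft2(f * np.conj(m)).real
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    h, w = corr.shape
    dy = peak[0] if peak[0] <= h // 2 else peak[0] - h
    dx = peak[1] if peak[1] <= w // 2 else peak[1] - w
    return int(dy), int(dx), shift_raster(moving, (dy, dx)).astype(fixed.dtype)


# ---------------------------------------------------------------------------
# masking and normalization
# ---------------------------------------------------------------------------

def tissue_mask(
    a1658: np.ndarray | BandImage,
    method: str = "otsu",
    threshold: float | None = None,
    min_hole_area: int = 64,
) -> np.ndarray:
    """Tissue/background mask from the Amide I (1658 cm^-1) absorbance.

    Amide I is the strongest, most spatially uniform protein band, so a simple
    global threshold (Otsu by default) separates tissue from bare substrate.
    Holes smaller than ``min_hole_area`` pixels are filled.
    """
    img = a1658.pixels if isinstance(a1658, BandImage) else np.asarray(a1658)
    if method == "otsu":
        if img.max() == img.min():
            raise DegenerateInputError("Otsu threshold undefined on a constant image")
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ParameterError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ParameterError(f"unknown mask method {method!r}")
    mask = img > thr
    if min_hole_area > 1 and mask.any():
        try:
            mask = remove_small_holes(mask, max_size=min_hole_area)
        except TypeError:  # scikit-image < 0.26 spells it area_threshold
            mask = remove_small_holes(mask, area_threshold=min_hole_area)
    return mask


def normalize_to_amide1(
    a1238: np.ndarray,
    a1546: np.ndarray,
    a1658: np.ndarray,
    mask: np.ndarray,
    clip_max: float = 3.0,
    a1658_floor: float = A1658_FLOOR,
) -> NormalizationResult:
    """Band-ratio normalization: r_b = A_b / A_1658 inside the tissue mask.

    Dividing by the Amide I band cancels the multiplicative section
    thickness/density field, leaving chemically meaningful contrast.  Pixels
    whose Amide I absorbance falls below ``a1658_floor`` are removed from the
    mask (the ratio there amplifies noise) and counted in the result.  Ratios
    are clipped to [0, clip_max]; outside the mask they are exactly 0.
    """
    a1238, a1546, a1658 = (np.asarray(a, dtype=np.float64) for a in (a1238, a1546, a1658))
    mask = np.asarray(mask, dtype=bool)
    if not (a1238.shape == a1546.shape == a1658.shape == mask.shape):
        raise ParameterError("band/mask shape mismatch")
    good = mask & (a1658 >= a1658_floor)
    n_removed = int(mask.sum() - good.sum())
    r1238 = np.zeros_like(a1238, dtype=np.float64)
    r1546 = np.zeros_like(a1546, dtype=np.float64)
    r1238[good] = np.clip(a1238[good] / a1658[good], 0.0, clip_max)
    r1546[good] = np.clip(a1546[good] / a1658[good], 0.0, clip_max)
    if not (np.all(np.isfinite(r1238)) and np.all(np.isfinite(r1546))):
        raise AssertionError("non-finite ratio despite Amide I floor")
    return NormalizationResult(r1238, r1546, good, n_removed)


def assemble_stack(
    r1238: np.ndarray,
    r1546: np.ndarray,
    df: np.ndarray,
    mask: np.ndarray,
    labels: LabelMap | None = None,
    stats: ChannelStats | None = None,
    section_id: str = "",
) -> tuple[MultimodalStack, LabelMap | None]:
    """Assemble the (r1238, r1546, df) stack on the shared 1 um grid.

    If ``stats`` is None the per-channel mean/sd over masked pixels is computed
    here and stored on the stack; otherwise the given statistics (e.g. from
    the training sections) are attached unchanged for reuse at inference.
    """
    arrs = [np.asarray(a, dtype=np.float32) for a in (r1238, r1546, df)]
    mask = np.asarray(mask, dtype=bool)
    shapes = {a.shape for a in arrs} | {mask.shape}
    if labels is not None:
        shapes.add(labels.shape)
    if len(shapes) != 1:
        raise ParameterError(f"grid mismatch among stack inputs: {shapes}")
    channels = np.stack(arrs)
    if stats is None:
        inside = channels[:, mask]
        sd = inside.std(axis=1)
        sd = np.where(sd > 0, sd, 1.0)
        stats = ChannelStats(mean=inside.mean(axis=1).astype(np.float64), sd=sd.astype(np.float64))
    stack = MultimodalStack(
        channels=channels,
        tissue_mask=mask,
        section_id=section_id,
        stats=stats,
        lineage={"channels": ["A1238/A1658", "A1546/A1658", "darkfield"]},
    )
    return stack, labels


# ---------------------------------------------------------------------------
# I/O helpers (float32 TIFF with resolution tags, JSON stats)
# ---------------------------------------------------------------------------

def write_band_tiff(path: str | Path, image: np.ndarray, pixel_size_um: float) -> None:
    """Write a float32 raster with the pixel pitch in TIFF resolution tags."""
    px_per_cm = 10_000.0 / pixel_size_um
    tifffile.imwrite(
        str(path),
        np.asarray(image, dtype=np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_band_tiff(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a raster and its pixel pitch (um) back from the resolution tags."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        image = page.asarray()
        xres = page.tags["XResolution"].value  # rational (num, den), px per cm
        px_per_cm = xres[0] / xres[1]
    return image, 10_000.0 / px_per_cm
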