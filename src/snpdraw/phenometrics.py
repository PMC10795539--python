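"""Silhouette-based fruit shape descriptors.

Works on any single-fruit RGB image — originals, decoded genotype means, or
SNP-predicted drawings. The descriptors are deliberately simple bounding-
geometry ratios:

* FSI (fruit shape index): silhouette height / width.
* SR (shoulder ratio): width near the top / width near the bottom. The
  extreme rows of a silhouette have near-zero width, so widths are read at
  an inset (default 10% of the height) from each end.
* a five-class shape category (flat ... oblong) obtained by thresholding
  FSI at four configurable cut points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .synthetic_fruit import FruitImage

__all__ = [
    "SilhouetteMask",
    "ShapeMetrics",
    "CATEGORIES",
    "DEFAULT_FSI_THRESHOLDS",
    "extract_silhouette",
    "fruit_shape_index",
    "shoulder_ratio",
    "classify_shape",
    "measure_image",
]

CATEGORIES = ("flat", "flat-globose", "globose", "oval", "oblong")

# FSI cut points between the five classes; the literature does not fix
# universal values, so these defaults are configurable and echoed in reports.
DEFAULT_FSI_THRESHOLDS = (0.85, 0.95, 1.05, 1.20)


@dataclass
class SilhouetteMask:
    """Binary foreground mask of a single fruit."""

    mask: np.ndarray  # (H, W) bool
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")
        if not self.mask.any():
            raise ValueError("empty silhouette mask")


@dataclass(frozen=True)
class ShapeMetrics:
    fsi: float
    sr: float
    category: str


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, FruitImage):
        return image.pixels
    return np.asarray(image)


def extract_silhouette(
    image,
    threshold_policy: str | float = "otsu",
    provenance: str = "original",
) -> SilhouetteMask:
    """Threshold a fruit image into a single-component binary silhouette.

    Greyscale conversion (channel mean), automatic Otsu threshold (or a
    fixed numeric threshold, e.g. 0.5 for soft decoder outputs), keep the
    largest connected component, fill holes.
    """
    pixels = _as_pixels(image)
    grey = pixels.mean(axis=2) if pixels.ndim == 3 else pixels
    if float(grey.max() - grey.min()) < 0.05:
        raise ValueError("no fruit distinguishable from background")
    if threshold_policy == "otsu":
        # a coarse histogram keeps near-identical background levels (e.g.
        # native canvas vs resize padding) in one bin; if the "foreground"
        # still swallows most of the frame the split was background-internal,
        # so fall back to the mid-range threshold
        thr = float(threshold_otsu(grey, nbins=64))
        if (grey > thr).mean() > 0.8:
            thr = float((grey.min() + grey.max()) / 2.0)
    else:
        thr = float(threshold_policy)
    fg = grey > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels, n = label(fg, return_num=True, connectivity=2)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == int(np.argmax(sizes))
    fg = ndimage.binary_fill_holes(fg)
    return SilhouetteMask(mask=fg, provenance=provenance)


def _extents(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def fruit_shape_index(mask: SilhouetteMask) -> float:
    """Height extent over width extent of the silhouette bounding box."""
    r0, r1, c0, c1 = _extents(mask.mask)
    return (r1 - r0 + 1) / (c1 - c0 + 1)


def _row_width(mask: np.ndarray, row: int) -> int:
    cols = np.flatnonzero(mask[row])
    if cols.size == 0:
        raise ValueError(f"zero width at measurement row {row}")
    return int(cols[-1] - cols[0] + 1)


def shoulder_ratio(mask: SilhouetteMask, offset_fraction: float = 0.10) -> float:
    """Width at the top inset row over width at the bottom inset row."""
    if not 0.0 < offset_fraction < 0.5:
        raise ValueError("offset_fraction must lie in (0, 0.5)")
    r0, r1, _, _ = _extents(mask.mask)
    height = r1 - r0 + 1
    inset = int(round(offset_fraction * height))
    top_row = min(r0 + inset, r1)
    bottom_row = max(r1 - inset, r0)
    return _row_width(mask.mask, top_row) / _row_width(mask.mask, bottom_row)


def classify_shape(
    fsi: float, thresholds: tuple[float, float, float, float] = DEFAULT_FSI_THRESHOLDS
) -> str:
    """Map an FSI value to one of the five shape classes.

    Intervals are left-closed: fsi < t1 -> flat; [t1,t2) -> flat-globose;
    [t2,t3) -> globose; [t3,t4) -> oval; >= t4 -> oblong.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (4,) or not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be 4 strictly increasing cut points")
    return CATEGORIES[int(np.searchsorted(t, fsi, side="right"))]


def measure_image(
    image,
    threshold_policy: str | float = "otsu",
    offset_fraction: float = 0.10,
    thresholds: tuple[float, float, float, float] = DEFAULT_FSI_THRESHOLDS,
    provenance: str = "original",
) -> ShapeMetrics:
    """Convenience: silhouette -> (FSI, SR, category) in one call."""
    sil = extract_silhouette(image, threshold_policy, provenance)
    fsi = fruit_shape_index(sil)
    return ShapeMetrics(
        fsi=fsi,
        sr=shoulder_ratio(sil, offset_fraction),
        category=classify_shape(fsi, thresholds),
    )
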