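"""Image loading and genotype-level dataset splitting.

The split unit is the genotype, never the image: all replicate images of a
genotype land on the same side of the train/validation partition, and the
partition is stratified by shape class so both sides preserve the overall
shape distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phenometrics import DEFAULT_FSI_THRESHOLDS, classify_shape, measure_image
from .synthetic_fruit import BACKGROUND_GREY, FruitImage

__all__ = ["DatasetSplit", "load_image_dir", "genotype_strata", "stratified_split"]

logger = logging.getLogger(__name__)

_EXTS = {".png", ".jpg", ".jpeg"}


def _pad_to_square(arr: np.ndarray, fill: float) -> np.ndarray:
    h, w = arr.shape[:2]
    size = max(h, w)
    out = np.full((size, size, 3), fill, dtype=arr.dtype)
    r0 = (size - h) // 2
    c0 = (size - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = arr
    return out


def load_image_dir(path: str | Path, target_size: int = 300) -> list[FruitImage]:
    """Load all ``<genotypeID>_<imageID>.png|jpg`` images in a directory.

    Non-square inputs are padded to a square with the background colour
    before bilinear resizing, so the aspect ratio — and therefore the fruit
    shape index — survives the resize.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _EXTS)
    if not files:
        raise ValueError(f"no PNG/JPEG images found in {path}")
    images: list[FruitImage] = []
    for f in files:
        stem = f.stem
        if "_" not in stem:
            raise ValueError(
                f"cannot parse genotype from filename {f.name!r}; expected "
                "<genotypeID>_<imageID>.<ext>"
            )
        genotype_id, image_id = stem.rsplit("_", 1)
        arr = np.asarray(Image.open(f).convert("RGB"), dtype=np.float64) / 255.0
        arr = _pad_to_square(arr, BACKGROUND_GREY)
        if arr.shape[0] != target_size:
            img = Image.fromarray((arr * 255).round().astype(np.uint8))
            img = img.resize((target_size, target_size), Image.BILINEAR)
            arr = np.asarray(img, dtype=np.float64) / 255.0
        images.append(FruitImage(pixels=arr, genotype_id=genotype_id, image_id=image_id))
    return images


@dataclass
class DatasetSplit:
    """Genotype-level train/validation partition."""

    train_genotypes: set[str]
    val_genotypes: set[str]
    train_fraction: float

    def __post_init__(self) -> None:
        if self.train_genotypes & self.val_genotypes:
            raise ValueError("train and validation genotypes overlap")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    def partition_images(
        self, images: list[FruitImage]
    ) -> tuple[list[FruitImage], list[FruitImage]]:
        train = [im for im in images if im.genotype_id in self.train_genotypes]
        val = [im for im in images if im.genotype_id in self.val_genotypes]
        unknown = {
            im.genotype_id
            for im in images
            if im.genotype_id not in self.train_genotypes | self.val_genotypes
        }
        if unknown:
            raise ValueError(f"images of genotypes outside the split: {sorted(unknown)[:5]}")
        return train, val

    def to_manifest(self, path: str | Path) -> None:
        rows = [(g, "train") for g in sorted(self.train_genotypes)] + [
            (g, "val") for g in sorted(self.val_genotypes)
        ]
        pd.DataFrame(rows, columns=["genotype_id", "partition"]).to_csv(path, index=False)


def genotype_strata(
    images: list[FruitImage],
    thresholds: tuple[float, float, float, float] = DEFAULT_FSI_THRESHOLDS,
) -> dict[str, str]:
    """Shape class per genotype, from the mean FSI of its images."""
    fsi_by_geno: dict[str, list[float]] = {}
    for im in images:
        fsi_by_geno.setdefault(im.genotype_id, []).append(measure_image(im).fsi)
    return {
        g: classify_shape(float(np.mean(v)), thresholds) for g, v in fsi_by_geno.items()
    }


def stratified_split(
    images: list[FruitImage],
    train_fraction: float = 0.9,
    strata: dict[str, str] | None = None,
    seed: int = 0,
) -> DatasetSplit:
    """Split genotypes into train/validation, preserving each stratum's
    proportion to within integer rounding.

    ``strata`` maps genotype -> label (typically the five-class shape
    category from :func:`genotype_strata`, which is computed here when not
    supplied). A stratum with a single genotype goes to train with a logged
    warning.
    """
    if strata is None:
        strata = genotype_strata(images)
    genotypes = sorted({im.genotype_id for im in images})
    missing = [g for g in genotypes if g not in strata]
    if missing:
        raise ValueError(f"genotypes without a stratum label: {missing[:5]}")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    val: set[str] = set()
    by_stratum: dict[str, list[str]] = {}
    for g in genotypes:
        by_stratum.setdefault(strata[g], []).append(g)
    for label in sorted(by_stratum):
        members = by_stratum[label]
        if len(members) == 1:
            logger.warning(
                "stratum %r has a single genotype (%s); assigning it to train",
                label,
                members[0],
            )
            train.add(members[0])
            continue
        order = rng.permutation(len(members))
        n_train = int(train_fraction * len(members) + 0.5)
        # keep both sides nonempty within a multi-genotype stratum
        n_train = min(max(n_train, 1), len(members) - 1)
        for rank, idx in enumerate(order):
            (train if rank < n_train else val).add(members[idx])
    return DatasetSplit(train, val, train_fraction)
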