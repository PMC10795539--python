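"""Parametric fruit silhouettes and simulated genotype-phenotype populations.

Real single-fruit image collections with matched SNP genotypes are rarely
redistributable, so this module provides a fully controllable stand-in:
a superellipse fruit with a linear vertical taper (realising a target
shoulder ratio) and optional sinusoidal lobing, plus a Hardy-Weinberg
population in which a handful of causal SNPs additively shift the fruit
shape index (FSI). Because the generative parameters are known exactly,
every downstream stage — silhouette metrics, autoencoder reconstruction,
SNP-to-embedding regression — can be validated by round trip.

Conventions
-----------
* FSI (fruit shape index) = silhouette height / width.
* SR (shoulder ratio) = silhouette width near the top / width near the
  bottom, measured at a 10% inset from each end.
* Allele dosage is coded 0 / 0.5 / 1 for AA / Aa / aa; causal effects are
  per *allele*, i.e. the phenotype uses allele counts (2 x dosage), so the
  additive genetic variance is the classical sum of 2 p (1-p) effect^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ShapeParams",
    "GeneticArchitecture",
    "FruitImage",
    "render_fruit",
    "simulate_population",
    "write_population",
    "additive_variance",
    "BACKGROUND_GREY",
]

BACKGROUND_GREY = 0.05
_SKIN_RGB = np.array([0.72, 0.30, 0.22])
# inset fraction at which the taper is calibrated; matches the default
# measurement inset of phenometrics.shoulder_ratio
_SR_INSET = 0.10
_SUPERELLIPSE_EXPONENT = 2.5


@dataclass(frozen=True)
class ShapeParams:
    """Generative parameters of one fruit silhouette.

    fsi_target
        Height/width ratio of the rendered silhouette.
    sr_target
        Top/bottom width ratio at the 10% inset rows.
    lobing_amplitude
        Fractional sinusoidal perturbation of the width profile, in [0, 0.2].
    rotation_jitter
        Rotation of the silhouette in degrees (shifts measured FSI slightly;
        keep 0 for exact round trips).
    """

    fsi_target: float = 1.0
    sr_target: float = 1.0
    lobing_amplitude: float = 0.0
    rotation_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.fsi_target <= 0:
            raise ValueError("fsi_target must be positive")
        if self.sr_target <= 0:
            raise ValueError("sr_target must be positive")
        if not 0.0 <= self.lobing_amplitude <= 0.2:
            raise ValueError("lobing_amplitude must lie in [0, 0.2]")


@dataclass
class FruitImage:
    """An RGB fruit image with provenance identifiers.

    ``pixels`` is (H, W, 3) float in [0, 1]. ``meta`` carries generator
    ground truth (analytic silhouette area, true shape parameters) when the
    image is synthetic.
    """

    pixels: np.ndarray
    genotype_id: str
    image_id: str
    meta: dict = field(default_factory=dict)


def _taper_coefficient(sr_target: float) -> float:
    """Linear taper t(v) = 1 - c v over v in [-1 (top), 1 (bottom)] such
    that width(top inset) / width(bottom inset) = sr_target; the symmetric
    superellipse factor cancels at mirrored rows."""
    u = 1.0 - 2.0 * _SR_INSET
    c = (sr_target - 1.0) / (u * (sr_target + 1.0))
    if abs(c) > 0.9:
        raise ValueError(
            f"sr_target={sr_target} needs taper coefficient {c:.2f}; "
            "silhouette would pinch to zero width"
        )
    return c


def _width_profile(params: ShapeParams, n_rows: int) -> np.ndarray:
    """Relative half-width per pixel row (top row first), max-normalised."""
    i = np.arange(n_rows)
    v = -1.0 + (2.0 * i + 1.0) / n_rows  # row centres, in (-1, 1)
    e = _SUPERELLIPSE_EXPONENT
    body = (1.0 - np.abs(v) ** e) ** (1.0 / e)
    taper = 1.0 - _taper_coefficient(params.sr_target) * v
    lobe = 1.0 + params.lobing_amplitude * np.sin(3.0 * np.pi * v)
    q = body * taper * lobe
    return q / q.max()


def render_fruit(
    params: ShapeParams,
    image_size: int = 300,
    seed: int = 0,
    fill_fraction: float = 0.7,
) -> FruitImage:
    """Render a single fruit on a uniform dark background.

    The silhouette's larger dimension occupies ``fill_fraction`` of the
    canvas, so both tall (FSI > 1) and flat (FSI < 1) fruits fit. Raises
    if the requested shape cannot fit the canvas at a usable resolution.
    """
    if image_size < 64:
        raise ValueError("image_size must be at least 64 px")
    if not 0.5 <= fill_fraction <= 0.9:
        raise ValueError("fill_fraction must lie in [0.5, 0.9]")
    span = fill_fraction * image_size
    if params.fsi_target >= 1.0:
        h = int(round(span))
        w = int(round(h / params.fsi_target))
    else:
        w = int(round(span))
        h = int(round(w * params.fsi_target))
    if min(h, w) < 0.15 * image_size:
        raise ValueError(
            f"fsi_target={params.fsi_target} leaves a {h}x{w} px silhouette; "
            "too extreme for this canvas"
        )
    if max(h, w) > 0.95 * image_size:
        raise ValueError("silhouette exceeds the canvas")

    profile = _width_profile(params, h)  # (h,)
    half_w = profile * (w / 2.0)

    rows = np.arange(image_size)
    cols = np.arange(image_size)
    cy, cx = (image_size - 1) / 2.0, (image_size - 1) / 2.0
    top = int(round(cy - h / 2.0))

    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    if params.rotation_jitter:
        th = math.radians(params.rotation_jitter)
        dy, dx = yy - cy, xx - cx
        yy = cy + math.cos(th) * dy - math.sin(th) * dx
        xx = cx + math.sin(th) * dy + math.cos(th) * dx
    row_idx = np.clip(np.round(yy - top).astype(int), -1, h)
    inside_rows = (row_idx >= 0) & (row_idx < h)
    hw = np.where(inside_rows, half_w[np.clip(row_idx, 0, h - 1)], -1.0)
    mask = np.abs(xx - cx) <= hw + 1e-9

    # rendering is a pure function of the parameters: identical ShapeParams
    # give bit-identical pixels (the seed argument is reserved for future
    # stochastic texture and currently unused)
    del seed
    pixels = np.full((image_size, image_size, 3), BACKGROUND_GREY, dtype=np.float64)
    # gentle vertical shading (brighter shoulders) so the skin is not flat
    shade = 1.0 - 0.1 * np.arange(h) / max(h - 1, 1)
    colour = _SKIN_RGB
    shade_map = shade[np.clip(row_idx, 0, h - 1)]
    for ch in range(3):
        channel = pixels[:, :, ch]
        channel[mask] = np.clip(colour[ch] * shade_map[mask], 0.1, 0.95)

    analytic_area = float(np.sum(2.0 * half_w))
    return FruitImage(
        pixels=pixels,
        genotype_id="synthetic",
        image_id="0",
        meta={
            "analytic_area": analytic_area,
            "fsi_target": params.fsi_target,
            "sr_target": params.sr_target,
            "height_px": h,
            "width_px": w,
        },
    )


@dataclass(frozen=True)
class GeneticArchitecture:
    """Additive genetic architecture for the fruit shape index.

    ``effect_sizes`` are per-allele effects of the ``n_causal`` causal SNPs;
    a genotype's mean FSI is ``baseline_fsi + sum(effects * allele_count)``
    with allele counts in {0, 1, 2}. Each rendered image adds independent
    Normal(0, env_sd) environmental noise to the genotype mean. The
    remaining ``n_neutral`` SNPs segregate but have no effect.
    """

    n_causal: int = 10
    n_neutral: int = 140
    effect_sizes: tuple[float, ...] | None = None
    baseline_fsi: float = 1.0
    env_sd: float = 0.04
    allele_freqs: tuple[float, ...] | None = None
    sr_base: float = 1.0
    sr_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal + self.n_neutral < 1:
            raise ValueError("need at least one SNP")
        if self.env_sd < 0:
            raise ValueError("env_sd must be non-negative")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes length must equal n_causal")
        if self.allele_freqs is not None:
            if len(self.allele_freqs) != self.n_causal + self.n_neutral:
                raise ValueError("allele_freqs length must equal total SNP count")
            if not all(0.0 < p < 1.0 for p in self.allele_freqs):
                raise ValueError("allele frequencies must lie in (0, 1)")


def _resolve_architecture(
    arch: GeneticArchitecture,
) -> tuple[np.ndarray, np.ndarray]:
    """Materialise effect sizes and allele frequencies from the seed."""
    rng = np.random.default_rng(arch.seed)
    n = arch.n_causal + arch.n_neutral
    if arch.allele_freqs is None:
        freqs = rng.uniform(0.15, 0.85, n)
    else:
        freqs = np.asarray(arch.allele_freqs, dtype=float)
    if arch.effect_sizes is None:
        if arch.n_causal:
            # scale so the additive genetic sd of FSI is ~0.11 in expectation
            raw = rng.normal(0.0, 1.0, arch.n_causal)
            var = np.sum(2 * freqs[: arch.n_causal] * (1 - freqs[: arch.n_causal]) * raw**2)
            effects = raw * (0.11 / math.sqrt(var)) if var > 0 else raw
        else:
            effects = np.zeros(0)
    else:
        effects = np.asarray(arch.effect_sizes, dtype=float)
    return effects, freqs


def additive_variance(arch: GeneticArchitecture) -> float:
    """Expected additive variance of genotype-mean FSI: sum 2 p (1-p) a^2."""
    effects, freqs = _resolve_architecture(arch)
    p = freqs[: arch.n_causal]
    return float(np.sum(2.0 * p * (1.0 - p) * effects**2))


_FSI_RENDER_RANGE = (0.62, 1.55)


def simulate_population(
    arch: GeneticArchitecture,
    n_genotypes: int = 100,
    images_per_genotype: int = 6,
    image_size: int = 64,
    seed: int = 0,
):
    """Simulate a genotyped population with replicated fruit images.

    Genotypes are drawn under Hardy-Weinberg equilibrium from the
    architecture's allele frequencies; per-image FSI is the genotype mean
    plus environmental noise, truncated to the renderer's working range.

    Returns
    -------
    (genotypes, images, truth)
        ``genotypes`` is a :class:`snpdraw.genotype_data.GenotypeMatrix`
        (samples x SNPs dosages); ``images`` a flat list of
        :class:`FruitImage`; ``truth`` a DataFrame with one row per
        genotype (genotype_id, fsi_mean, sr_target) holding the noiseless
        generative values for parameter-recovery tests.
    """
    from .genotype_data import GenotypeMatrix

    if n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    if images_per_genotype < 1:
        raise ValueError("images_per_genotype must be >= 1")

    effects, freqs = _resolve_architecture(arch)
    n_snps = arch.n_causal + arch.n_neutral
    rng = np.random.default_rng(seed)

    # Hardy-Weinberg: allele count ~ Binomial(2, p); dosage = count / 2
    counts = rng.binomial(2, freqs[None, :], size=(n_genotypes, n_snps))
    dosages = counts / 2.0

    sample_ids = [f"G{i + 1:03d}" for i in range(n_genotypes)]
    snp_ids = [f"causal_{j + 1}" for j in range(arch.n_causal)] + [
        f"neutral_{j + 1}" for j in range(arch.n_neutral)
    ]
    genotypes = GenotypeMatrix(sample_ids, snp_ids, dosages)

    if arch.n_causal:
        # centre the additive term at its Hardy-Weinberg expectation so
        # baseline_fsi is the population-mean FSI and the renderer's working
        # range is used symmetrically
        genetic = counts[:, : arch.n_causal] @ effects
        genetic -= float(2.0 * freqs[: arch.n_causal] @ effects)
    else:
        genetic = np.zeros(n_genotypes)
    fsi_means = arch.baseline_fsi + genetic
    sr_targets = (
        arch.sr_base + rng.normal(0.0, arch.sr_sd, n_genotypes)
        if arch.sr_sd > 0
        else np.full(n_genotypes, arch.sr_base)
    )

    images: list[FruitImage] = []
    for g in range(n_genotypes):
        for k in range(images_per_genotype):
            fsi = fsi_means[g] + (rng.normal(0.0, arch.env_sd) if arch.env_sd > 0 else 0.0)
            fsi = float(np.clip(fsi, *_FSI_RENDER_RANGE))
            img = render_fruit(
                ShapeParams(fsi_target=fsi, sr_target=float(sr_targets[g])),
                image_size=image_size,
            )
            img.genotype_id = sample_ids[g]
            img.image_id = str(k + 1)
            images.append(img)

    truth = pd.DataFrame(
        {
            "genotype_id": sample_ids,
            "fsi_mean": np.clip(fsi_means, *_FSI_RENDER_RANGE),
            "sr_target": sr_targets,
        }
    )
    return genotypes, images, truth


def write_population(
    out_dir: str | Path,
    genotypes,
    images: list[FruitImage],
    truth: pd.DataFrame,
) -> Path:
    """Write a simulated population to disk in the package's exchange
    formats: PNGs named ``<genotypeID>_<imageID>.png``, the genotype matrix
    as CSV (rows = genotypes), and the true shape parameters as CSV."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for img in images:
        arr = (np.clip(img.pixels, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(img_dir / f"{img.genotype_id}_{img.image_id}.png")
    genotypes.to_csv(out / "genotypes.csv")
    truth.to_csv(out / "true_shape_params.csv", index=False)
    return out
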