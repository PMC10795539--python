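"""Shared fixtures: one simulated population and one trained pipeline.

The expensive artefacts (rendered population, trained autoencoder, the
paired panel batteries) are built once per session and reused across test
modules. The study conditions are fixed here: 50 genotypes x 4 images at
64 px, 10 causal + 140 neutral SNPs, heritable FSI, 90/10 genotype-level
stratified split.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from snpdraw.autoencoder import (
    DESK_SPEC,
    build_autoencoder,
    build_genotype_targets,
    decode_embeddings,
    encode_images,
    train_autoencoder,
)
from snpdraw.evaluation import train_panel_battery
from snpdraw.genotype_data import select_panel
from snpdraw.image_pipeline import stratified_split
from snpdraw.phenometrics import measure_image
from snpdraw.predictor import desk_predictor_spec
from snpdraw.synthetic_fruit import GeneticArchitecture, simulate_population

IMAGE_SIZE = 64


@pytest.fixture(scope="session")
def population():
    """Simulated population: genotypes, images, and generative truth."""
    arch = GeneticArchitecture(n_causal=10, n_neutral=140, seed=7)
    genotypes, images, truth = simulate_population(
        arch, n_genotypes=50, images_per_genotype=4, image_size=IMAGE_SIZE, seed=11
    )
    return {"arch": arch, "genotypes": genotypes, "images": images, "truth": truth}


@pytest.fixture(scope="session")
def split(population):
    return stratified_split(population["images"], train_fraction=0.9, seed=0)


@pytest.fixture(scope="session")
def trained_autoencoder(population, split):
    """Autoencoder trained on the population's training images.

    Captures a snapshot of reconstruction quality after the short
    15-epoch regime, then continues to the desk-profile default of 30
    epochs for the model used by downstream stages.
    """
    train_imgs, val_imgs = split.partition_images(population["images"])
    encoder, decoder = build_autoencoder(DESK_SPEC, IMAGE_SIZE, seed=0)
    history_15 = train_autoencoder(
        encoder,
        decoder,
        train_imgs,
        loss="mse",
        epochs=15,
        optimizer="adam",
        learning_rate=3e-3,
        batch_size=8,
        lr_schedule="cosine",
        augment="vstretch",
        seed=0,
    )
    recon_15 = decode_embeddings(decoder, encode_images(encoder, val_imgs))
    fsi_errors_15 = np.array(
        [
            abs(measure_image(rec).fsi - measure_image(orig).fsi)
            for orig, rec in zip(val_imgs, recon_15)
        ]
    )
    history_30 = train_autoencoder(
        encoder,
        decoder,
        train_imgs,
        loss="mse",
        epochs=15,
        optimizer="adam",
        learning_rate=3e-3,
        batch_size=8,
        lr_schedule="cosine",
        augment="vstretch",
        seed=1,
    )
    return {
        "encoder": encoder,
        "decoder": decoder,
        "history_15": history_15,
        "fsi_errors_15": fsi_errors_15,
        "history_30": history_15 + history_30,
        "train_images": train_imgs,
        "val_images": val_imgs,
    }


@pytest.fixture(scope="session")
def trained_autoencoder_hires(population):
    """Autoencoder trained at 96 px for shape-retention measurements.

    At 64 px an FSI difference of 0.05 is about two pixels of silhouette
    extent, so per-image retention checks are dominated by quantization;
    96 px gives the same pipeline a fair measurement scale.
    """
    arch = population["arch"]
    _, images, _ = simulate_population(
        arch, n_genotypes=50, images_per_genotype=4, image_size=96, seed=11
    )
    hsplit = stratified_split(images, train_fraction=0.9, seed=0)
    train_imgs, val_imgs = hsplit.partition_images(images)
    encoder, decoder = build_autoencoder(DESK_SPEC, 96, seed=0)
    train_autoencoder(
        encoder,
        decoder,
        train_imgs,
        loss="mse",
        epochs=30,
        optimizer="adam",
        learning_rate=3e-3,
        batch_size=8,
        lr_schedule="cosine",
        augment="vstretch",
        seed=0,
    )
    return {
        "encoder": encoder,
        "decoder": decoder,
        "train_images": train_imgs,
        "val_images": val_imgs,
    }


@pytest.fixture(scope="session")
def embedding_targets(trained_autoencoder):
    """Per-genotype mean-embedding targets under the frozen encoder."""
    enc = trained_autoencoder["encoder"]
    dec = trained_autoencoder["decoder"]
    train_imgs = trained_autoencoder["train_images"]
    val_imgs = trained_autoencoder["val_images"]
    z_train = encode_images(enc, train_imgs)
    z_val = encode_images(enc, val_imgs)
    train_targets = build_genotype_targets(
        z_train, [im.genotype_id for im in train_imgs], decoder=dec
    )
    val_targets = build_genotype_targets(
        z_val, [im.genotype_id for im in val_imgs], decoder=dec
    )
    return {"train": train_targets, "val": val_targets}


@pytest.fixture(scope="session")
def panel_battery(population, split, embedding_targets):
    """Ten paired predictor trainings: causal panel vs equal-size neutral."""
    genotypes = population["genotypes"]
    causal_ids = [s for s in genotypes.snp_ids if s.startswith("causal")]
    neutral_ids = [s for s in genotypes.snp_ids if s.startswith("neutral")]
    val_ids = sorted(split.val_genotypes)
    causal_maes, neutral_maes = [], []
    for i in range(10):
        spec = desk_predictor_spec(len(causal_ids))
        causal = train_panel_battery(
            genotypes,
            embedding_targets["train"],
            val_ids,
            kind="targeted",
            n_models=1,
            targeted_ids=causal_ids,
            val_targets=embedding_targets["val"],
            spec=spec,
            seed=i,
        )
        neutral = train_panel_battery(
            genotypes.subset_snps(neutral_ids),
            embedding_targets["train"],
            val_ids,
            kind="random",
            n_models=1,
            n_total=len(causal_ids),
            val_targets=embedding_targets["val"],
            spec=spec,
            seed=100 + i,
        )
        causal_maes.append(causal[0]["val_mae"])
        neutral_maes.append(neutral[0]["val_mae"])
    return {"causal": causal_maes, "neutral": neutral_maes}


@pytest.fixture(scope="session")
def dilution_battery(population, split, embedding_targets):
    """Causal core alone vs the core diluted 10x with neutral SNPs."""
    genotypes = population["genotypes"]
    causal_ids = [s for s in genotypes.snp_ids if s.startswith("causal")]
    val_ids = sorted(split.val_genotypes)
    core_maes, diluted_maes = [], []
    for i in range(5):
        for kind, n_total, size, out, seed in (
            ("targeted", None, len(causal_ids), core_maes, i),
            ("augmented", 10 * len(causal_ids), 10 * len(causal_ids), diluted_maes, 200 + i),
        ):
            spec = desk_predictor_spec(size)
            rec = train_panel_battery(
                genotypes,
                embedding_targets["train"],
                val_ids,
                kind=kind,
                n_models=1,
                n_total=n_total,
                targeted_ids=causal_ids,
                val_targets=embedding_targets["val"],
                spec=spec,
                seed=seed,
            )
            out.append(rec[0]["val_mae"])
    return {"core": core_maes, "diluted": diluted_maes}


def paired_one_sided_p(a, b) -> float:
    """One-sided paired t test that mean(a) < mean(b)."""
    return float(sps.ttest_rel(a, b, alternative="less").pvalue)
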