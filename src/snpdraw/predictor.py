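"""SNP-to-embedding regression and the assembled SNP-to-image model.

The embedding predictor is a deliberately small two-layer network
(n_snps -> 300 -> 64, sigmoid on both layers) trained with mean absolute
error, SGD, a reduce-on-plateau learning-rate schedule, and an early
stopper watching validation MAE. Attaching the trained predictor to the
trained autoencoder's decoder yields a composite model that maps a
genotype's SNP dosages straight to a fruit image; no end-to-end training
happens at assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .autoencoder import GenotypeEmbeddingTargets, batch_to_images
from .genotype_data import GenotypeMatrix, SNPPanel
from .synthetic_fruit import FruitImage

__all__ = [
    "PredictorSpec",
    "TrainingHistory",
    "SnpToImageModel",
    "desk_predictor_spec",
    "build_predictor",
    "train_predictor",
    "predict_embeddings",
    "assemble_snp_to_image",
]


@dataclass(frozen=True)
class PredictorSpec:
    """Hyperparameters of the embedding predictor.

    Defaults follow the reference training regime: 300 hidden units,
    sigmoid activations, MAE loss, SGD at learning rate 0.05 with a
    reduce-on-plateau schedule, up to 1000 epochs with early stopping.
    """

    n_snps: int = 150
    hidden_units: int = 300
    output_dim: int = 64
    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 1000
    batch_size: int = 32
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    early_patience: int = 25
    early_min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


def desk_predictor_spec(n_snps: int, max_epochs: int = 600) -> PredictorSpec:
    """Training profile for desk-scale fixtures (tens of genotypes).

    With ~45 training genotypes an epoch is a handful of gradient steps, so
    relative to the full-scale regime the learning rate is raised and the
    batch shrunk; the plateau scheduler gets a longer fuse so it does not
    freeze the rate during the slow early phase.
    """
    return PredictorSpec(
        n_snps=n_snps,
        learning_rate=0.2,
        batch_size=8,
        max_epochs=max_epochs,
        plateau_patience=60,
        early_patience=50,
        early_min_delta=1e-4,
    )


def build_predictor(spec: PredictorSpec, seed: int = 0) -> nn.Sequential:
    """Two-layer sigmoid network mapping SNP dosages to an embedding."""
    rng = np.random.default_rng(seed)
    # LeCun init: sigmoid units need pre-activations of order 1 even when
    # the SNP input is narrow, which fan-in+fan-out scaling underestimates
    return nn.Sequential(
        [
            nn.Dense(spec.n_snps, spec.hidden_units, rng, init="lecun", name="fc1"),
            nn.Sigmoid(),
            nn.Dense(spec.hidden_units, spec.output_dim, rng, init="lecun", name="fc2"),
            nn.Sigmoid(),
        ]
    )


@dataclass
class TrainingHistory:
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_val_mae: float = float("nan")

    @property
    def final_val_mae(self) -> float:
        """Validation MAE of the returned (best early-stopping) weights."""
        if not np.isnan(self.best_val_mae):
            return self.best_val_mae
        return self.val_mae[-1] if self.val_mae else float("nan")


def _design(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    targets: GenotypeEmbeddingTargets,
    genotype_ids: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in genotype_ids if g not in genotypes.sample_ids]
    if missing:
        raise KeyError(
            f"genotypes present in targets but absent from the matrix: {missing[:5]}"
        )
    sub = genotypes.subset_samples(genotype_ids).subset_snps(list(panel.snp_ids))
    X = sub.values.astype(np.float32)
    Y = targets.matrix(genotype_ids).astype(np.float32)
    return X, Y


def train_predictor(
    model: nn.Sequential,
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    targets: GenotypeEmbeddingTargets,
    val_genotypes: list[str],
    val_targets: GenotypeEmbeddingTargets | None = None,
    spec: PredictorSpec | None = None,
    seed: int = 0,
) -> TrainingHistory:
    """Fit the predictor on per-genotype mean embeddings.

    Training genotypes are all target genotypes not named in
    ``val_genotypes``; validation targets may come from a separate
    :class:`GenotypeEmbeddingTargets` (embeddings of held-out images under
    the frozen encoder). Restores the best early-stopping weights before
    returning.
    """
    spec = spec or PredictorSpec(n_snps=len(panel))
    val_targets = val_targets or targets
    val_ids = [g for g in val_genotypes]
    train_ids = [g for g in targets.genotype_ids if g not in set(val_ids)]
    missing_val = [g for g in val_ids if g not in val_targets.mean_embeddings]
    if missing_val:
        raise KeyError(f"validation genotypes without targets: {missing_val[:5]}")
    X, Y = _design(genotypes, panel, targets, train_ids)
    Xv, Yv = _design(genotypes, panel, val_targets, val_ids)

    opt = nn.SGD(model.params(), lr=spec.learning_rate, momentum=spec.momentum)
    sched = nn.ReduceLROnPlateau(
        opt, factor=spec.plateau_factor, patience=spec.plateau_patience
    )
    stopper = nn.EarlyStopper(spec.early_patience, spec.early_min_delta)
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    n = X.shape[0]
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, spec.batch_size):
            xb, yb = X[order[s : s + spec.batch_size]], Y[order[s : s + spec.batch_size]]
            pred = model.forward(xb)
            value, grad = nn.mae_loss(pred, yb)
            opt.zero_grad()
            model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(value)
        val_mae = float(np.mean(np.abs(model.forward(Xv) - Yv)))
        history.train_mae.append(float(np.mean(losses)))
        history.val_mae.append(val_mae)
        sched.step(val_mae)
        if stopper.update(val_mae, model):
            history.stopped_epoch = epoch + 1
            break
    if stopper.best_state is not None:
        model.load_state_dict(stopper.best_state)
        history.best_val_mae = float(stopper.best)
    return history


def predict_embeddings(
    model: nn.Sequential, genotypes: GenotypeMatrix, panel: SNPPanel
) -> pd.DataFrame:
    """Predicted embedding per sample, as a (samples x dims) DataFrame."""
    sub = genotypes.subset_snps(list(panel.snp_ids))
    pred = model.forward(sub.values.astype(np.float32))
    return pd.DataFrame(pred, index=genotypes.sample_ids)


@dataclass
class SnpToImageModel:
    """Composite model: SNP dosages -> predicted embedding -> drawn image."""

    predictor: nn.Sequential
    decoder: nn.Sequential
    panel: SNPPanel

    def draw(self, genotype_row) -> FruitImage:
        """Draw the predicted fruit image for one genotype.

        ``genotype_row`` is a mapping / pandas Series of SNP id -> dosage
        covering the panel, or an array already ordered like the panel.
        """
        if isinstance(genotype_row, (pd.Series, dict)):
            row = pd.Series(genotype_row)
            missing = [s for s in self.panel.snp_ids if s not in row.index]
            if missing:
                raise KeyError(f"genotype row missing panel SNPs: {missing[:5]}")
            x = row[list(self.panel.snp_ids)].to_numpy(dtype=np.float32)
        else:
            x = np.asarray(genotype_row, dtype=np.float32)
            if x.shape != (len(self.panel),):
                raise ValueError(
                    f"expected {len(self.panel)} dosages, got shape {x.shape}"
                )
        if not np.isin(x, [0.0, 0.5, 1.0]).all():
            raise ValueError("dosages must lie in {0, 0.5, 1}")
        z = self.predictor.forward(x[None, :])
        img = batch_to_images(self.decoder.forward(z))[0]
        return FruitImage(pixels=img, genotype_id="predicted", image_id="0",
                          meta={"embedding": z[0].copy()})

    def draw_many(self, genotypes: GenotypeMatrix) -> list[FruitImage]:
        sub = genotypes.subset_snps(list(self.panel.snp_ids))
        z = self.predictor.forward(sub.values.astype(np.float32))
        imgs = batch_to_images(self.decoder.forward(z))
        return [
            FruitImage(pixels=imgs[i], genotype_id=g, image_id="predicted",
                       meta={"embedding": z[i].copy()})
            for i, g in enumerate(sub.sample_ids)
        ]


def assemble_snp_to_image(
    predictor: nn.Sequential, decoder: nn.Sequential, panel: SNPPanel
) -> SnpToImageModel:
    """Attach the trained predictor to the trained decoder.

    Pure composition: dimensions are checked, no weights are updated.
    """
    probe = np.zeros((1, len(panel)), dtype=np.float32)
    z = predictor.forward(probe)
    try:
        decoder.forward(z.astype(np.float32))
    except ValueError as exc:
        raise ValueError(
            f"predictor output dim {z.shape[1]} does not match decoder input ({exc})"
        ) from exc
    return SnpToImageModel(predictor=predictor, decoder=decoder, panel=panel)
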