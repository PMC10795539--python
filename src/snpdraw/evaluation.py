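"""Prediction-quality metrics and the comparative experiments.

Covers the evaluation battery for SNP-to-image models:

* embedding MAE between predicted and target mean embeddings;
* a resampling null threshold — the MAE one would get by merely redrawing
  each genotype's phenotype from its own Normal(mu, sigma) distribution,
  estimated over many replicate datasets; a model is only informative if
  its MAE beats this boundary;
* 1-D Wasserstein distances between metric distributions (predicted vs
  decoded-mean vs original);
* the five-class shape confusion matrix with accuracy and macro F score;
* model batteries (many retrainings with fresh random panels) compared by
  Welch's t test, and the panel-size ladder that dilutes a targeted core
  with increasing numbers of random markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from .autoencoder import GenotypeEmbeddingTargets
from .genotype_data import GenotypeMatrix, SNPPanel, select_panel
from .phenometrics import CATEGORIES
from .predictor import PredictorSpec, build_predictor, train_predictor

__all__ = [
    "GenotypeShapeStats",
    "EvalReport",
    "embedding_mae",
    "null_threshold",
    "wasserstein_1d",
    "shape_confusion",
    "compare_model_batteries",
    "train_panel_battery",
    "panel_ladder_experiment",
]


def embedding_mae(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute error over all genotypes and embedding dimensions."""
    predicted, target = np.asarray(predicted), np.asarray(target)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    return float(np.mean(np.abs(predicted - target)))


@dataclass
class GenotypeShapeStats:
    """Per-genotype mean and standard deviation of a shape metric."""

    stats: dict[str, tuple[float, float]]  # genotype -> (mu, sigma)

    def __post_init__(self) -> None:
        if not self.stats:
            raise ValueError("no genotypes in stats")
        for g, (mu, sd) in self.stats.items():
            if not np.isfinite(mu):
                raise ValueError(f"non-finite mean for genotype {g!r}")
            if sd < 0:
                raise ValueError(f"negative sd for genotype {g!r}")

    @classmethod
    def from_values(cls, values_by_genotype: dict[str, Sequence[float]]) -> "GenotypeShapeStats":
        return cls(
            {
                g: (float(np.mean(v)), float(np.std(v)))
                for g, v in values_by_genotype.items()
            }
        )

    @property
    def mus(self) -> np.ndarray:
        return np.array([m for m, _ in self.stats.values()])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s for _, s in self.stats.values()])


def null_threshold(
    stats: GenotypeShapeStats, n_datasets: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """MAE expected from random within-genotype resampling.

    For each replicate dataset, one value per genotype is drawn from
    Normal(mu_g, sigma_g) and the MAE of those draws against the genotype
    means is recorded; returns (mean, sd) of the replicate MAEs. A
    predictor whose MAE exceeds this boundary is doing no better than
    sampling from the phenotype distribution itself.
    """
    rng = np.random.default_rng(seed)
    sigmas = stats.sigmas
    draws = rng.normal(0.0, 1.0, size=(n_datasets, sigmas.size)) * sigmas[None, :]
    maes = np.abs(draws).mean(axis=1)
    return float(maes.mean()), float(maes.std())


def wasserstein_1d(sample_a, sample_b) -> float:
    """First-order Wasserstein distance between two empirical distributions."""
    a, b = np.asarray(sample_a, dtype=float), np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(stats.wasserstein_distance(a, b))


def shape_confusion(
    true_categories: Sequence[str], predicted_categories: Sequence[str]
) -> tuple[pd.DataFrame, float, float]:
    """5x5 confusion matrix (fixed class order), accuracy, macro F score.

    The macro F score averages over the classes present in the true
    labels, so absent classes do not dilute it.
    """
    true_c, pred_c = list(true_categories), list(predicted_categories)
    if len(true_c) != len(pred_c):
        raise ValueError("label sequences differ in length")
    unknown = (set(true_c) | set(pred_c)) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown shape categories: {sorted(unknown)}")
    cm = _sk_confusion(true_c, pred_c, labels=list(CATEGORIES))
    confusion = pd.DataFrame(cm, index=CATEGORIES, columns=CATEGORIES)
    accuracy = float(np.trace(cm) / cm.sum())
    present = [c for c in CATEGORIES if c in set(true_c)]
    f_score = float(
        _sk_f1(true_c, pred_c, labels=present, average="macro", zero_division=0)
    )
    return confusion, accuracy, f_score


def compare_model_batteries(
    mae_a: Sequence[float],
    mae_b: Sequence[float],
    paired: bool = False,
    alternative: str = "two-sided",
) -> dict:
    """Compare two batteries of model MAEs by t test.

    Unpaired batteries use Welch's unequal-variance t test; pass
    ``paired=True`` when the batteries share training seeds one-to-one.
    """
    a, b = np.asarray(mae_a, dtype=float), np.asarray(mae_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each battery needs at least 2 models")
    if paired:
        if a.size != b.size:
            raise ValueError("paired batteries must have equal size")
        t, p = stats.ttest_rel(a, b, alternative=alternative)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return {
        "t": float(t),
        "p": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "paired": paired,
        "alternative": alternative,
    }


def train_panel_battery(
    genotypes: GenotypeMatrix,
    targets: GenotypeEmbeddingTargets,
    val_genotypes: list[str],
    kind: str,
    n_models: int,
    n_total: int | None = None,
    targeted_ids: list[str] | None = None,
    val_targets: GenotypeEmbeddingTargets | None = None,
    spec: PredictorSpec | None = None,
    seed: int = 0,
    exclude_ids: list[str] | None = None,
) -> list[dict]:
    """Train ``n_models`` predictors of one panel kind, renewing random
    panels (and weight initialisations) per model.

    Returns one record per model: panel, trained model, validation MAE.
    """
    records = []
    for i in range(n_models):
        panel = select_panel(
            genotypes,
            kind,
            n_total=n_total,
            targeted_ids=targeted_ids,
            seed=seed * 10_000 + i,
            exclude_ids=exclude_ids,
        )
        model_spec = spec or PredictorSpec(n_snps=len(panel))
        model = build_predictor(model_spec, seed=seed * 10_000 + i)
        history = train_predictor(
            model,
            genotypes,
            panel,
            targets,
            val_genotypes,
            val_targets,
            model_spec,
            seed=seed * 10_000 + i,
        )
        records.append(
            {
                "panel": panel,
                "model": model,
                "val_mae": history.final_val_mae,
                "history": history,
            }
        )
    return records


def panel_ladder_experiment(
    genotypes: GenotypeMatrix,
    targeted_ids: list[str],
    sizes: Sequence[int],
    models_per_size: int,
    targets: GenotypeEmbeddingTargets,
    val_genotypes: list[str],
    val_targets: GenotypeEmbeddingTargets | None = None,
    spec_factory=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel-size ladder: augmented (targeted core + random fill) vs fully
    random panels at each size, ``models_per_size`` fresh models per cell.

    Returns (tidy results, per-cell summary with median and IQR).
    """
    sizes = list(sizes)
    n_avail = len(genotypes.snp_ids)
    bad = [s for s in sizes if s > n_avail]
    if bad:
        raise ValueError(f"panel sizes {bad} exceed the {n_avail} available SNPs")
    bad = [s for s in sizes if s < len(targeted_ids)]
    if bad:
        raise ValueError(
            f"panel sizes {bad} are smaller than the {len(targeted_ids)}-SNP targeted core"
        )
    rows = []
    for si, size in enumerate(sizes):
        for kind in ("augmented", "random"):
            for rep in range(models_per_size):
                model_seed = seed * 100_000 + si * 1_000 + rep * 2 + (kind == "random")
                panel = select_panel(
                    genotypes,
                    kind,
                    n_total=size,
                    targeted_ids=targeted_ids if kind == "augmented" else None,
                    seed=model_seed,
                )
                spec = (
                    spec_factory(len(panel)) if spec_factory else PredictorSpec(n_snps=len(panel))
                )
                model = build_predictor(spec, seed=model_seed)
                history = train_predictor(
                    model,
                    genotypes,
                    panel,
                    targets,
                    val_genotypes,
                    val_targets,
                    spec,
                    seed=model_seed,
                )
                rows.append(
                    {
                        "size": size,
                        "kind": kind,
                        "replicate": rep,
                        "val_mae": history.final_val_mae,
                    }
                )
    results = pd.DataFrame(rows)
    summary = (
        results.groupby(["size", "kind"])["val_mae"]
        .agg(
            median="median",
            q1=lambda v: float(np.percentile(v, 25)),
            q3=lambda v: float(np.percentile(v, 75)),
            n="count",
        )
        .reset_index()
    )
    return results, summary


@dataclass
class EvalReport:
    """Full evaluation of one SNP-to-image model, with provenance echo."""

    embedding_mae: float
    fsi_mae: float
    sr_mae: float
    null_boundary: tuple[float, float]
    wasserstein: dict[str, float]
    confusion: pd.DataFrame
    accuracy: float
    f_score: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("embedding_mae", "fsi_mae", "sr_mae"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "embedding_mae": self.embedding_mae,
            "fsi_mae": self.fsi_mae,
            "sr_mae": self.sr_mae,
            "null_boundary_mean": self.null_boundary[0],
            "null_boundary_sd": self.null_boundary[1],
            "wasserstein": dict(self.wasserstein),
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "f_score": self.f_score,
            "config": dict(self.config),
        }
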