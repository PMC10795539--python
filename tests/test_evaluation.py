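"""Evaluation metrics against independent oracles, plus experiment drivers."""

import numpy as np
import pytest

from snpdraw.autoencoder import build_genotype_targets
from snpdraw.evaluation import (
    EvalReport,
    GenotypeShapeStats,
    compare_model_batteries,
    embedding_mae,
    null_threshold,
    panel_ladder_experiment,
    shape_confusion,
    wasserstein_1d,
)
from snpdraw.genotype_data import GenotypeMatrix
from snpdraw.predictor import PredictorSpec


def test_embedding_mae_identity_and_offset():
    x = np.random.default_rng(0).uniform(0, 1, (5, 64))
    assert embedding_mae(x, x) == 0.0
    assert embedding_mae(x + 0.1, x) == pytest.approx(0.1)


def test_embedding_mae_equals_brute_force_double_loop():
    rng = np.random.default_rng(1)
    pred, target = rng.uniform(0, 1, (5, 64)), rng.uniform(0, 1, (5, 64))
    total = 0.0
    for i in range(5):
        for j in range(64):
            total += abs(pred[i, j] - target[i, j])
    assert embedding_mae(pred, target) == pytest.approx(total / (5 * 64))


def test_embedding_mae_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        embedding_mae(np.zeros((2, 3)), np.zeros((3, 2)))


def test_null_threshold_degenerate_sigmas():
    stats = GenotypeShapeStats({f"g{i}": (1.0, 0.0) for i in range(10)})
    mean, sd = null_threshold(stats, n_datasets=100, seed=0)
    assert mean == 0.0 and sd == 0.0


def test_null_threshold_matches_half_normal_closed_form():
    """With equal sigmas s the expected per-genotype |draw - mu| is the
    half-normal mean s*sqrt(2/pi)."""
    s = 0.07
    stats = GenotypeShapeStats({f"g{i}": (1.0, s) for i in range(36)})
    mean, sd = null_threshold(stats, n_datasets=10_000, seed=3)
    assert mean == pytest.approx(s * np.sqrt(2 / np.pi), rel=0.02)
    assert sd > 0


def test_null_threshold_is_seeded():
    stats = GenotypeShapeStats({f"g{i}": (1.0, 0.1) for i in range(5)})
    assert null_threshold(stats, 500, seed=7) == null_threshold(stats, 500, seed=7)


def test_stats_validation():
    with pytest.raises(ValueError):
        GenotypeShapeStats({})
    with pytest.raises(ValueError):
        GenotypeShapeStats({"g": (1.0, -0.1)})


def test_wasserstein_point_masses():
    assert wasserstein_1d([0.0], [0.5]) == pytest.approx(0.5)
    assert wasserstein_1d([0.3, 0.3], [0.3]) == 0.0


def test_wasserstein_equals_sorted_difference_mean_for_equal_sizes():
    rng = np.random.default_rng(2)
    a, b = rng.normal(1, 0.2, 50), rng.normal(1.1, 0.3, 50)
    brute = np.mean(np.abs(np.sort(a) - np.sort(b)))
    assert wasserstein_1d(a, b) == pytest.approx(brute, rel=1e-9)


def test_wasserstein_metric_properties():
    rng = np.random.default_rng(3)
    x, y, z = (rng.normal(0, 1, 40) for _ in range(3))
    assert wasserstein_1d(x, y) == pytest.approx(wasserstein_1d(y, x))
    assert wasserstein_1d(x, x) == 0.0
    assert wasserstein_1d(x, z) <= wasserstein_1d(x, y) + wasserstein_1d(y, z) + 1e-12


def test_wasserstein_empty_sample_rejected():
    with pytest.raises(ValueError):
        wasserstein_1d([], [1.0])


def test_confusion_perfect_predictions():
    labels = ["flat", "globose", "oval", "oblong", "flat-globose"] * 2
    cm, acc, f = shape_confusion(labels, labels)
    assert acc == 1.0 and f == 1.0
    assert np.trace(cm.to_numpy()) == len(labels)


def test_confusion_majority_collapse_accuracy():
    true = ["flat"] * 5 + ["globose"] * 5
    pred = ["flat"] * 10
    _, acc, _ = shape_confusion(true, pred)
    assert acc == 0.5


def test_confusion_matches_hand_computed_macro_f():
    true = ["flat", "flat", "globose", "globose", "oval",
            "oval", "flat", "globose", "oval", "flat"]
    pred = ["flat", "globose", "globose", "globose", "oval",
            "flat", "flat", "flat", "oval", "flat"]
    cm, acc, f = shape_confusion(true, pred)
    # hand counts: flat TP3 FP2 FN1; globose TP2 FP1 FN1; oval TP2 FP0 FN1
    f_flat = 2 * 3 / (2 * 3 + 2 + 1)
    f_glob = 2 * 2 / (2 * 2 + 1 + 1)
    f_oval = 2 * 2 / (2 * 2 + 0 + 1)
    assert acc == pytest.approx(7 / 10)
    assert f == pytest.approx((f_flat + f_glob + f_oval) / 3)
    assert cm.loc["flat", "globose"] == 1
    assert cm.to_numpy().sum() == 10
    assert (cm.sum(axis=1)["flat"]) == 4  # row sums = true counts


def test_confusion_unknown_label_rejected():
    with pytest.raises(ValueError, match="unknown"):
        shape_confusion(["flat"], ["banana"])


def test_identical_batteries_give_t_zero_p_one():
    a = [0.08, 0.09, 0.10, 0.11]
    res = compare_model_batteries(a, list(a))
    assert res["t"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_welch_t_test_power_on_separated_batteries():
    """Batteries N(0.08, 0.003) vs N(0.09, 0.002), n=30: Welch's test
    should reject at p < 0.01 nearly always."""
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(100):
        a = rng.normal(0.08, 0.003, 30)
        b = rng.normal(0.09, 0.002, 30)
        if compare_model_batteries(a, b)["p"] < 0.01:
            hits += 1
    assert hits >= 95


def test_batteries_require_two_models_each():
    with pytest.raises(ValueError):
        compare_model_batteries([0.1], [0.1, 0.2])


def test_paired_comparison_uses_pairing():
    rng = np.random.default_rng(4)
    base = rng.normal(0.1, 0.02, 12)
    shifted = base + 0.001 + rng.normal(0, 1e-4, 12)
    res = compare_model_batteries(base, shifted, paired=True, alternative="less")
    assert res["p"] < 0.001  # small shift is undetectable unpaired at this n
    unpaired = compare_model_batteries(base, shifted, alternative="less")
    assert unpaired["p"] > res["p"]


def test_panel_ladder_bookkeeping_and_summary():
    rng = np.random.default_rng(6)
    n_geno, n_snps = 25, 60
    matrix = GenotypeMatrix(
        [f"g{i}" for i in range(n_geno)],
        [f"s{j}" for j in range(n_snps)],
        rng.choice([0.0, 0.5, 1.0], size=(n_geno, n_snps)),
    )
    emb = rng.uniform(0.2, 0.8, (n_geno, 64))
    targets = build_genotype_targets(emb, matrix.sample_ids)
    results, summary = panel_ladder_experiment(
        matrix,
        targeted_ids=[f"s{j}" for j in range(6)],
        sizes=(12, 24),
        models_per_size=3,
        targets=targets,
        val_genotypes=matrix.sample_ids[:5],
        spec_factory=lambda n: PredictorSpec(n_snps=n, max_epochs=3, early_patience=3),
        seed=0,
    )
    assert len(results) == 2 * 2 * 3  # sizes x kinds x replicates
    assert set(results["kind"]) == {"augmented", "random"}
    assert results["val_mae"].notna().all()
    assert len(summary) == 4
    assert {"median", "q1", "q3", "n"} <= set(summary.columns)


def test_panel_ladder_size_validation():
    matrix = GenotypeMatrix(["a", "b"], ["s1", "s2"], np.zeros((2, 2)))
    targets = build_genotype_targets(np.zeros((2, 64)), ["a", "b"])
    with pytest.raises(ValueError, match="exceed"):
        panel_ladder_experiment(matrix, ["s1"], (5,), 1, targets, ["a"])
    with pytest.raises(ValueError, match="smaller"):
        panel_ladder_experiment(matrix, ["s1", "s2"], (1,), 1, targets, ["a"])


def test_eval_report_echoes_provenance():
    import pandas as pd

    report = EvalReport(
        embedding_mae=0.08,
        fsi_mae=0.04,
        sr_mae=0.03,
        null_boundary=(0.075, 0.008),
        wasserstein={"pred_vs_decoded": 0.02},
        confusion=pd.DataFrame(np.eye(5, dtype=int)),
        accuracy=1.0,
        f_score=1.0,
        config={"thresholds": (0.85, 0.95, 1.05, 1.2), "seed": 3, "panel": "targeted"},
    )
    d = report.to_dict()
    assert d["config"]["seed"] == 3
    assert d["null_boundary_mean"] == 0.075
    with pytest.raises(ValueError):
        EvalReport(
            embedding_mae=-0.1,
            fsi_mae=0,
            sr_mae=0,
            null_boundary=(0, 0),
            wasserstein={},
            confusion=pd.DataFrame(),
            accuracy=0,
            f_score=0,
        )
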