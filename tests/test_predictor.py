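"""Embedding predictor: contracts, training baselines, and the assembled
SNP-to-image model."""

import numpy as np
import pandas as pd
import pytest

from snpdraw.autoencoder import DESK_SPEC, build_autoencoder, build_genotype_targets
from snpdraw.genotype_data import GenotypeMatrix, select_panel
from snpdraw.predictor import (
    PredictorSpec,
    assemble_snp_to_image,
    build_predictor,
    desk_predictor_spec,
    predict_embeddings,
    train_predictor,
)


def test_reference_spec_parameter_count():
    """150 -> 300 -> 64 with biases: 150*300 + 300 + 300*64 + 64 = 64,564."""
    model = build_predictor(PredictorSpec(n_snps=150))
    assert model.n_params() == 64_564


def test_panel_ladder_maximum_width_builds():
    model = build_predictor(PredictorSpec(n_snps=300_150))
    assert model.n_params() == 300_150 * 300 + 300 + 300 * 64 + 64


def test_outputs_lie_in_unit_interval():
    model = build_predictor(PredictorSpec(n_snps=20), seed=1)
    rng = np.random.default_rng(0)
    x = rng.choice([0.0, 0.5, 1.0], size=(7, 20)).astype(np.float32)
    y = model.forward(x)
    assert y.shape == (7, 64)
    assert y.min() > 0.0 and y.max() < 1.0


@pytest.fixture
def tiny_setup():
    rng = np.random.default_rng(5)
    n_geno, n_snps = 30, 12
    values = rng.choice([0.0, 0.5, 1.0], size=(n_geno, n_snps))
    matrix = GenotypeMatrix(
        [f"g{i}" for i in range(n_geno)], [f"s{j}" for j in range(n_snps)], values
    )
    panel = select_panel(matrix, "random", n_total=12, seed=0)
    return matrix, panel, rng


def _quick_spec(n_snps, epochs=150):
    return PredictorSpec(
        n_snps=n_snps,
        learning_rate=0.2,
        batch_size=8,
        max_epochs=epochs,
        plateau_patience=60,
        early_patience=epochs,
    )


def test_constant_targets_are_learnable(tiny_setup):
    matrix, panel, _ = tiny_setup
    const = np.full((len(matrix.sample_ids), 64), 0.35)
    targets = build_genotype_targets(const, matrix.sample_ids)
    spec = _quick_spec(len(panel))
    model = build_predictor(spec, seed=0)
    hist = train_predictor(
        model, matrix, panel, targets, val_genotypes=matrix.sample_ids[:5], spec=spec
    )
    assert hist.final_val_mae < 0.01


def test_shuffled_targets_converge_to_mean_prediction_baseline(tiny_setup):
    """With targets decoupled from the SNPs, validation MAE lands near the
    MAE of always predicting the training-mean vector."""
    matrix, panel, rng = tiny_setup
    emb = rng.uniform(0.2, 0.8, (len(matrix.sample_ids), 64))
    targets = build_genotype_targets(emb, list(rng.permutation(matrix.sample_ids)))
    val_ids = matrix.sample_ids[:6]
    train_ids = matrix.sample_ids[6:]
    Y_train = targets.matrix(train_ids)
    Y_val = targets.matrix(val_ids)
    baseline = np.abs(Y_val - Y_train.mean(axis=0)).mean()
    spec = _quick_spec(len(panel))
    model = build_predictor(spec, seed=1)
    hist = train_predictor(model, matrix, panel, targets, val_ids, spec=spec, seed=1)
    assert hist.final_val_mae == pytest.approx(baseline, rel=0.25)


def test_missing_target_genotype_named(tiny_setup):
    matrix, panel, rng = tiny_setup
    emb = rng.uniform(0, 1, (3, 64))
    targets = build_genotype_targets(emb, ["g0", "g1", "ghost"])
    spec = _quick_spec(len(panel), epochs=2)
    model = build_predictor(spec)
    with pytest.raises(KeyError, match="ghost"):
        train_predictor(model, matrix, panel, targets, val_genotypes=["g0"], spec=spec)


def test_assembly_is_pure_composition(tiny_setup):
    matrix, panel, _ = tiny_setup
    _, decoder = build_autoencoder(DESK_SPEC, 64, seed=0)
    predictor = build_predictor(PredictorSpec(n_snps=len(panel)), seed=2)
    before = {k: v.copy() for k, v in predictor.state_dict().items()}
    before_dec = {k: v.copy() for k, v in decoder.state_dict().items()}
    model = assemble_snp_to_image(predictor, decoder, panel)
    row = matrix.row("g0")
    drawn = model.draw(row)
    z = predictor.forward(row[list(panel.snp_ids)].to_numpy(dtype=np.float32)[None, :])
    direct = decoder.forward(z)[0].transpose(1, 2, 0)
    np.testing.assert_array_equal(drawn.pixels, direct)
    for k in before:
        np.testing.assert_array_equal(predictor.state_dict()[k], before[k])
    for k in before_dec:
        np.testing.assert_array_equal(decoder.state_dict()[k], before_dec[k])


def test_assembly_dimension_mismatch_rejected(tiny_setup):
    matrix, panel, _ = tiny_setup
    _, decoder = build_autoencoder(DESK_SPEC, 64, seed=0)
    bad = build_predictor(PredictorSpec(n_snps=len(panel), output_dim=32))
    with pytest.raises(ValueError, match="match|mismatch"):
        assemble_snp_to_image(bad, decoder, panel)


def test_draw_is_deterministic_and_validates_input(tiny_setup):
    matrix, panel, _ = tiny_setup
    _, decoder = build_autoencoder(DESK_SPEC, 64, seed=1)
    model = assemble_snp_to_image(
        build_predictor(PredictorSpec(n_snps=len(panel)), seed=3), decoder, panel
    )
    row = matrix.row("g3")
    a, b = model.draw(row), model.draw(row)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    assert 0.0 <= a.pixels.min() and a.pixels.max() <= 1.0
    with pytest.raises(KeyError, match="missing panel SNPs"):
        model.draw(pd.Series({panel.snp_ids[0]: 0.5}))
    with pytest.raises(ValueError, match="dosages"):
        model.draw(np.full(len(panel), 0.3))


def test_untrained_model_still_draws_valid_image(tiny_setup):
    matrix, panel, _ = tiny_setup
    _, decoder = build_autoencoder(DESK_SPEC, 64, seed=9)
    model = assemble_snp_to_image(
        build_predictor(PredictorSpec(n_snps=len(panel)), seed=9), decoder, panel
    )
    img = model.draw(matrix.row("g1"))
    assert img.pixels.shape == (64, 64, 3)
    assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0


def test_predict_embeddings_frame_shape(tiny_setup):
    matrix, panel, _ = tiny_setup
    model = build_predictor(PredictorSpec(n_snps=len(panel)), seed=0)
    df = predict_embeddings(model, matrix, panel)
    assert df.shape == (len(matrix.sample_ids), 64)
    assert list(df.index) == matrix.sample_ids


def test_high_causal_dosage_draws_taller_fruit(
    population, split, embedding_targets, trained_autoencoder
):
    """Monotone effect recovery: a genotype loaded with shape-increasing
    alleles draws a visibly different (correctly ordered) FSI than one
    loaded with shape-decreasing alleles."""
    from snpdraw.phenometrics import measure_image

    genotypes = population["genotypes"]
    truth = population["truth"].set_index("genotype_id")
    causal_ids = [s for s in genotypes.snp_ids if s.startswith("causal")]
    spec = desk_predictor_spec(len(causal_ids))
    panel = select_panel(genotypes, "targeted", targeted_ids=causal_ids)
    model = build_predictor(spec, seed=0)
    train_predictor(
        model,
        genotypes,
        panel,
        embedding_targets["train"],
        sorted(split.val_genotypes),
        embedding_targets["val"],
        spec,
        seed=0,
    )
    composite = assemble_snp_to_image(model, trained_autoencoder["decoder"], panel)
    order = truth["fsi_mean"].sort_values()
    low_id, high_id = order.index[0], order.index[-1]
    fsi_low = measure_image(composite.draw(genotypes.row(low_id))).fsi
    fsi_high = measure_image(composite.draw(genotypes.row(high_id))).fsi
    assert fsi_high > fsi_low
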