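"""Autoencoder architecture contracts, training behaviour, and targets."""

import numpy as np
import pytest

from snpdraw import nn
from snpdraw.autoencoder import (
    DEFAULT_SPEC,
    DESK_SPEC,
    AutoencoderSpec,
    build_autoencoder,
    build_genotype_targets,
    decode_embeddings,
    encode_images,
    images_to_batch,
    load_checkpoint,
    save_checkpoint,
    train_autoencoder,
)
from snpdraw.phenometrics import measure_image
from snpdraw.synthetic_fruit import ShapeParams, render_fruit


def _dense_layers(model):
    return [l for l in model.layers if isinstance(l, nn.Dense)]


def test_full_scale_architecture_matches_reference_sizes():
    """At 300 px the encoder's dense chain is 8192/4096/2048 with a
    64-unit sigmoid bottleneck, mirrored by the decoder."""
    enc, dec = build_autoencoder(DEFAULT_SPEC, image_size=300, seed=0)
    enc_dense = _dense_layers(enc)
    assert [d.W.data.shape[1] for d in enc_dense] == [8192, 4096, 2048, 64]
    assert enc_dense[0].W.data.shape[0] == 128 * 5 * 5  # flatten of final conv map
    dec_dense = _dense_layers(dec)
    assert [d.W.data.shape[1] for d in dec_dense] == [2048, 4096, 8192, 3200]
    assert isinstance(enc.layers[-1], nn.Sigmoid)
    assert isinstance(dec.layers[-1], nn.Sigmoid)


def test_full_scale_forward_pass_stays_in_unit_interval():
    enc, dec = build_autoencoder(DEFAULT_SPEC, image_size=300, seed=0)
    x = np.random.default_rng(0).uniform(0, 1, (1, 3, 300, 300)).astype(np.float32)
    z = enc.forward(x)
    assert z.shape == (1, 64)
    assert float(z.min()) >= 0.0 and float(z.max()) <= 1.0
    out = dec.forward(z)
    assert out.shape == (1, 3, 300, 300)
    assert float(out.min()) >= 0.0 and float(out.max()) <= 1.0


def test_desk_scale_shape_audit_forward_and_backward():
    enc, dec = build_autoencoder(DESK_SPEC, image_size=64, seed=1)
    x = np.random.default_rng(1).uniform(0, 1, (3, 3, 64, 64)).astype(np.float32)
    z = enc.forward(x)
    assert z.shape == (3, 64)
    out = dec.forward(z)
    assert out.shape == x.shape
    _, grad = nn.mse_loss(out, x)
    gz = dec.backward(grad.astype(np.float32))
    assert gz.shape == z.shape
    gx = enc.backward(gz)
    assert gx.shape == x.shape


def test_incompatible_image_size_names_failing_dimension():
    with pytest.raises(ValueError, match="px"):
        build_autoencoder(DEFAULT_SPEC, image_size=16)


def test_spec_invariants_validated():
    with pytest.raises(ValueError, match="non-decreasing"):
        AutoencoderSpec(n_conv_layers=3, filters=(32, 16, 64), dense_sizes=(128,))
    with pytest.raises(ValueError, match="filters length"):
        AutoencoderSpec(n_conv_layers=2, filters=(16, 32, 64))


def test_overfitting_one_repeated_image_reduces_mse():
    img = render_fruit(ShapeParams(fsi_target=1.1), image_size=64)
    batch = [img] * 8
    enc, dec = build_autoencoder(DESK_SPEC, 64, seed=0)
    X = images_to_batch(batch)
    initial = nn.mse_loss(dec.forward(enc.forward(X)), X)[0]
    history = train_autoencoder(
        enc, dec, batch, loss="mse", epochs=5, optimizer="adam",
        learning_rate=3e-3, batch_size=8, seed=0,
    )
    assert len(history) == 5
    assert history[-1] < initial


def test_training_rejects_empty_set_and_unknown_loss():
    enc, dec = build_autoencoder(DESK_SPEC, 64, seed=0)
    with pytest.raises(ValueError):
        train_autoencoder(enc, dec, [], epochs=1)
    img = render_fruit(ShapeParams(), image_size=64)
    with pytest.raises(ValueError, match="unknown loss"):
        train_autoencoder(enc, dec, [img], loss="nope", epochs=1)


def test_perceptual_loss_unavailable_is_advised_at_training_time():
    enc, dec = build_autoencoder(DESK_SPEC, 64, seed=0)
    img = render_fruit(ShapeParams(), image_size=64)
    with pytest.raises(ValueError, match="mse|ssim"):
        train_autoencoder(enc, dec, [img], loss="perceptual", epochs=1)


def test_identical_images_give_identical_embeddings():
    enc, _ = build_autoencoder(DESK_SPEC, 64, seed=2)
    img = render_fruit(ShapeParams(fsi_target=0.9), image_size=64)
    z = encode_images(enc, [img, img])
    np.testing.assert_array_equal(z[0], z[1])
    assert z.shape == (2, 64)
    assert z.min() >= 0.0 and z.max() <= 1.0


def test_trained_embeddings_separate_shapes_better_than_replicates(trained_autoencoder):
    """After training, two very different silhouettes are farther apart in
    embedding space than two images of the same genotype."""
    enc = trained_autoencoder["encoder"]
    far_a = render_fruit(ShapeParams(fsi_target=0.7), image_size=64)
    far_b = render_fruit(ShapeParams(fsi_target=1.3), image_size=64)
    val = trained_autoencoder["val_images"]
    same = [im for im in val if im.genotype_id == val[0].genotype_id][:2]
    z = encode_images(enc, [far_a, far_b] + same)
    d_far = np.linalg.norm(z[0] - z[1])
    d_same = np.linalg.norm(z[2] - z[3])
    assert d_far > d_same


def test_shape_retention_on_trained_fixture(trained_autoencoder_hires):
    """Decoded reconstructions keep the fruit shape index for >= 90% of
    held-out images (measured at 96 px, where 0.05 FSI is ~3 px)."""
    enc = trained_autoencoder_hires["encoder"]
    dec = trained_autoencoder_hires["decoder"]
    val = trained_autoencoder_hires["val_images"]
    rec = decode_embeddings(dec, encode_images(enc, val))
    errs = np.array(
        [abs(measure_image(r).fsi - measure_image(o).fsi) for o, r in zip(val, rec)]
    )
    assert (errs <= 0.05).mean() >= 0.9


def test_smoothed_training_loss_non_increasing(trained_autoencoder):
    # a single continuous run; the concatenated two-phase history has a
    # harmless bump where the optimizer state restarts
    history = np.asarray(trained_autoencoder["history_15"])
    smooth = np.convolve(history, np.ones(5) / 5, mode="valid")
    assert np.all(np.diff(smooth) <= 1e-6)


def test_mean_targets_equal_brute_force_means():
    rng = np.random.default_rng(0)
    emb = rng.uniform(0, 1, (12, 6))
    gids = ["a", "a", "b", "c", "b", "a", "c", "c", "c", "b", "a", "b"]
    targets = build_genotype_targets(emb, gids)
    for g in "abc":
        brute = np.zeros(6)
        n = 0
        for i, gid in enumerate(gids):
            if gid == g:
                brute += emb[i]
                n += 1
        np.testing.assert_allclose(targets.mean_embeddings[g], brute / n, rtol=1e-12)


def test_mean_of_two_vectors_is_elementwise():
    emb = np.array([[0.2, 0.6], [0.4, 0.8]])
    targets = build_genotype_targets(emb, ["g", "g"])
    np.testing.assert_allclose(targets.mean_embeddings["g"], [0.3, 0.7])


def test_decoded_mean_of_identical_embeddings_equals_single_decode():
    _, dec = build_autoencoder(DESK_SPEC, 64, seed=3)
    z = np.full((3, 64), 0.4, dtype=np.float32)
    targets = build_genotype_targets(z, ["g", "g", "g"], decoder=dec)
    single = decode_embeddings(dec, z[:1])[0]
    np.testing.assert_allclose(targets.decoded_means["g"], single, atol=1e-6)


def test_target_matrix_shape_scales_with_population(trained_autoencoder):
    imgs = trained_autoencoder["train_images"]
    z = encode_images(trained_autoencoder["encoder"], imgs)
    targets = build_genotype_targets(z, [im.genotype_id for im in imgs])
    n_geno = len({im.genotype_id for im in imgs})
    assert targets.matrix().shape == (n_geno, 64)


def test_mismatched_ids_rejected():
    with pytest.raises(ValueError):
        build_genotype_targets(np.zeros((3, 4)), ["a", "b"])


def test_checkpoint_roundtrip_preserves_encodings(tmp_path):
    enc, dec = build_autoencoder(DESK_SPEC, 64, seed=4)
    img = render_fruit(ShapeParams(fsi_target=1.2), image_size=64)
    z_before = encode_images(enc, [img])
    path = tmp_path / "ae.npz"
    save_checkpoint(path, enc, dec, DESK_SPEC, 64)
    enc2, dec2, spec, size = load_checkpoint(path)
    assert spec == DESK_SPEC and size == 64
    np.testing.assert_allclose(encode_images(enc2, [img]), z_before, atol=1e-7)
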