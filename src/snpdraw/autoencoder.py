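"""Convolutional autoencoder: image -> 64-value embedding -> image.

The encoder stacks stride-2 3x3 convolutions (ReLU), flattens, and passes
through leaky-ReLU dense layers down to a sigmoid bottleneck, so every
embedding coordinate lies in [0, 1]. The decoder mirrors the encoder
layer-for-layer (transposed convolutions, matching output paddings) and
ends in a sigmoid, so decoded intensities also lie in [0, 1].

Two ready-made profiles are provided:

* :data:`DEFAULT_SPEC` — the full-scale architecture for 300 px images
  (6 convs, filters 16..128, dense 8192/4096/2048, embedding 64);
* :data:`DESK_SPEC` — a reduced CPU-friendly profile for 64 px images
  (4 convs, filters 8..64, dense 1024/512/256, embedding 64).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .synthetic_fruit import FruitImage

__all__ = [
    "AutoencoderSpec",
    "DEFAULT_SPEC",
    "DESK_SPEC",
    "GenotypeEmbeddingTargets",
    "build_autoencoder",
    "train_autoencoder",
    "encode_images",
    "decode_embeddings",
    "build_genotype_targets",
    "save_checkpoint",
    "load_checkpoint",
    "images_to_batch",
    "batch_to_images",
]


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture hyperparameters of the convolutional autoencoder."""

    n_conv_layers: int = 6
    kernel: int = 3
    stride: int = 2
    filters: tuple[int, ...] = (16, 32, 48, 64, 96, 128)
    dense_sizes: tuple[int, ...] = (8192, 4096, 2048)
    embedding_dim: int = 64
    leaky_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if len(self.filters) != self.n_conv_layers:
            raise ValueError("filters length must equal n_conv_layers")
        if any(b < a for a, b in zip(self.filters, self.filters[1:])):
            raise ValueError("filters must be non-decreasing")


DEFAULT_SPEC = AutoencoderSpec()
DESK_SPEC = AutoencoderSpec(
    n_conv_layers=4,
    filters=(8, 16, 32, 64),
    dense_sizes=(1024, 512, 256),
)


def _conv_chain_sizes(spec: AutoencoderSpec, image_size: int) -> list[int]:
    sizes = [image_size]
    for i in range(spec.n_conv_layers):
        nxt = (sizes[-1] + 2 - spec.kernel) // spec.stride + 1
        if nxt < 2:
            raise ValueError(
                f"conv layer {i + 1} would reduce the feature map to {nxt} px "
                f"(from input {image_size} px); use fewer conv layers or larger images"
            )
        sizes.append(nxt)
    return sizes


def build_autoencoder(
    spec: AutoencoderSpec = DEFAULT_SPEC, image_size: int = 300, seed: int = 0
) -> tuple[nn.Sequential, nn.Sequential]:
    """Build mirrored (encoder, decoder) networks for square RGB images."""
    rng = np.random.default_rng(seed)
    sizes = _conv_chain_sizes(spec, image_size)
    final = sizes[-1]
    flat = spec.filters[-1] * final * final

    enc_layers: list[nn.layers.Layer] = []
    c_prev = 3
    for i, c in enumerate(spec.filters):
        enc_layers.append(
            nn.Conv2d(c_prev, c, rng, spec.kernel, spec.stride, 1, name=f"enc_conv{i}")
        )
        enc_layers.append(nn.ReLU())
        c_prev = c
    enc_layers.append(nn.Flatten())
    d_prev = flat
    for i, d in enumerate(spec.dense_sizes):
        enc_layers.append(nn.Dense(d_prev, d, rng, init="he", name=f"enc_fc{i}"))
        enc_layers.append(nn.LeakyReLU(spec.leaky_alpha))
        d_prev = d
    # two guards against latent collapse: LayerNorm keeps the bottleneck's
    # input scale bounded whatever the dense stack drifts to, and BatchNorm
    # on the pre-activation forces the code to vary across the batch so the
    # sigmoid cannot saturate into a constant embedding
    enc_layers.append(nn.LayerNorm())
    enc_layers.append(
        nn.Dense(d_prev, spec.embedding_dim, rng, init="xavier", name="enc_bottleneck")
    )
    enc_layers.append(nn.BatchNorm())
    enc_layers.append(nn.Sigmoid())
    encoder = nn.Sequential(enc_layers)

    dec_layers: list[nn.layers.Layer] = []
    d_prev = spec.embedding_dim
    for i, d in enumerate(reversed(spec.dense_sizes)):
        dec_layers.append(nn.Dense(d_prev, d, rng, init="he", name=f"dec_fc{i}"))
        dec_layers.append(nn.LeakyReLU(spec.leaky_alpha))
        d_prev = d
    dec_layers.append(nn.Dense(d_prev, flat, rng, init="he", name="dec_expand"))
    dec_layers.append(nn.LeakyReLU(spec.leaky_alpha))
    dec_layers.append(nn.Reshape((spec.filters[-1], final, final)))
    chan = list(spec.filters)[::-1][1:] + [3]  # mirror: ...,16 -> 3
    c_prev = spec.filters[-1]
    for i, c_out in enumerate(chan):
        small = sizes[-(i + 1)]
        big = sizes[-(i + 2)]
        op = big - ((small - 1) * spec.stride - 2 + spec.kernel)
        if not 0 <= op < spec.stride:
            raise ValueError(f"cannot invert conv chain at stage {i} ({small}->{big} px)")
        dec_layers.append(
            nn.ConvTranspose2d(
                c_prev, c_out, rng, spec.kernel, spec.stride, 1, op, name=f"dec_conv{i}"
            )
        )
        dec_layers.append(nn.ReLU() if c_out != 3 else nn.Sigmoid())
        c_prev = c_out
    decoder = nn.Sequential(dec_layers)
    return encoder, decoder


def images_to_batch(images) -> np.ndarray:
    """Stack FruitImages (or (H,W,3) arrays) into an (N,3,H,W) float32 batch."""
    arrs = [
        im.pixels if isinstance(im, FruitImage) else np.asarray(im) for im in images
    ]
    batch = np.stack(arrs).astype(np.float32)
    if batch.ndim != 4 or batch.shape[-1] != 3:
        raise ValueError("expected (N, H, W, 3) images")
    return batch.transpose(0, 3, 1, 2)


def batch_to_images(batch: np.ndarray) -> np.ndarray:
    """(N,3,H,W) -> (N,H,W,3)."""
    return np.asarray(batch).transpose(0, 2, 3, 1)


_LOSSES = {"mse": nn.mse_loss, "ssim": nn.ssim_loss}


def _resolve_loss(loss):
    if callable(loss):
        return loss
    if loss == "perceptual":
        # constructing without a feature extractor raises the advisory error
        return nn.PerceptualLoss(None)
    try:
        return _LOSSES[loss]
    except KeyError:
        raise ValueError(f"unknown loss {loss!r}; choose mse, ssim, or perceptual")


def train_autoencoder(
    encoder: nn.Sequential,
    decoder: nn.Sequential,
    images,
    loss: str = "mse",
    epochs: int = 35,
    optimizer: str = "sgd",
    learning_rate: float | None = None,
    momentum: float = 0.9,
    batch_size: int = 32,
    lr_schedule: str | None = None,
    augment: str | None = None,
    seed: int = 0,
) -> list[float]:
    """Train encoder+decoder jointly to reconstruct the training images.

    Returns the per-epoch mean training loss (length = ``epochs``).
    ``loss`` may be ``'mse'``, ``'ssim'``, ``'perceptual'`` (needs a feature
    extractor — see :class:`snpdraw.nn.PerceptualLoss`), or any callable
    ``(pred, target) -> (value, grad)``.

    ``augment='vstretch'`` applies a random vertical rescale (factor
    0.85–1.15) to half the training images each step, widening the range
    of aspect ratios the representation covers; useful on small training
    sets whose held-out genotypes may fall outside the training shape
    range.
    """
    if len(images) < 1:
        raise ValueError("need at least one training image")
    loss_fn = _resolve_loss(loss)
    X = images if isinstance(images, np.ndarray) else images_to_batch(images)
    params = encoder.params() + decoder.params()
    if optimizer == "sgd":
        opt = nn.SGD(params, lr=0.01 if learning_rate is None else learning_rate, momentum=momentum)
    elif optimizer == "adam":
        opt = nn.Adam(params, lr=1e-3 if learning_rate is None else learning_rate)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    history: list[float] = []
    _init_output_bias(decoder, X)
    encoder.train(True)
    decoder.train(True)
    lr0 = opt.lr
    for epoch in range(epochs):
        if lr_schedule == "cosine":
            # decay to lr0/10; quietens late-epoch noise on short runs
            opt.lr = lr0 * (0.1 + 0.45 * (1 + np.cos(np.pi * epoch / max(epochs - 1, 1))))
        elif lr_schedule is not None:
            raise ValueError(f"unknown lr_schedule {lr_schedule!r}")
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            xb = X[order[start : start + batch_size]]
            if augment == "vstretch":
                xb = _vstretch_batch(xb, rng)
            elif augment is not None:
                raise ValueError(f"unknown augment {augment!r}")
            z = encoder.forward(xb)
            xr = decoder.forward(z)
            value, grad = loss_fn(xr, xb)
            opt.zero_grad()
            gz = decoder.backward(grad.astype(np.float32))
            encoder.backward(gz)
            opt.step()
            losses.append(value)
        history.append(float(np.mean(losses)))
    _recalibrate_batchnorm(encoder, X)
    encoder.eval()
    decoder.eval()
    return history


def _vstretch_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly rescale half the images vertically (nearest-neighbour row
    resampling about the centre); edge rows clip to background."""
    xb = xb.copy()
    h = xb.shape[2]
    cy = (h - 1) / 2.0
    rows = np.arange(h)
    for i in range(xb.shape[0]):
        if rng.random() < 0.5:
            continue
        f = rng.uniform(0.85, 1.15)
        src = np.clip(np.round(cy + (rows - cy) / f).astype(int), 0, h - 1)
        xb[i] = xb[i][:, src, :]
    return xb


def _init_output_bias(decoder: nn.Sequential, X: np.ndarray) -> None:
    """Base-rate initialisation: start the sigmoid output at the training
    set's per-channel mean intensity, so early epochs are spent on image
    structure rather than on finding the background level."""
    last_param_layer = None
    for layer in decoder.layers:
        if layer.params():
            last_param_layer = layer
    if not isinstance(last_param_layer, nn.ConvTranspose2d):
        return
    if np.any(last_param_layer.b.data != 0.0):
        return  # already trained or customised
    mean = X.mean(axis=(0, 2, 3)).astype(np.float64)
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    last_param_layer.b.data[...] = np.log(mean / (1 - mean)).astype(np.float32)


def _recalibrate_batchnorm(model: nn.Sequential, X: np.ndarray) -> None:
    """Replace lagging exponential BatchNorm statistics with exact
    statistics over the training set (one forward pass, momentum 0)."""
    bns = [l for l in model.layers if isinstance(l, nn.BatchNorm)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.0
        bn.training = True
    model.forward(X)
    for bn, m in zip(bns, saved):
        bn.momentum = m


def encode_images(encoder: nn.Sequential, images, batch_size: int = 64) -> np.ndarray:
    """Deterministically encode images to (N, embedding_dim) in [0, 1]."""
    X = images if isinstance(images, np.ndarray) else images_to_batch(images)
    encoder.eval()
    outs = [
        encoder.forward(X[i : i + batch_size]) for i in range(0, X.shape[0], batch_size)
    ]
    return np.concatenate(outs, axis=0)


def decode_embeddings(decoder: nn.Sequential, embeddings: np.ndarray) -> np.ndarray:
    """Decode (N, embedding_dim) vectors to (N, H, W, 3) images in [0, 1]."""
    z = np.atleast_2d(np.asarray(embeddings, dtype=np.float32))
    decoder.eval()
    return batch_to_images(decoder.forward(z))


@dataclass
class GenotypeEmbeddingTargets:
    """Per-genotype mean embeddings and their decoded mean images."""

    mean_embeddings: dict[str, np.ndarray]
    decoded_means: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.mean_embeddings)

    def matrix(self, genotype_ids: list[str] | None = None) -> np.ndarray:
        ids = genotype_ids if genotype_ids is not None else self.genotype_ids
        return np.stack([self.mean_embeddings[g] for g in ids])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix(), index=self.genotype_ids)
        df.columns = [f"e{i + 1}" for i in range(df.shape[1])]
        df.index.name = "genotype_id"
        df.to_csv(path)


def build_genotype_targets(
    embeddings: np.ndarray,
    genotype_ids: list[str],
    decoder: nn.Sequential | None = None,
) -> GenotypeEmbeddingTargets:
    """Group per-image embeddings by genotype and average element-wise.

    When a decoder is given, each mean vector is also decoded into the
    genotype's mean image (the phenometric reference for prediction
    quality).
    """
    embeddings = np.asarray(embeddings)
    if embeddings.shape[0] != len(genotype_ids):
        raise ValueError("one genotype id per embedding row is required")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(genotype_ids):
        groups.setdefault(str(g), []).append(i)
    for g, idx in groups.items():
        if not idx:
            raise ValueError(f"genotype {g!r} has no images")
    means = {g: embeddings[idx].mean(axis=0) for g, idx in groups.items()}
    targets = GenotypeEmbeddingTargets(mean_embeddings=means)
    if decoder is not None:
        decoded = decode_embeddings(decoder, np.stack(list(means.values())))
        targets.decoded_means = dict(zip(means.keys(), decoded))
    return targets


def save_checkpoint(
    path,
    encoder: nn.Sequential,
    decoder: nn.Sequential,
    spec: AutoencoderSpec,
    image_size: int,
    extra: dict | None = None,
) -> None:
    """Single-file .npz checkpoint with the spec embedded as JSON."""
    meta = {"spec": asdict(spec), "image_size": image_size, "extra": extra or {}}
    arrays = {f"enc/{k}": v for k, v in encoder.state_dict().items()}
    arrays.update({f"dec/{k}": v for k, v in decoder.state_dict().items()})
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[nn.Sequential, nn.Sequential, AutoencoderSpec, int]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    spec_d = meta["spec"]
    spec_d["filters"] = tuple(spec_d["filters"])
    spec_d["dense_sizes"] = tuple(spec_d["dense_sizes"])
    spec = AutoencoderSpec(**spec_d)
    encoder, decoder = build_autoencoder(spec, meta["image_size"], seed=0)
    encoder.load_state_dict(
        {k[4:]: data[k] for k in data.files if k.startswith("enc/")}
    )
    decoder.load_state_dict(
        {k[4:]: data[k] for k in data.files if k.startswith("dec/")}
    )
    return encoder, decoder, spec, meta["image_size"]
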