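"""Reconstruction and regression losses.

Each loss returns ``(value, grad)`` where ``grad`` is the derivative of the
scalar loss with respect to the prediction array, so training loops can feed
it straight into ``Sequential.backward``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["mse_loss", "mae_loss", "ssim_loss", "PerceptualLoss"]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def _ssim_channel(
    x: np.ndarray, y: np.ndarray, c1: float, c2: float
) -> tuple[float, np.ndarray]:
    """Global (whole-image) SSIM of prediction y against target x, with
    the gradient w.r.t. y. Statistics are taken over all pixels of the
    channel, i.e. a single-window SSIM."""
    n = x.size
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    cxy = ((x - mx) * (y - my)).mean()
    a1, a2 = 2 * mx * my + c1, 2 * cxy + c2
    b1, b2 = mx**2 + my**2 + c1, vx + vy + c2
    s = (a1 * a2) / (b1 * b2)
    # quotient rule; d my/dy = 1/n, d vy/dy = 2(y-my)/n, d cxy/dy = (x-mx)/n
    da1 = 2 * mx / n
    da2 = 2 * (x - mx) / n
    db1 = 2 * my / n
    db2 = 2 * (y - my) / n
    grad = (da1 * a2 + a1 * da2) / (b1 * b2) - s * (db1 * b2 + b1 * db2) / (b1 * b2)
    return float(s), grad


def ssim_loss(
    pred: np.ndarray, target: np.ndarray, c1: float = 0.01**2, c2: float = 0.03**2
) -> tuple[float, np.ndarray]:
    """1 - mean global SSIM over samples and channels, for (N,C,H,W) batches."""
    n, c = pred.shape[0], pred.shape[1]
    total = 0.0
    grad = np.zeros_like(pred)
    for i in range(n):
        for ch in range(c):
            s, g = _ssim_channel(target[i, ch], pred[i, ch], c1, c2)
            total += s
            grad[i, ch] = -g / (n * c)
    return 1.0 - total / (n * c), grad


class PerceptualLoss:
    """Feature-reconstruction loss: sum of L1 distances between feature maps
    of prediction and target under a frozen feature extractor.

    The extractor is a sequence of callables mapping (N,C,H,W) -> feature
    maps (typically the early pooling stages of a pretrained classification
    network). No pretrained weights ship with this package, so an extractor
    must be supplied explicitly; otherwise construction fails with advice to
    use the self-contained ``mse``/``ssim`` losses.
    """

    def __init__(self, stages: Sequence[Callable] | None = None) -> None:
        if not stages:
            raise ValueError(
                "perceptual loss needs a pretrained feature extractor, and none "
                "is bundled with this package; pass feature stages explicitly "
                "or fall back to loss='mse' or loss='ssim'"
            )
        self.stages = list(stages)

    def __call__(self, pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
        # Stages must be snpdraw.nn layers (forward/backward protocol).
        # Target features first, so layer caches left behind belong to the
        # prediction pass when we backpropagate.
        ft_list = []
        ft = target
        for stage in self.stages:
            ft = stage.forward(ft)
            ft_list.append(ft)
        fp_list = []
        fp = pred
        for stage in self.stages:
            fp = stage.forward(fp)
            fp_list.append(fp)
        total = 0.0
        grads = []
        for fp, ft in zip(fp_list, ft_list):
            diff = fp - ft
            total += float(np.mean(np.abs(diff)))
            grads.append(np.sign(diff) / diff.size)
        upstream = np.zeros_like(grads[-1])
        for stage, g in zip(reversed(self.stages), reversed(grads)):
            upstream = stage.backward(upstream + g)
        return total, upstream
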