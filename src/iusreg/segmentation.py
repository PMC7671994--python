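"""Resection-cavity segmentation with a compact 3D U-Net.

The network follows the encoder--decoder U-Net pattern with three
resolution steps by default: per level two 3x3x3 convolutions (instance
normalization + ReLU), max-pooling on the way down, 2x2x2 up-convolution
with skip concatenation on the way up, dropout (p=0.3) before each
synthesis-path convolution, and a final 1-voxel convolution + sigmoid
giving a per-voxel cavity probability.

Training uses the Tversky loss, which weights false negatives (beta) more
heavily than false positives (alpha) when beta > alpha and therefore favors
over-segmentation — the right bias for a structure that is subsequently
cleaned up by keeping only its largest connected component. Patches are
sampled so that a configurable fraction (default 20%) contains only
background; the rest must contain at least one foreground voxel.

The implementation is pure numpy (see :mod:`iusreg.nn`); it is sized for
patch-based training of small volumetric models on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from . import nn
from .grids import BinaryMask, Volume3D

__all__ = ["UNetConfig", "PatchSample", "UNet3D", "sample_patches",
           "tversky_loss", "build_unet", "train", "predict_mask",
           "largest_component", "TrainingError"]


class TrainingError(RuntimeError):
    pass


@dataclass
class UNetConfig:
    """Hyperparameters of the segmentation stage.

    ``patch_core`` is the labelled region per patch; the network input
    additionally sees ``patch_pad`` voxels of image context on every side,
    so input blocks are (core + 2*pad)^3. The loss is evaluated on the
    central core only.
    """

    levels: int = 3
    base_channels: int = 16
    dropout_p: float = 0.3
    patch_core: int = 48
    patch_pad: int = 20
    batch_size: int = 5
    learning_rate: float = 0.0005
    bg_patch_fraction: float = 0.2
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    epochs: int = 30
    patches_per_epoch: int = 20
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if not 0 <= self.bg_patch_fraction <= 1:
            raise ValueError("bg_patch_fraction must be in [0, 1]")
        if abs(self.tversky_alpha + self.tversky_beta - 1.0) > 1e-9:
            raise ValueError("tversky_alpha + tversky_beta must equal 1")
        for name in ("levels", "base_channels", "patch_core", "batch_size",
                     "epochs", "patches_per_epoch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patch_pad < 0:
            raise ValueError("patch_pad must be >= 0")
        if self.patch_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"patch input size {self.patch_size} must be divisible by "
                f"2^levels = {2 ** self.levels}")

    @property
    def patch_size(self) -> int:
        return self.patch_core + 2 * self.patch_pad


@dataclass
class PatchSample:
    """One training patch: image context block + label core."""

    image_patch: np.ndarray   # (core+2*pad)^3 float32
    label_patch: np.ndarray   # core^3 bool
    origin_index: tuple       # corner of the core in the source volume


def tversky_loss(pred: np.ndarray, target: np.ndarray, alpha: float,
                 beta: float, smooth: float = 1e-5) -> float:
    """Soft Tversky loss on probability maps.

    ``1 - (TP+s)/(TP + alpha*FP + beta*FN + s)`` with soft counts
    TP = sum p*t, FP = sum p*(1-t), FN = sum (1-p)*t. With
    alpha = beta = 0.5 this is exactly one minus the soft DICE coefficient.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    tp = float((p * t).sum())
    fp = float((p * (1 - t)).sum())
    fn = float(((1 - p) * t).sum())
    return 1.0 - (tp + smooth) / (tp + alpha * fp + beta * fn + smooth)


def sample_patches(volume: Volume3D, label: BinaryMask, config: UNetConfig,
                   n: int, rng: np.random.Generator | None = None
                   ) -> list[PatchSample]:
    """Draw patches; each is background-only with prob. bg_patch_fraction.

    Foreground draws pick a random cavity voxel and a random core position
    containing it; background draws rejection-sample cores free of
    foreground. Blocks reaching past the volume border are mirror-padded.
    """
    if tuple(volume.shape) != tuple(label.shape):
        raise ValueError("volume and label must share one grid")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fg = np.argwhere(label.data)
    if len(fg) == 0 and config.bg_patch_fraction < 1 and n > 0:
        raise ValueError("label has no foreground but foreground patches "
                         "were requested (bg_patch_fraction < 1)")
    core = config.patch_core
    pad = config.patch_pad
    shape = np.array(volume.shape)
    # mirror-pad once; core origins may range over [-core+1, shape-1] in
    # principle, but we keep cores inside the padded support
    img = np.pad(volume.data, pad, mode="reflect")
    lab = label.data
    out = []
    for _ in range(n):
        if rng.random() < config.bg_patch_fraction:
            for _try in range(1000):
                origin = np.array([rng.integers(-core // 2,
                                                shape[a] - core // 2)
                                   for a in range(3)])
                sl = tuple(slice(max(o, 0), min(o + core, s))
                           for o, s in zip(origin, shape))
                if not lab[sl].any():
                    break
            else:
                raise ValueError("could not draw a background-only patch")
        else:
            vox = fg[rng.integers(len(fg))]
            origin = np.array([rng.integers(vox[a] - core + 1, vox[a] + 1)
                               for a in range(3)])
        label_patch = _extract(lab, origin, core, pad=0).astype(bool)
        image_patch = _extract_padded(img, origin, core, pad)
        out.append(PatchSample(image_patch, label_patch, tuple(origin)))
    return out


def _extract(arr: np.ndarray, origin, size: int, pad: int) -> np.ndarray:
    """Extract a size^3 block at origin, mirror-padding past the borders."""
    shape = np.array(arr.shape)
    lo = np.array(origin)
    hi = lo + size
    pad_lo = np.maximum(-lo, 0)
    pad_hi = np.maximum(hi - shape, 0)
    sl = tuple(slice(max(l, 0), min(h, s))
               for l, h, s in zip(lo, hi, shape))
    block = arr[sl]
    if pad_lo.any() or pad_hi.any():
        block = np.pad(block, list(zip(pad_lo, pad_hi)), mode="reflect")
    return block


def _extract_padded(padded_img: np.ndarray, origin, core: int,
                    pad: int) -> np.ndarray:
    """Image block of (core+2*pad)^3 around a core at ``origin``.

    ``padded_img`` is the volume already mirror-padded by ``pad``; the
    core origin in padded coordinates is origin + pad, so the context block
    starts at origin (padded frame).
    """
    return _extract(padded_img, np.array(origin), core + 2 * pad, 0) \
        .astype(np.float32)


class UNet3D:
    """Encoder-decoder with skip connections; see the module docstring."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params: list[nn.Parameter] = []
        c_in = 1
        self.enc = []
        ch = config.base_channels
        for lev in range(config.levels):
            self.enc.append(self._block(c_in, ch))
            c_in = ch
            ch *= 2
        self.bottleneck = self._block(c_in, ch)
        self.dec = []
        for lev in range(config.levels):
            ch_up = ch // 2
            up = self._upconv(ch, ch_up)
            block = self._block(ch_up * 2, ch_up)
            self.dec.append((up, block))
            ch = ch_up
        self.final_w = self._param((ch, 1), ch)
        self.final_b = nn.Parameter(np.zeros(1, dtype=np.float32))
        self.params.append(self.final_b)

    def _param(self, shape, fan_in):
        std = np.sqrt(2.0 / fan_in)
        p = nn.Parameter(self.rng.normal(0.0, std, shape).astype(np.float32))
        self.params.append(p)
        return p

    def _conv_layer(self, c_in, c_out):
        # weights stored as 27 (C_in, C_out) matrices, one per tap
        w = self._param((27, c_in, c_out), 27 * c_in)
        b = nn.Parameter(np.zeros(c_out, dtype=np.float32))
        g = nn.Parameter(np.ones(c_out, dtype=np.float32))
        be = nn.Parameter(np.zeros(c_out, dtype=np.float32))
        self.params += [b, g, be]
        return (w, b, g, be)

    def _block(self, c_in, c_out):
        return (self._conv_layer(c_in, c_out), self._conv_layer(c_out, c_out))

    def _upconv(self, c_in, c_out):
        w = self._param((c_in, 8 * c_out), 8 * c_in)
        b = nn.Parameter(np.zeros(c_out, dtype=np.float32))
        self.params.append(b)
        return (w, b)

    @staticmethod
    def _apply_conv(x, layer, training, dropout_p=0.0, rng=None):
        w, b, g, be = layer
        if dropout_p > 0:
            x = nn.dropout(x, dropout_p, rng, training)
        x = nn.conv3d(x, w, b)
        x = nn.instance_norm(x, g, be)
        return nn.relu(x)

    def forward(self, x: np.ndarray, training: bool = False) -> nn.Tensor:
        """x: (N, D, H, W, 1) float32 -> per-voxel probabilities.

        Inputs are standardized per sample (zero mean, unit variance) so
        the network is indifferent to the acquisition's intensity scale.
        """
        x = np.asarray(x, dtype=np.float32)
        mu = x.mean(axis=(1, 2, 3, 4), keepdims=True)
        sd = x.std(axis=(1, 2, 3, 4), keepdims=True) + 1e-6
        t = nn.Tensor((x - mu) / sd)
        skips = []
        for block in self.enc:
            for layer in block:
                t = self._apply_conv(t, layer, training)
            skips.append(t)
            t = nn.maxpool3d(t)
        for layer in self.bottleneck:
            t = self._apply_conv(t, layer, training)
        p = self.config.dropout_p
        for (up, block), skip in zip(self.dec, reversed(skips)):
            t = nn.conv_transpose3d(t, up[0], up[1])
            t = nn.concat_channels(skip, t)
            for layer in block:
                t = self._apply_conv(t, layer, training, dropout_p=p,
                                     rng=self.rng)
        t = nn.conv3d_1x1(t, self.final_w, self.final_b)
        return nn.sigmoid(t)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params)

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_state(self, state) -> None:
        for p, s in zip(self.params, state):
            p.data = s.copy()


def build_unet(config: UNetConfig) -> UNet3D:
    """Construct the 3D U-Net; weights are He-initialized from config.seed."""
    return UNet3D(config)


def train(model: UNet3D, training_set, config: UNetConfig,
          val=None):
    """Patch-based training with SGD + momentum under the Tversky loss.

    ``training_set``/``val`` are sequences of (Volume3D, BinaryMask) pairs.
    Per epoch, ``patches_per_epoch`` patches are drawn from each training
    pair and consumed in mini-batches of ``batch_size``. The model state
    with the best validation loss is restored at the end (last epoch when
    no validation set is given). Returns (model, history dataframe-like
    dict with per-epoch losses).
    """
    if not training_set:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed + 1)
    mom_state: dict = {}
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best = (np.inf, None)
    for epoch in range(config.epochs):
        batches = _draw_batches(training_set, config, rng)
        losses = []
        for xb, tb in batches:
            probs = model.forward(xb, training=True)
            core = _crop_core(probs, config)
            loss = nn.tversky_loss_op(core, tb, config.tversky_alpha,
                                      config.tversky_beta)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            nn.sgd_step(model.params, config.learning_rate, config.momentum,
                        mom_state)
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        if val:
            vb = _draw_batches(val, config, np.random.default_rng(
                config.seed + 2))
            vl = []
            for xb, tb in vb:
                probs = model.forward(xb, training=False)
                core = _crop_core(probs, config)
                vl.append(tversky_loss(core.data, tb, config.tversky_alpha,
                                       config.tversky_beta))
            val_loss = float(np.mean(vl))
        else:
            val_loss = np.nan
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        score = val_loss if val else -epoch  # no val: keep the last epoch
        if score < best[0]:
            best = (score, model.get_state())
    if best[1] is not None:
        model.set_state(best[1])
    return model, history


def _draw_batches(dataset, config: UNetConfig, rng):
    patches = []
    for vol, lab in dataset:
        patches += sample_patches(vol, lab, config, config.patches_per_epoch,
                                  rng)
    rng.shuffle(patches)
    batches = []
    for i in range(0, len(patches), config.batch_size):
        chunk = patches[i:i + config.batch_size]
        xb = np.stack([p.image_patch for p in chunk])[..., None]
        tb = np.stack([p.label_patch for p in chunk])[..., None]
        batches.append((xb.astype(np.float32), tb.astype(np.float32)))
    return batches


def _crop_core(probs: nn.Tensor, config: UNetConfig) -> nn.Tensor:
    pad = config.patch_pad
    if pad == 0:
        return probs
    data = probs.data[:, pad:-pad, pad:-pad, pad:-pad, :]

    def backward(g):
        if probs.requires_grad:
            big = np.zeros_like(probs.data)
            big[:, pad:-pad, pad:-pad, pad:-pad, :] = g
            probs._accumulate(big)

    return nn.Tensor(data, (probs,), backward)


def predict_mask(model: UNet3D, volume: Volume3D,
                 config: UNetConfig | None = None,
                 threshold: float = 0.5):
    """Segment a whole volume by tiling it into overlapping context blocks.

    The volume is partitioned into non-overlapping cores (each voxel is
    predicted exactly once; tiles at the far border shift inward and only
    write voxels not yet covered). Each core is evaluated with
    ``patch_pad`` voxels of mirror-padded context. Probabilities are
    thresholded at 0.5 and cleaned with :func:`largest_component`.

    Returns (probability Volume3D, BinaryMask).
    """
    config = config or model.config
    core = config.patch_core
    pad = config.patch_pad
    shape = np.array(volume.shape)
    img = np.pad(volume.data.astype(np.float32), pad, mode="reflect")
    probs = np.full(volume.shape, -1.0, dtype=np.float32)
    starts = [_tile_starts(shape[a], core) for a in range(3)]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                origin = np.array([sx, sy, sz])
                block = _extract(img, origin, core + 2 * pad, 0)[None, ...,
                                                                 None]
                out = model.forward(block, training=False).data[0, ..., 0]
                if pad:
                    out = out[pad:-pad, pad:-pad, pad:-pad]
                sl = tuple(slice(o, min(o + core, s))
                           for o, s in zip(origin, shape))
                view = probs[sl]
                cropped = out[tuple(slice(0, v) for v in view.shape)]
                view[view < 0] = cropped[view < 0]
    prob_vol = volume.with_data(probs)
    mask = BinaryMask.on_grid(volume, probs >= threshold)
    return prob_vol, largest_component(mask)


def _tile_starts(extent: int, core: int) -> list[int]:
    if extent <= core:
        return [0]
    starts = list(range(0, extent - core + 1, core))
    if starts[-1] + core < extent:
        starts.append(extent - core)
    return starts


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected foreground component.

    Empty masks pass through unchanged; size ties keep the component whose
    label comes first in scan order.
    """
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return BinaryMask(labels == keep, mask.spacing, mask.origin,
                      mask.direction)
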