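"""3D fully convolutional DenseNet ("Tiramisu") for two-class tumor segmentation.

The encoder applies an initial 3x3x3 convolution and then alternates dense
blocks with transition-down stages; the listed ``dense_block_layers`` give
the layer counts of the encoder blocks, the last entry being the bottleneck
block, and the decoder mirrors the remaining entries in reverse.  Each dense
layer is ReLU -> 3x3x3 convolution producing ``growth_rate`` new feature
maps -> dropout, with its input the concatenation of everything produced
before it in the block.  Transition-down is a width-preserving 1x1x1
convolution, dropout, and max pooling; transition-up is nearest-neighbour
upsampling followed by a width-preserving 3x3x3 convolution, concatenated
with the skip from the same resolution.  A final 1x1x1 convolution maps to
two class channels; class probabilities are the channel softmax.

In-plane pooling always halves; the axial (z) axis is pooled only while its
current extent is even, so thin stacks (e.g. 24 slices against 4 transitions)
never collapse below one slice.  The network is fully convolutional: one
build serves any admissible input size.

Normalization layers are omitted: with batch size 1 batch statistics are
degenerate, and the fixed window normalization applied to the input (see
:mod:`idolseg.training`) already fixes the input scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._autograd import Tensor, concat, conv3d
from .volumes import Mask, Volume

__all__ = [
    "NetConfig",
    "LossConfig",
    "SegmentationModel",
    "build_network",
    "composite_loss",
    "save_checkpoint",
    "load_checkpoint",
]

PROB_FLOOR = 1e-7  # probability clamp floor inside the losses


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    The defaults are five dense blocks of 2, 3, 4, 5 and 7 layers (the last
    being the bottleneck) with growth rate 12, on single-channel input and
    two output classes.
    """

    dense_block_layers: Tuple[int, ...] = (2, 3, 4, 5, 7)
    growth_rate: int = 12
    in_channels: int = 1
    out_classes: int = 2
    dropout_rate: float = 0.2
    first_conv_channels: Optional[int] = None  # default: 4 * growth_rate

    def __post_init__(self) -> None:
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if len(self.dense_block_layers) < 2:
            raise ValueError("need at least one down block and a bottleneck")
        if self.first_conv_channels is None:
            self.first_conv_channels = 4 * self.growth_rate

    @property
    def n_down(self) -> int:
        return len(self.dense_block_layers) - 1

    @property
    def inplane_divisor(self) -> int:
        return 2**self.n_down

    def down_widths(self) -> List[int]:
        """Feature widths after each down dense block (skip widths)."""
        w = self.first_conv_channels
        widths = []
        for n in self.dense_block_layers[:-1]:
            w = w + n * self.growth_rate
            widths.append(w)
        return widths


@dataclass
class LossConfig:
    """Weights of the combined cross-entropy / dual cross-entropy / Dice loss.

    ``dce_lambda`` weighs the wrong-class penalty -log(1 - p_wrong) inside
    the dual cross-entropy term (at 0 the term reduces to plain CE);
    ``smooth`` is the soft-Dice smoothing constant.
    """

    w_ce: float = 1.0
    w_dce: float = 1.0
    w_dice: float = 1.0
    dce_lambda: float = 1.0
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.w_ce < 0 or self.w_dce < 0 or self.w_dice < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_ce + self.w_dce + self.w_dice == 0:
            raise ValueError("at least one loss weight must be positive")


def _he_conv(rng, c_out, c_in, k) -> Tuple[Tensor, Tensor]:
    fan_in = c_in * k[0] * k[1] * k[2]
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, *k))
    weight = Tensor(w.astype(np.float32), requires_grad=True)
    bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
    return weight, bias


class _Conv:
    def __init__(self, rng, c_in, c_out, k=(3, 3, 3)):
        self.w, self.b = _he_conv(rng, c_out, c_in, k)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b)

    def params(self) -> List[Tensor]:
        return [self.w, self.b]


class _DenseBlock:
    """Dense block; ``keep_input`` controls whether the output concatenates
    the block input (encoder style) or only the new features (bottleneck /
    inner decoder blocks)."""

    def __init__(self, rng, c_in, n_layers, growth, keep_input: bool):
        self.convs = []
        c = c_in
        for _ in range(n_layers):
            self.convs.append(_Conv(rng, c, growth))
            c += growth
        self.keep_input = keep_input
        self.out_channels = c if keep_input else n_layers * growth

    def __call__(self, x: Tensor, dropout, rng) -> Tensor:
        feats = []
        cur = x
        for conv in self.convs:
            h = conv(cur.relu())
            if dropout > 0 and rng is not None:
                h = h.dropout(dropout, rng)
            feats.append(h)
            cur = concat([cur, h])
        if self.keep_input:
            return cur
        return feats[0] if len(feats) == 1 else concat(feats)

    def params(self) -> List[Tensor]:
        return [p for c in self.convs for p in c.params()]


class SegmentationModel:
    """FC-DenseNet mapping a (X, Y, Z) volume to per-voxel class probabilities."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        g = cfg.growth_rate
        self.first = _Conv(rng, cfg.in_channels, cfg.first_conv_channels)
        self.down_blocks: List[_DenseBlock] = []
        self.td_convs: List[_Conv] = []
        c = cfg.first_conv_channels
        skip_widths = []
        for n in cfg.dense_block_layers[:-1]:
            db = _DenseBlock(rng, c, n, g, keep_input=True)
            self.down_blocks.append(db)
            c = db.out_channels
            skip_widths.append(c)
            self.td_convs.append(_Conv(rng, c, c, k=(1, 1, 1)))
        self.bottleneck = _DenseBlock(
            rng, c, cfg.dense_block_layers[-1], g, keep_input=False
        )
        f = self.bottleneck.out_channels
        self.tu_convs: List[_Conv] = []
        self.up_blocks: List[_DenseBlock] = []
        up_layer_counts = list(cfg.dense_block_layers[:-1])[::-1]
        for i, n in enumerate(up_layer_counts):
            self.tu_convs.append(_Conv(rng, f, f))
            c_in = f + skip_widths[len(skip_widths) - 1 - i]
            last = i == len(up_layer_counts) - 1
            db = _DenseBlock(rng, c_in, n, g, keep_input=last)
            self.up_blocks.append(db)
            f = db.out_channels
        self.classifier = _Conv(rng, f, cfg.out_classes, k=(1, 1, 1))

    # -- parameters --------------------------------------------------------

    def parameters(self) -> List[Tensor]:
        ps = self.first.params()
        for db in self.down_blocks:
            ps += db.params()
        for c in self.td_convs:
            ps += c.params()
        ps += self.bottleneck.params()
        for c in self.tu_convs:
            ps += c.params()
        for db in self.up_blocks:
            ps += db.params()
        ps += self.classifier.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def copy(self) -> "SegmentationModel":
        """Deep, independent copy (same architecture, duplicated weights)."""
        other = SegmentationModel(self.cfg, seed=0)
        for a, b in zip(other.parameters(), self.parameters()):
            a.data = b.data.copy()
        return other

    # -- forward -----------------------------------------------------------

    def _check_shape(self, shape: Tuple[int, int, int]) -> None:
        d = self.cfg.inplane_divisor
        if shape[0] % d or shape[1] % d:
            raise ValueError(
                f"in-plane dims {shape[:2]} must be divisible by {d} "
                f"(= 2^{self.cfg.n_down} transition-down stages)"
            )

    def forward_logits(
        self, x: np.ndarray, training: bool = False, rng: Optional[np.random.Generator] = None
    ) -> Tensor:
        """Logits tensor (out_classes, X, Y, Z) from a normalized 3D array."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={x.ndim}")
        self._check_shape(x.shape)
        drop = self.cfg.dropout_rate if training else 0.0
        drng = rng if training else None
        t = Tensor(x[None])
        t = self.first(t)
        skips = []
        factors = []
        for db, td in zip(self.down_blocks, self.td_convs):
            t = db(t, drop, drng)
            skips.append(t)
            z = t.data.shape[3]
            fz = 2 if z % 2 == 0 and z > 1 else 1
            factors.append((2, 2, fz))
            t = td(t)
            if drop > 0 and drng is not None:
                t = t.dropout(drop, drng)
            t = t.max_pool(factors[-1])
        t = self.bottleneck(t, drop, drng)
        for tu, db, skip, f in zip(
            self.tu_convs, self.up_blocks, skips[::-1], factors[::-1]
        ):
            t = tu(t.upsample(f))
            t = concat([t, skip])
            t = db(t, drop, drng)
        return self.classifier(t)

    def forward_prob(
        self, x: np.ndarray, training: bool = False, rng: Optional[np.random.Generator] = None
    ) -> Tensor:
        return self.forward_logits(x, training, rng).softmax_channels()

    def predict_prob(self, x: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-free) class probabilities, (2, X, Y, Z)."""
        return self.forward_prob(x, training=False).data


def build_network(cfg: NetConfig | None = None, seed: int = 0) -> SegmentationModel:
    """Construct a seeded FC-DenseNet; identical cfg and seed give identical weights."""
    return SegmentationModel(cfg if cfg is not None else NetConfig(), seed=seed)


# -- composite loss ---------------------------------------------------------


def loss_from_logits_tensor(
    logits: Tensor, truth_fg: np.ndarray, cfg: LossConfig
) -> Tensor:
    """Composite loss from raw logits, via fused log-softmax.

    Numerically preferred for training: the cross-entropy gradient with
    respect to the logits is bounded (onehot - p) even where the predicted
    probability of the true class underflows.  Same formula as
    :func:`loss_from_prob_tensor`.
    """
    y = np.asarray(truth_fg, dtype=np.float32)
    onehot = np.stack([1.0 - y, y]).astype(np.float32)
    n = float(y.size)
    logp = logits.log_softmax_channels()
    ce = logp.mul_arr(onehot).sum() * (-1.0 / n)
    p = logp.exp()
    comp = p.rsub(1.0).clamp(PROB_FLOOR, 1.0)
    wrong = comp.log().mul_arr(1.0 - onehot).sum() * (-1.0 / n)
    dce = ce + cfg.dce_lambda * wrong
    p_fg = p.slice_channel(1)
    num = p_fg.mul_arr(y).sum() * 2.0 + cfg.smooth
    den = p_fg.sum() + (float(y.sum()) + cfg.smooth)
    dice_loss = num.div(den).rsub(1.0)
    return cfg.w_ce * ce + cfg.w_dce * dce + cfg.w_dice * dice_loss


def loss_from_prob_tensor(p: Tensor, truth_fg: np.ndarray, cfg: LossConfig) -> Tensor:
    """Composite loss as an autograd node, from class probabilities.

    total = w_ce*CE + w_dce*DCE + w_dice*(1 - softDice) with
    CE   = mean_v -log p(true class),
    DCE  = CE + lambda * mean_v -log(1 - p(wrong class)),
    softDice = (2*sum(p_fg*y) + eps) / (sum(p_fg) + sum(y) + eps).
    Probabilities are clamped at 1e-7 so the loss is always finite.
    """
    y = np.asarray(truth_fg, dtype=np.float32)
    onehot = np.stack([1.0 - y, y]).astype(np.float32)
    n = float(y.size)
    pc = p.clamp(PROB_FLOOR, 1.0)
    ce = pc.log().mul_arr(onehot).sum() * (-1.0 / n)
    comp = p.rsub(1.0).clamp(PROB_FLOOR, 1.0)
    wrong = comp.log().mul_arr(1.0 - onehot).sum() * (-1.0 / n)
    dce = ce + cfg.dce_lambda * wrong
    p_fg = p.slice_channel(1)
    num = p_fg.mul_arr(y).sum() * 2.0 + cfg.smooth
    den = p_fg.sum() + (float(y.sum()) + cfg.smooth)
    dice_loss = num.div(den).rsub(1.0)
    return cfg.w_ce * ce + cfg.w_dce * dce + cfg.w_dice * dice_loss


def composite_loss(
    prob: Volume | np.ndarray, truth: Mask | np.ndarray, cfg: LossConfig | None = None
) -> float:
    """Scalar composite loss from a foreground-probability volume and a mask.

    ``prob`` holds p(foreground) per voxel; the background probability is its
    complement.  See :func:`loss_from_prob_tensor` for the formula.
    """
    cfg = cfg if cfg is not None else LossConfig()
    p_fg = np.asarray(prob.data if isinstance(prob, Volume) else prob, dtype=np.float32)
    y = np.asarray(truth.data if isinstance(truth, Mask) else truth, dtype=np.float32)
    if p_fg.shape != y.shape:
        raise ValueError(f"shape mismatch: prob {p_fg.shape} vs truth {y.shape}")
    if p_fg.min() < 0 or p_fg.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    p = Tensor(np.stack([1.0 - p_fg, p_fg]))
    return float(loss_from_prob_tensor(p, y, cfg).item())


# -- checkpoints -------------------------------------------------------------


def save_checkpoint(model: SegmentationModel, path: str) -> None:
    """Serialize weights and the embedded NetConfig to one ``.npz`` file."""
    cfg = asdict(model.cfg)
    cfg["dense_block_layers"] = list(cfg["dense_block_layers"])
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> SegmentationModel:
    with np.load(path) as npz:
        cfg_d = json.loads(bytes(npz["config"]).decode())
        cfg_d["dense_block_layers"] = tuple(cfg_d["dense_block_layers"])
        model = SegmentationModel(NetConfig(**cfg_d), seed=0)
        for i, p in enumerate(model.parameters()):
            p.data = npz[f"param_{i}"].copy()
    return model
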