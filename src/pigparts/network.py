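"""The hourglass part-detection network and its analytic description.

The architecture is an encoder-decoder of 41 layer blocks: an input
block; five encoder levels of 3x3 conv blocks (conv + batch norm + ReLU)
each followed by 2x2 max pooling; five max-unpooling stages that reuse
the pooling indices of their mirrored pooling layer; depth concatenation
of the symmetric encoder feature map immediately after the first four
unpooling stages; and a final 3x3 convolution producing the 16 output
channels.  Conv blocks per encoder level: (2, 2, 3, 3, 3); per decoder
level: (3, 3, 3, 3, 0).

Two recursions summarize what the network can see.  With per-block
stride s_l (2 for pooling, 0.5 for unpooling, 1 otherwise) the effective
stride is s^eff_l = s^eff_{l-1} * s_l, and with kernel width w_l (3 for
convolutions, lower-bounded at 1 for pooling) the receptive field is
r_l = r_{l-1} + (w_l - 1) * s^eff_{l-1}.  For this spec the bottleneck
effective stride is 32 and the output receptive field is 363 pixels
(radius 181), comfortably larger than the longest animals at the
480-column working scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentSpec, augment_annotations, augment_image, sample_draw
from .core import FrameAnnotation
from .encoder import N_CHANNELS, N_PART_CHANNELS, TargetMaps, encode_frame
from .layers import Adam, Conv3x3, ConvBlock, MaxPool2x2, MaxUnpool2x2


class BlockKind(Enum):
    INPUT = "I"
    CONV_BLOCK = "C"
    MAX_POOL = "M"
    MAX_UNPOOL = "U"
    DEPTH_CONCAT = "D"
    OUTPUT = "O"


@dataclass(frozen=True)
class LayerBlockSpec:
    kind: BlockKind
    stride: float = 1.0
    kernel_width: int = 1
    channels_out: int = 0
    pool_ref: Optional[int] = None   # unpool: index of the paired pool block
    skip_ref: Optional[int] = None   # concat: index of the encoder source block


#: conv blocks per encoder / decoder resolution level
ENCODER_CONVS = (2, 2, 3, 3, 3)
DECODER_CONVS = (3, 3, 3, 3, 0)

#: channel widths per resolution level; the default lands near the
#: 4e6-coefficient budget of the full-size network
DEFAULT_WIDTHS = (16, 32, 64, 128, 320)
SMALL_WIDTHS = (8, 16, 24, 32, 48)


def hourglass_spec(widths: Sequence[int] = DEFAULT_WIDTHS) -> list[LayerBlockSpec]:
    """The ordered 41-block hourglass layer specification."""
    if len(widths) != 5:
        raise ValueError("expected one width per resolution level")
    blocks: list[LayerBlockSpec] = [LayerBlockSpec(BlockKind.INPUT, channels_out=3)]
    pool_positions: list[int] = []
    skip_positions: list[int] = []
    for lvl in range(5):
        for _ in range(ENCODER_CONVS[lvl]):
            blocks.append(LayerBlockSpec(BlockKind.CONV_BLOCK, kernel_width=3,
                                         channels_out=widths[lvl]))
        skip_positions.append(len(blocks) - 1)
        pool_positions.append(len(blocks))
        blocks.append(LayerBlockSpec(BlockKind.MAX_POOL, stride=2.0,
                                     channels_out=widths[lvl]))
    for lvl in range(5):
        enc_lvl = 4 - lvl  # resolution level the decoder returns to
        blocks.append(LayerBlockSpec(BlockKind.MAX_UNPOOL, stride=0.5,
                                     channels_out=blocks[-1].channels_out,
                                     pool_ref=pool_positions[4 - lvl]))
        if lvl < 4:
            blocks.append(LayerBlockSpec(
                BlockKind.DEPTH_CONCAT,
                channels_out=blocks[-1].channels_out + widths[enc_lvl],
                skip_ref=skip_positions[enc_lvl]))
            target_width = widths[enc_lvl - 1] if enc_lvl > 0 else widths[0]
            for _ in range(DECODER_CONVS[lvl]):
                blocks.append(LayerBlockSpec(BlockKind.CONV_BLOCK, kernel_width=3,
                                             channels_out=target_width))
    blocks.append(LayerBlockSpec(BlockKind.OUTPUT, kernel_width=3,
                                 channels_out=N_CHANNELS))
    assert len(blocks) == 41, len(blocks)
    return blocks


def effective_strides(spec: Sequence[LayerBlockSpec]) -> list[float]:
    """Cumulative product of block strides (s0 = 1)."""
    out, s = [], 1.0
    for block in spec:
        s *= block.stride
        out.append(s)
    return out


def receptive_field(spec: Sequence[LayerBlockSpec]) -> list[int]:
    """Receptive-field recursion; pooling kernels use the lower bound w=1."""
    strides = effective_strides(spec)
    out, r = [], 1.0
    prev_stride = 1.0
    for i, block in enumerate(spec):
        if i > 0:
            r += (block.kernel_width - 1) * prev_stride
        prev_stride = strides[i]
        out.append(int(round(r)))
    return out


# ---------------------------------------------------------------------------
# trainable model


class HourglassModel:
    """Runtime realization of a 41-block hourglass spec."""

    def __init__(self, spec: Sequence[LayerBlockSpec], seed: int = 0):
        self.spec = list(spec)
        rng = np.random.default_rng(seed)
        self.enc_convs: list[list[ConvBlock]] = []
        self.pools: list[MaxPool2x2] = []
        self.dec_convs: list[list[ConvBlock]] = []
        self.unpools: list[MaxUnpool2x2] = []
        self.concat_levels: list[bool] = []

        c_prev = 3
        i = 1
        skip_widths: list[int] = []
        for lvl in range(5):
            convs = []
            while self.spec[i].kind is BlockKind.CONV_BLOCK:
                convs.append(ConvBlock(c_prev, self.spec[i].channels_out, rng))
                c_prev = self.spec[i].channels_out
                i += 1
            assert self.spec[i].kind is BlockKind.MAX_POOL
            skip_widths.append(c_prev)
            self.enc_convs.append(convs)
            self.pools.append(MaxPool2x2())
            i += 1
        for lvl in range(5):
            assert self.spec[i].kind is BlockKind.MAX_UNPOOL
            self.unpools.append(MaxUnpool2x2(self.pools[4 - lvl]))
            i += 1
            has_concat = i < len(self.spec) and self.spec[i].kind is BlockKind.DEPTH_CONCAT
            self.concat_levels.append(has_concat)
            convs = []
            if has_concat:
                c_prev = c_prev + skip_widths[4 - lvl]
                i += 1
                while self.spec[i].kind is BlockKind.CONV_BLOCK:
                    convs.append(ConvBlock(c_prev, self.spec[i].channels_out, rng))
                    c_prev = self.spec[i].channels_out
                    i += 1
            self.dec_convs.append(convs)
        assert self.spec[i].kind is BlockKind.OUTPUT
        self.out_conv = Conv3x3(c_prev, N_CHANNELS, rng)
        self._skip_shapes: list[tuple[int, int, int]] | None = None

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """[H, W, 3] float32 -> [H, W, 16]; H and W must be multiples of 32."""
        if x.shape[0] % 32 or x.shape[1] % 32:
            raise ValueError("input spatial dims must be multiples of 32 "
                             "(use predict_maps for arbitrary sizes)")
        x = x.astype(np.float32)
        skips = []
        for lvl in range(5):
            for blk in self.enc_convs[lvl]:
                x = blk.forward(x, train)
            skips.append(x)
            x = self.pools[lvl].forward(x, train)
        self._skips = skips if train else None
        for lvl in range(5):
            x = self.unpools[lvl].forward(x, train)
            if self.concat_levels[lvl]:
                x = np.concatenate([x, skips[4 - lvl]], axis=-1)
            for blk in self.dec_convs[lvl]:
                x = blk.forward(x, train)
        return self.out_conv.forward(x, train)

    def backward(self, dy: np.ndarray) -> None:
        skip_grads: list[np.ndarray | None] = [None] * 5
        g = self.out_conv.backward(dy)
        for lvl in reversed(range(5)):
            for blk in reversed(self.dec_convs[lvl]):
                g = blk.backward(g)
            if self.concat_levels[lvl]:
                c_skip = self._skips[4 - lvl].shape[-1]
                g, g_skip = g[..., :-c_skip], g[..., -c_skip:]
                skip_grads[4 - lvl] = g_skip
            g = self.unpools[lvl].backward(g)
        for lvl in reversed(range(5)):
            g = self.pools[lvl].backward(g)
            if skip_grads[lvl] is not None:
                g = g + skip_grads[lvl]
            for blk in reversed(self.enc_convs[lvl]):
                g = blk.backward(g)
        self._skips = None

    def parameters(self):
        out = []
        for lvl in range(5):
            for bi, blk in enumerate(self.enc_convs[lvl]):
                out += [(f"enc{lvl}.{bi}.{n}", v, g) for n, v, g in blk.parameters()]
        for lvl in range(5):
            for bi, blk in enumerate(self.dec_convs[lvl]):
                out += [(f"dec{lvl}.{bi}.{n}", v, g) for n, v, g in blk.parameters()]
        out += [(f"out.{n}", v, g) for n, v, g in self.out_conv.parameters()]
        return out

    def parameter_count(self) -> int:
        return int(sum(v.size for _, v, _ in self.parameters()))

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: v for name, v, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        for name, arr in state.items():
            own[name][...] = arr


def build_model(spec: Sequence[LayerBlockSpec] | None = None,
                widths: Sequence[int] = DEFAULT_WIDTHS,
                seed: int = 0) -> HourglassModel:
    """Construct a trainable model from a layer spec (or a width profile)."""
    return HourglassModel(spec if spec is not None else hourglass_spec(widths), seed=seed)


def _pad32(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[:2]
    ph, pw = (-h) % 32, (-w) % 32
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return x, (h, w)


def predict_maps(model: HourglassModel, image: np.ndarray) -> np.ndarray:
    """Inference on an [R, C, 3] image of any size -> stacked [16, R, C].

    Inputs are padded (reflect) to multiples of 32 and the output cropped
    back, so the convolutional geometry is preserved.
    """
    x, (h, w) = _pad32(image.astype(np.float32))
    y = model.forward(x, train=False)
    return y[:h, :w, :].transpose(2, 0, 1).astype(float)


# ---------------------------------------------------------------------------
# selective loss


def _selective_loss_grad(pred_hwc: np.ndarray, target: TargetMaps,
                         assoc_weight: float = 1.0,
                         peak_weight: float = 0.0,
                         error_weight: float = 0.0):
    """Loss value and gradient w.r.t. the [H, W, 16] prediction.

    Mean-squared error over all pixels of the four part channels, plus
    mean-squared error over *assigned* pixels only of the twelve
    association channels; unassigned association pixels receive exactly
    zero gradient so the network is free there.

    The optional training reweightings only change optimization
    dynamics, never the optimum (the target given an image is
    deterministic, and every per-pixel weight is positive):

    * ``assoc_weight`` rescales the association term — offsets are tens
      of pixels, so its raw magnitude dwarfs the unit-peak heatmap term;
    * ``peak_weight`` multiplies part-channel pixels by
      ``1 + peak_weight * target``, accelerating peak amplitudes that
      plain MSE — dominated by the empty background — learns slowly;
    * ``error_weight`` multiplies them by ``1 + error_weight * |diff|``,
      accelerating the suppression of spurious mid-amplitude responses.
    """
    t = target.stacked().transpose(1, 2, 0).astype(np.float32)
    if pred_hwc.shape != t.shape:
        raise ValueError(f"shape mismatch {pred_hwc.shape} vs {t.shape}")
    mask = target.assoc_mask.transpose(1, 2, 0).astype(np.float32)
    diff = pred_hwc - t
    part_diff = diff[..., :N_PART_CHANNELS]
    n_part = part_diff.size
    weight = 1.0
    if peak_weight or error_weight:
        weight = (1.0 + peak_weight * t[..., :N_PART_CHANNELS]
                  + error_weight * np.abs(part_diff))
    part_term = float(np.sum(weight * part_diff ** 2) / n_part)
    n_assoc = float(mask.sum())
    masked = diff[..., N_PART_CHANNELS:] * mask
    assoc_term = float(np.sum(masked ** 2) / n_assoc) if n_assoc > 0 else 0.0
    grad = np.zeros_like(diff)
    grad[..., :N_PART_CHANNELS] = 2.0 * weight * part_diff / n_part
    if n_assoc > 0:
        grad[..., N_PART_CHANNELS:] = assoc_weight * 2.0 * masked * mask / n_assoc
    return part_term + assoc_weight * assoc_term, grad


def selective_loss(pred: np.ndarray, target: TargetMaps) -> float:
    """Masked MSE between a [16, R, C] prediction and a target."""
    loss, _ = _selective_loss_grad(
        np.asarray(pred, dtype=np.float32).transpose(1, 2, 0), target)
    return loss


# ---------------------------------------------------------------------------
# training


class TrainingDivergenceError(RuntimeError):
    def __init__(self, history: list[float]):
        super().__init__(f"loss became non-finite at step {len(history)}")
        self.history = history


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 1e-2
    lr_decay: float = 0.5          # multiplicative decay applied per epoch tail
    assoc_weight: float = 1e-3     # balances offset-regression vs heatmap terms
    part_peak_weight: float = 4.0  # emphasizes kernel pixels over background
    part_error_weight: float = 10.0  # emphasizes mis-responses (ghost peaks)
    seed: int = 0
    augment: Optional[AugmentSpec] = field(default_factory=AugmentSpec)
    log_every: int = 0             # 0 = silent


def desk_scale_train_config(seed: int = 0) -> TrainConfig:
    """Training conditions for the reduced-resolution synthetic suite.

    Flips and full-circle rotations are kept; the scale range is
    narrowed to (0.75, 1.3) and shifts to +-10 px, both proportionate to
    the half-resolution scenes the suite uses.
    """
    return TrainConfig(
        epochs=14,
        seed=seed,
        augment=AugmentSpec(scale_range=(0.75, 1.3), shift_range_px=10.0, seed=seed),
    )


def train(model: HourglassModel,
          frames: Sequence[tuple[np.ndarray, FrameAnnotation]],
          config: TrainConfig) -> tuple[HourglassModel, list[float]]:
    """Minimize the selective loss over augmented (image, target) pairs.

    Each step draws one frame (epoch-shuffled), samples an augmentation,
    transforms image and annotations jointly, re-encodes the target, and
    takes one Adam step.  Returns the model and the per-step loss
    history; a non-finite loss aborts with the history attached.
    """
    if not frames:
        raise ValueError("need at least one training frame")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    n = len(frames)
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * (config.lr_decay ** (epoch / max(config.epochs - 1, 1) * 2))
        order = rng.permutation(n)
        for k in order:
            image, frame = frames[k]
            if config.augment is not None:
                draw = sample_draw(config.augment, rng)
                aug_frame = augment_annotations(frame, draw)
                if aug_frame.n_pigs == 0:
                    continue  # every animal left the frame; skip the draw
                image_in = augment_image(image, draw)
            else:
                aug_frame, image_in = frame, image
            target = encode_frame(aug_frame)
            pred = model.forward(image_in.astype(np.float32), train=True)
            loss, grad = _selective_loss_grad(
                pred, target, config.assoc_weight,
                config.part_peak_weight, config.part_error_weight)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(history)
            history.append(loss)
            model.backward(grad.astype(np.float32))
            opt.step()
            if config.log_every and len(history) % config.log_every == 0:
                recent = history[-config.log_every:]
                print(f"step {len(history)}: loss {np.mean(recent):.5f}")
    return model, history
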