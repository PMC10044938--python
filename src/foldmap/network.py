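"""Residual dense encoder-decoder producing a symmetric base-pairing score map.

The model is a fully-convolutional segmentation-style network over the
146-channel contact-matrix encoding:

* feature extraction — three basic convolution modules (BCM = convolution +
  batch normalization + ReLU) condensing 146 channels to
  ``feature_channels`` (default 16);
* encoder — ``num_levels`` repetitions of a dense connected module (DCM —
  a BCM stack where every layer sees the concatenation of all preceding
  feature maps, and the block output keeps the input map) followed by a
  transition-down (2x2 max-pool + BCM), so depth grows while spatial size
  shrinks;
* bottleneck DCM;
* decoder — ``num_levels`` repetitions of transition-up (2x nearest
  upsampling + BCM projecting to the matching encoder depth), a residual
  skip-add of the same-resolution encoder map, and a DCM (without input
  concatenation, so depth falls back to ``dcm_layers * growth_rate``);
* head — 1x1 convolution to one channel, symmetrization (raw map plus its
  transpose, then batch normalization), crop back to L x L.

Inputs are zero-padded spatially to a multiple of 2**num_levels; padded
cells are excluded from the symmetrization statistics via a mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .encoding import N_CHANNELS, InputConformation, build_input_conformation
from .nn import autograd as ag
from .nn.autograd import Tensor, no_grad
from .nn.layers import BatchNorm2d, Conv2d, Module
from .sequence import RnaSequence

CHECKPOINT_VERSION = 1


class SequenceTooLongError(ValueError):
    """Raised for sequences beyond the configured maximum length."""


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``pad_multiple`` is derived: spatial sizes must be divisible by
    ``downsample_factor ** num_levels`` for the encoder pyramid.
    """

    feature_channels: int = 16
    dcm_layers_per_block: int = 3
    growth_rate: int = 16
    num_levels: int = 4
    kernel_size: int = 3
    downsample_factor: int = 2
    max_length: int = 720
    seed: int = 0

    @property
    def pad_multiple(self) -> int:
        return self.downsample_factor ** self.num_levels

    def __post_init__(self) -> None:
        for name in ("feature_channels", "dcm_layers_per_block", "growth_rate",
                     "num_levels", "kernel_size", "max_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.downsample_factor != 2:
            raise ValueError("only downsample_factor=2 is implemented")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same-padding convolution)")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def residual_skip_add(decoder_map: Tensor, encoder_map: Tensor) -> Tensor:
    """Elementwise sum of same-shape decoder and encoder feature maps."""
    if decoder_map.shape != encoder_map.shape:
        raise ValueError(
            f"skip-add shape mismatch: decoder {decoder_map.shape} "
            f"vs encoder {encoder_map.shape}"
        )
    return ag.add(decoder_map, encoder_map)


class BCM(Module):
    """Basic convolution module: convolution + batch normalization + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = self.add_module("conv", Conv2d(in_channels, out_channels,
                                                   kernel_size, rng))
        self.bn = self.add_module("bn", BatchNorm2d(out_channels))
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn.forward(self.conv.forward(x)))


class DCM(Module):
    """Dense connected module: BCM stack with all-to-all feature reuse.

    Layer k consumes the concatenation of the block input and the outputs of
    layers 1..k-1. The block output concatenates all layer outputs, plus the
    block input when ``include_input`` (encoder side).
    """

    def __init__(self, in_channels: int, n_layers: int, growth: int,
                 kernel_size: int, include_input: bool, rng: np.random.Generator):
        super().__init__()
        self.include_input = include_input
        self.layers: List[BCM] = []
        depth = in_channels
        for k in range(n_layers):
            layer = self.add_module(f"layer{k}", BCM(depth, growth, kernel_size, rng))
            self.layers.append(layer)
            depth += growth
        self.out_channels = (in_channels if include_input else 0) + n_layers * growth

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        outputs = []
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else ag.concat_channels(feats)
            y = layer.forward(inp)
            outputs.append(y)
            feats.append(y)
        collected = ([x] if self.include_input else []) + outputs
        return collected[0] if len(collected) == 1 else ag.concat_channels(collected)


class TransitionDown(Module):
    """Halve spatial size (2x2 max-pool) then BCM."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.bcm = self.add_module("bcm", BCM(channels, channels, kernel_size, rng))
        self.out_channels = channels

    def forward(self, x: Tensor) -> Tensor:
        return self.bcm.forward(ag.maxpool2(x))


class TransitionUp(Module):
    """Double spatial size (nearest upsampling) then BCM reducing depth."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bcm = self.add_module("bcm", BCM(in_channels, out_channels,
                                              kernel_size, rng))
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return self.bcm.forward(ag.upsample_nearest2(x))


class PairScoreNet(Module):
    """The full encoder-decoder from input conformation to score map."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel_size
        f, g, n = cfg.feature_channels, cfg.growth_rate, cfg.dcm_layers_per_block

        self.feature_extraction = [
            self.add_module("fe0", BCM(N_CHANNELS, f, k, rng)),
            self.add_module("fe1", BCM(f, f, k, rng)),
            self.add_module("fe2", BCM(f, f, k, rng)),
        ]

        self.encoder_dcms: List[DCM] = []
        self.transitions_down: List[TransitionDown] = []
        depth = f
        self.skip_depths: List[int] = []
        for lvl in range(cfg.num_levels):
            dcm = self.add_module(
                f"enc{lvl}", DCM(depth, n, g, k, include_input=True, rng=rng)
            )
            self.encoder_dcms.append(dcm)
            depth = dcm.out_channels
            self.skip_depths.append(depth)
            td = self.add_module(f"td{lvl}", TransitionDown(depth, k, rng))
            self.transitions_down.append(td)

        self.bottleneck = self.add_module(
            "bottleneck", DCM(depth, n, g, k, include_input=False, rng=rng)
        )

        self.transitions_up: List[TransitionUp] = []
        self.decoder_dcms: List[DCM] = []
        cur = self.bottleneck.out_channels
        for lvl in reversed(range(cfg.num_levels)):
            tu = self.add_module(
                f"tu{lvl}", TransitionUp(cur, self.skip_depths[lvl], k, rng)
            )
            self.transitions_up.append(tu)
            dcm = self.add_module(
                f"dec{lvl}",
                DCM(self.skip_depths[lvl], n, g, k, include_input=False, rng=rng),
            )
            self.decoder_dcms.append(dcm)
            cur = dcm.out_channels

        self.head = self.add_module("head", Conv2d(cur, 1, 1, rng))
        self.sym_bn = self.add_module("sym_bn", BatchNorm2d(1))

    # ------------------------------------------------------------------
    def forward_batch(self, x: np.ndarray, lengths: Sequence[int],
                      requires_grad: bool = True) -> Tensor:
        """Score a padded batch.

        x: (N, 146, H, W) with H = W a multiple of ``pad_multiple``;
        ``lengths`` gives the un-padded size of each sample. Returns logits
        of shape (N, 1, H, W); cells outside the valid L x L square of each
        sample are zeroed and carry no gradient.
        """
        n, c, h, w = x.shape
        if c != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} input channels, got {c}")
        if h % self.cfg.pad_multiple or w % self.cfg.pad_multiple:
            raise ValueError(
                f"spatial size {h}x{w} not a multiple of {self.cfg.pad_multiple}"
            )
        valid = np.zeros((n, 1, h, w), dtype=np.float32)
        for b, L in enumerate(lengths):
            valid[b, 0, :L, :L] = 1.0

        t = Tensor(x.astype(np.float32), requires_grad=False)
        for fe in self.feature_extraction:
            t = fe.forward(t)
        self.feature_depth_ = t.shape[1]

        skips = []
        for dcm, td in zip(self.encoder_dcms, self.transitions_down):
            t = dcm.forward(t)
            skips.append(t)
            t = td.forward(t)
        t = self.bottleneck.forward(t)
        for tu, dcm, skip in zip(self.transitions_up, self.decoder_dcms,
                                 reversed(skips)):
            t = tu.forward(t)
            t = residual_skip_add(t, skip)
            t = dcm.forward(t)

        raw = self.head.forward(t)
        sym = ag.add(raw, ag.transpose_spatial(raw))
        return self.sym_bn.forward(sym, mask=valid)

    # ------------------------------------------------------------------
    def score_map(self, conf: InputConformation | np.ndarray,
                  length: Optional[int] = None) -> np.ndarray:
        """Inference: one conformation -> symmetric L x L score map."""
        if isinstance(conf, InputConformation):
            x, L = conf.tensor, conf.length
        else:
            x, L = conf, length or conf.shape[-1]
        if L > self.cfg.max_length:
            raise SequenceTooLongError(
                f"sequence length {L} exceeds the configured maximum "
                f"{self.cfg.max_length}; long sequences are refused rather "
                "than truncated"
            )
        pm = self.cfg.pad_multiple
        H = ((L + pm - 1) // pm) * pm
        batch = np.zeros((1, N_CHANNELS, H, H), dtype=np.float32)
        batch[0, :, :L, :L] = x
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward_batch(batch, [L], requires_grad=False)
        finally:
            self.train(was_training)
        S = out.data[0, 0, :L, :L].astype(np.float64)
        return 0.5 * (S + S.T)  # remove residual float asymmetry

    def predict(self, seq: RnaSequence) -> np.ndarray:
        """Sequence -> score map (encoding + forward)."""
        return self.score_map(build_input_conformation(seq))


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: PairScoreNet, path) -> None:
    """Weights + config in one NPZ (config as an embedded JSON string)."""
    meta = json.dumps(
        {"version": CHECKPOINT_VERSION, "config": asdict(model.cfg)}
    )
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **model.state_dict())


def load_checkpoint(path) -> PairScoreNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        model = PairScoreNet(NetworkConfig(**meta["config"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model
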