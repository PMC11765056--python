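"""The cascaded dual 3D U-Net.

Model A (base width 16) maps the 11-channel input — standardized CT, seven
OAR masks in canonical order, PTV56/63/70 — to a coarse dose; its final
16-channel decoder feature map is concatenated onto the same 11 input
channels to form Model B's 27-channel input, and Model B (base width 32)
predicts the final dose.  Both dose heads are 1x1x1 convolutions followed by
ReLU, so predicted doses are non-negative by construction.

Each sub-model is a five-level encoder/decoder.  The first three encoder
levels are concatenative residual blocks: two 3x3x3 conv blocks (conv,
instance norm, ReLU) whose output is concatenated channel-wise with the
level-start feature map, then 2x2x2 max-pooled.  With base width ``W`` the
level-start widths follow ``W * (2^k - 1)``: 16/48/112/240/496 for Model A
and 32/96/224/480/992 for Model B.  Level four is the pooled level-three
output; level five is a stride-2 3x3x3 conv block (15W -> 31W).  Decoder
levels up-sample trilinearly, reduce with a 3x3x3 conv block to widths
8W/4W/2W/W, concatenate the encoder level-start map (skips 15W/7W/3W/W,
i.e. 240+128 / 112+64 / 48+32 / 16+16 for Model A), and apply two conv
blocks at the same width.  Instance norm carries learnable affine
parameters and convolutions carry biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .errors import ConfigError
from .patient_io import VoxelGrid

__all__ = [
    "ModelConfig",
    "CascadeModel",
    "build_model",
    "forward",
    "count_parameters",
    "conv_parameter_count",
    "INPUT_CHANNELS",
]

#: Fixed input contract: CT + 7 OARs + 3 PTVs.
INPUT_CHANNELS = 11


@dataclass(frozen=True)
class ModelConfig:
    """Channel plan and grid contract of the cascade."""

    grid: VoxelGrid
    base_width_a: int = 16
    base_width_b: int = 32
    levels: int = 5
    kernel: int = 3
    in_channels: int = INPUT_CHANNELS
    single_model: bool = False  # ablation: Model B alone on the 11-channel input

    def __post_init__(self) -> None:
        if self.levels != 5 or self.kernel != 3:
            raise ConfigError("the cascade is defined for 5 levels and 3x3x3 kernels")
        if self.base_width_a < 1 or self.base_width_b < 1:
            raise ConfigError("base widths must be positive")
        factor = 2 ** (self.levels - 1)
        if any(s % factor for s in self.grid.shape):
            raise ConfigError(
                f"grid extents {self.grid.shape} must be divisible by {factor}")

    @property
    def model_b_in_channels(self) -> int:
        """Model B consumes the input plus Model A's final decoder features."""
        if self.single_model:
            return self.in_channels
        return self.in_channels + self.base_width_a


def conv_parameter_count(cin: int, cout: int, kernel: int, bias: bool = True) -> int:
    """Trainable scalars of one convolution layer."""
    return kernel ** 3 * cin * cout + (cout if bias else 0)


class _ConvBlock:
    """conv -> instance norm (affine) -> ReLU."""

    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator, dtype, params: List[nn.Tensor]):
        std = np.sqrt(2.0 / (cin * kernel ** 3))
        self.w = nn.Tensor(rng.normal(0.0, std, (cout, cin, kernel, kernel, kernel))
                           .astype(dtype))
        self.b = nn.Tensor(np.zeros(cout, dtype=dtype))
        self.gamma = nn.Tensor(np.ones(cout, dtype=dtype))
        self.beta = nn.Tensor(np.zeros(cout, dtype=dtype))
        params.extend([self.w, self.b, self.gamma, self.beta])

    def __call__(self, x: nn.Tensor, stride: int = 1) -> nn.Tensor:
        return nn.relu(nn.instance_norm(nn.conv3d(x, self.w, self.b, stride=stride),
                                        self.gamma, self.beta))


class SubUNet:
    """One encoder/decoder sub-model with the concatenative channel plan."""

    def __init__(self, width: int, in_channels: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.width = width
        self.in_channels = in_channels
        self.params: List[nn.Tensor] = []
        w = width
        mk = lambda ci, co, k=3: _ConvBlock(ci, co, k, rng, dtype, self.params)

        self.stem = mk(in_channels, w)
        self.encoder = []
        s = w
        for k in (1, 2, 3):
            out = w * 2 ** k
            self.encoder.append((mk(s, out), mk(out, out)))
            s += out  # concatenative residual growth: W(2^{k+1}-1)
        self.bottleneck = mk(15 * w, 31 * w)  # stride-2 at call time
        self.decoder = []
        cur = 31 * w
        for u, skip in zip((8 * w, 4 * w, 2 * w, w), (15 * w, 7 * w, 3 * w, w)):
            self.decoder.append((mk(cur, u), mk(u + skip, u), mk(u, u)))
            cur = u
        std = np.sqrt(2.0 / w)
        self.head_w = nn.Tensor(rng.normal(0.0, std, (1, w, 1, 1, 1)).astype(dtype))
        self.head_b = nn.Tensor(np.zeros(1, dtype=dtype))
        self.params.extend([self.head_w, self.head_b])

    def __call__(self, x: nn.Tensor) -> Tuple[nn.Tensor, nn.Tensor]:
        """Returns (dose, final decoder features)."""
        s1 = self.stem(x)
        skips = []
        cur = s1
        for blk1, blk2 in self.encoder:
            skips.append(cur)
            cur = nn.maxpool2(nn.concat([cur, blk2(blk1(cur))]))
        skips.append(cur)  # level-4 map, 15W channels
        cur = self.bottleneck(cur, stride=2)  # level-5 map, 31W channels
        for (up, conv1, conv2), skip in zip(self.decoder, reversed(skips)):
            cur = up(nn.upsample2(cur))
            cur = conv2(conv1(nn.concat([cur, skip])))
        dose = nn.relu(nn.conv3d(cur, self.head_w, self.head_b))
        return dose, cur

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params)


@dataclass
class CascadeModel:
    """Both sub-models plus the channel plan they were built from."""

    model_a: Optional[SubUNet]
    model_b: SubUNet
    config: ModelConfig
    init_seed: int = 0

    def all_params(self) -> List[nn.Tensor]:
        params = [] if self.model_a is None else list(self.model_a.params)
        return params + list(self.model_b.params)

    def state_arrays(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.all_params())}

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        params = self.all_params()
        if len(arrays) != len(params):
            raise ConfigError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            a = arrays[f"p{i}"]
            if a.shape != p.data.shape:
                raise ConfigError("checkpoint parameter shape mismatch")
            p.data = a.astype(p.data.dtype)


def build_model(config: ModelConfig, init_seed: int = 0,
                dtype=np.float32) -> CascadeModel:
    """Construct the cascade with He-scaled normal weights, zero biases.

    Deterministic given ``init_seed``: both sub-models draw from one seeded
    stream in a fixed order.
    """
    rng = np.random.default_rng(int(init_seed))
    model_a = None
    if not config.single_model:
        model_a = SubUNet(config.base_width_a, config.in_channels, rng, dtype)
    model_b = SubUNet(config.base_width_b, config.model_b_in_channels, rng, dtype)
    return CascadeModel(model_a=model_a, model_b=model_b, config=config,
                        init_seed=int(init_seed))


def forward(model: CascadeModel, input_11ch: np.ndarray
            ) -> Tuple[Optional[nn.Tensor], Optional[nn.Tensor], nn.Tensor]:
    """Run the cascade on one multi-channel volume.

    ``input_11ch`` is ``(in_channels, D, H, W)`` with the fixed channel order
    (CT, OARs in canonical order, PTV56, PTV63, PTV70); absent structures are
    all-zero channels.  Returns ``(dose_a, features_a, dose_b)`` tensors; the
    first two are ``None`` in single-model mode.
    """
    expected = model.config.in_channels
    if input_11ch.ndim != 4 or input_11ch.shape[0] != expected:
        raise ConfigError(
            f"input must have {expected} channels, got shape {input_11ch.shape}")
    dtype = model.model_b.params[0].data.dtype
    x = nn.Tensor(np.ascontiguousarray(input_11ch, dtype=dtype))
    if model.model_a is None:
        dose_b, _ = model.model_b(x)
        return None, None, dose_b
    dose_a, features_a = model.model_a(x)
    dose_b, _ = model.model_b(nn.concat([x, features_a]))
    return dose_a, features_a, dose_b


def count_parameters(model: CascadeModel) -> int:
    """Number of trainable scalars across both sub-models."""
    return sum(p.data.size for p in model.all_params())
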