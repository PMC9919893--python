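"""Generators and discriminators of the waveform-translation CycleGAN.

Two generators map between the peripheral domain X (brachial + radial
pressure) and the central domain Y (abdominal-aortic pressure + area):
``Gxy: X→Y`` and ``Gyx: Y→X``.  Each is two stacked GRU layers followed by a
per-timestep linear projection to 2 features and a tanh, so outputs live in
(−1, 1) like the normalized inputs.

Two discriminators score 2-channel windows with five stacked stride-2
convolutions (kernel 5, padding 1), channel count doubling per layer, each
followed by a normalization layer and LeakyReLU(0.2), then a flatten and a
linear projection to one feature.  The normalization kind and the final
activation depend on the adversarial loss: batch-norm + sigmoid for the
least-squares GAN, instance-norm + linear for the Wasserstein critic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .preprocessing import NormalizationSpec, WindowSpec

KERNEL, STRIDE, PADDING = 5, 2, 1
NUM_CONV_LAYERS = 5
NUM_GRU_LAYERS = 2
#: minimum window length that survives five stride-2 convolutions
#: (each layer needs input >= kernel - 2*padding = 3; iterating the length
#: recurrence backwards gives 3 -> 7 -> 15 -> 31 -> 63)
MIN_DISCRIMINATOR_INPUT = 63


@dataclass
class GeneratorSpec:
    gru_features: int = 64  # grid: 64 or 128
    num_gru_layers: int = NUM_GRU_LAYERS
    in_channels: int = 2
    out_channels: int = 2

    def __post_init__(self):
        if self.out_channels != 2 or self.in_channels != 2:
            raise ValueError("generators map 2-channel windows to 2-channel windows")
        if self.num_gru_layers != NUM_GRU_LAYERS:
            raise ValueError("generator depth is fixed at two GRU layers")
        if self.gru_features < 1:
            raise ValueError("gru_features must be positive")


@dataclass
class DiscriminatorSpec:
    first_layer_features: int = 8  # grid: 6 or 8
    norm_kind: str = "batch"  # batch (LSGAN) | instance (WGAN-GP)
    final_activation: str = "sigmoid"  # sigmoid (LSGAN) | linear (WGAN-GP)
    num_conv_layers: int = NUM_CONV_LAYERS
    kernel: int = KERNEL
    stride: int = STRIDE
    padding: int = PADDING
    leaky_relu_slope: float = 0.2

    def __post_init__(self):
        if self.norm_kind not in ("batch", "instance"):
            raise ValueError("norm_kind must be 'batch' or 'instance'")
        if self.final_activation not in ("sigmoid", "linear"):
            raise ValueError("final_activation must be 'sigmoid' or 'linear'")
        consistent = (self.norm_kind, self.final_activation) in (
            ("batch", "sigmoid"),
            ("instance", "linear"),
        )
        if not consistent:
            raise ValueError(
                "norm/final-activation pair must match the adversarial loss: "
                "batch+sigmoid (LSGAN) or instance+linear (WGAN-GP)"
            )

    @classmethod
    def for_loss(cls, loss_kind: str, first_layer_features: int) -> "DiscriminatorSpec":
        if loss_kind == "lsgan":
            return cls(first_layer_features, norm_kind="batch", final_activation="sigmoid")
        if loss_kind == "wgan_gp":
            return cls(first_layer_features, norm_kind="instance", final_activation="linear")
        raise ValueError(f"unknown loss kind {loss_kind!r}")


def conv_output_length(
    len_in: int, kernel: int = KERNEL, stride: int = STRIDE, padding: int = PADDING
) -> int:
    """Output length of one convolution layer: floor((L + 2p − k)/s) + 1."""
    if len_in < kernel - 2 * padding:
        raise ValueError(f"input length {len_in} too small for kernel {kernel}")
    return (len_in + 2 * padding - kernel) // stride + 1


def discriminator_feature_lengths(len_in: int, spec: DiscriminatorSpec) -> List[int]:
    """Time lengths after each of the stacked convolution layers."""
    lengths = []
    cur = len_in
    for _ in range(spec.num_conv_layers):
        cur = conv_output_length(cur, spec.kernel, spec.stride, spec.padding)
        lengths.append(cur)
    return lengths


class Generator(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        h = spec.gru_features
        self.gru_layers = [
            nn.GRULayer(spec.in_channels if i == 0 else h, h, rng)
            for i in range(spec.num_gru_layers)
        ]
        self.proj = nn.Linear(h, spec.out_channels, rng)
        # the tanh head must be able to span (-1, 1) from the start; the
        # 0.02-scale conv initialization cannot (pre-activations ~0.1)
        bound = 1.0 / np.sqrt(h)
        self.proj.weight.data = rng.uniform(-bound, bound, size=(h, spec.out_channels))

    def forward(self, x: Tensor) -> Tensor:
        """(B, 2, T) in [−1,1] → (B, 2, T) in (−1,1)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape((1,) + x.shape)
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        seq = x.swapaxes(1, 2)  # (B, T, C)
        for layer in self.gru_layers:
            seq = layer(seq)
        out = self.proj(seq)  # (B, T, 2)
        return ad.tanh(out).swapaxes(1, 2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference on a (2, T) or (B, 2, T) array, returning numpy."""
        arr = np.asarray(x, dtype=np.float64)
        squeeze = arr.ndim == 2
        with ad.no_grad():
            out = self.forward(Tensor(arr)).data
        return out[0] if squeeze else out


class Discriminator(nn.Module):
    def __init__(
        self, spec: DiscriminatorSpec, window_len: int, rng: np.random.Generator
    ):
        if window_len < MIN_DISCRIMINATOR_INPUT:
            raise ValueError(
                f"window length {window_len} too short for "
                f"{spec.num_conv_layers} stride-{spec.stride} layers"
            )
        self.spec = spec
        self.window_len = window_len
        self.convs: List[nn.Conv1d] = []
        self.norms: List[nn.Module] = []
        in_ch = 2
        out_ch = spec.first_layer_features
        for _ in range(spec.num_conv_layers):
            self.convs.append(
                nn.Conv1d(in_ch, out_ch, spec.kernel, spec.stride, spec.padding, rng)
            )
            norm_cls = nn.BatchNorm1d if spec.norm_kind == "batch" else nn.InstanceNorm1d
            self.norms.append(norm_cls(out_ch))
            in_ch, out_ch = out_ch, out_ch * 2
        lengths = discriminator_feature_lengths(window_len, spec)
        self.flat_features = in_ch * lengths[-1]
        self.head = nn.Linear(self.flat_features, 1, rng)

    def forward(self, v: Tensor) -> Tensor:
        """(B, 2, T) → (B,) score: in (0,1) with a sigmoid head, else raw."""
        if not isinstance(v, Tensor):
            v = Tensor(np.asarray(v, dtype=np.float64))
        if v.ndim == 2:
            v = v.reshape((1,) + v.shape)
        if v.shape[2] != self.window_len:
            raise ValueError(
                f"discriminator built for window {self.window_len}, got {v.shape[2]}"
            )
        h = v
        for conv, norm in zip(self.convs, self.norms):
            h = ad.leaky_relu(norm(conv(h)), self.spec.leaky_relu_slope)
        b = h.shape[0]
        flat = h.reshape((b, self.flat_features))
        score = self.head(flat).reshape((b,))
        if self.spec.final_activation == "sigmoid":
            score = ad.sigmoid(score)
        return score


@dataclass
class CycleGANModels:
    gxy: Generator
    gyx: Generator
    dx: Discriminator
    dy: Discriminator
    g_spec: GeneratorSpec
    d_spec: DiscriminatorSpec
    window_len: int


def build_models(
    g_spec: GeneratorSpec,
    d_spec: DiscriminatorSpec,
    window_len: int,
    seed: int,
) -> CycleGANModels:
    """Four independently initialized networks, reproducible from the seed."""
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(4)]
    return CycleGANModels(
        gxy=Generator(g_spec, rngs[0]),
        gyx=Generator(g_spec, rngs[1]),
        dx=Discriminator(d_spec, window_len, rngs[2]),
        dy=Discriminator(d_spec, window_len, rngs[3]),
        g_spec=g_spec,
        d_spec=d_spec,
        window_len=window_len,
    )


def save_checkpoint(
    path,
    models: CycleGANModels,
    norm_spec: Optional[NormalizationSpec] = None,
    window_spec: Optional[WindowSpec] = None,
) -> None:
    """All four parameter states + specs, in one compressed archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, module in (
        ("gxy", models.gxy),
        ("gyx", models.gyx),
        ("dx", models.dx),
        ("dy", models.dy),
    ):
        for i, arr in enumerate(module.state_arrays()):
            arrays[f"{tag}_{i:03d}"] = arr
    meta = {
        "g_spec": asdict(models.g_spec),
        "d_spec": asdict(models.d_spec),
        "window_len": models.window_len,
        "normalization": asdict(norm_spec) if norm_spec else None,
        "window": asdict(window_spec) if window_spec else None,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path):
    """Returns (models, norm_spec, window_spec); specs may be None."""
    with np.load(Path(path), allow_pickle=False) as blob:
        meta = json.loads(bytes(blob["meta_json"].tobytes()).decode())
        models = build_models(
            GeneratorSpec(**meta["g_spec"]),
            DiscriminatorSpec(**meta["d_spec"]),
            meta["window_len"],
            seed=0,
        )
        for tag, module in (
            ("gxy", models.gxy),
            ("gyx", models.gyx),
            ("dx", models.dx),
            ("dy", models.dy),
        ):
            n = len(module.parameters())
            module.load_state_arrays([blob[f"{tag}_{i:03d}"] for i in range(n)])
    norm = (
        NormalizationSpec(**meta["normalization"]) if meta.get("normalization") else None
    )
    window = WindowSpec(**meta["window"]) if meta.get("window") else None
    return models, norm, window
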