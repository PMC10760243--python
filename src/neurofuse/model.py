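"""Configurable multi-channel 3D convolutional classifier.

The architecture follows the AlexNet-3D-with-dropout lineage used for
volumetric neuroimaging classification: repeated
[conv3d -> batchnorm -> ReLU -> (maxpool at designated stages)] blocks,
adaptive average pooling to a fixed spatial size, then a two-layer
fully-connected head with ReLU + dropout and a final linear layer that
emits one logit per diagnostic class.  Adaptive pooling makes the same
classifier accept any input grid large enough for the conv stack — both
the full 53 x 63 x 52 acquisition grid and small synthetic grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import nn
from .fusion import ModelInput

__all__ = ["ModelConfig", "ClassifierModel", "build_model", "KERNEL_COMBOS"]

#: the searched kernel-size / stride / padding combinations
KERNEL_COMBOS = ((5, 2, 0), (3, 2, 1))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the AlexNet-3D convention: five conv blocks with
    filter counts (64, 128, 192, 192, 128), max pooling after blocks 1, 2
    and 5, dropout 0.5 in the FC head, and adaptive average pooling to
    1x1x1 so the FC width is independent of the input grid.
    """

    n_channels: int = 1
    n_classes: int = 2
    conv_filters: tuple[int, ...] = (64, 128, 192, 192, 128)
    kernel_size: int = 3
    stride: int = 2
    padding: int = 1
    pool_stages: tuple[int, ...] = (1, 2, 5)
    pool_size: int = 3
    pool_stride: int = 2
    dropout_rate: float = 0.5
    fc_widths: tuple[int, int] = (64, 32)
    adaptive_pool_size: int = 1
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 3:
            raise ValueError(f"n_channels must be 1-3, got {self.n_channels}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not self.conv_filters:
            raise ValueError("need at least one conv block")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ModelConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("conv_filters", "pool_stages", "fc_widths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class ClassifierModel:
    """A built network plus its config, mode flag, and (de)serialization."""

    def __init__(self, config: ModelConfig, net: nn.Sequential) -> None:
        self.config = config
        self.net = net
        self.mode = "eval"

    def train_mode(self) -> None:
        self.mode = "train"

    def eval_mode(self) -> None:
        self.mode = "eval"

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    @staticmethod
    def _batch_array(batch: Union[np.ndarray, Sequence[ModelInput]]) -> np.ndarray:
        if isinstance(batch, np.ndarray):
            x = batch
        else:
            shapes = {mi.channels[0].grid.dims for mi in batch}
            if len(shapes) > 1:
                raise ValueError(f"batch mixes grids: {sorted(shapes)}")
            x = np.stack([mi.as_array() for mi in batch], axis=0)
        if x.ndim != 5:
            raise ValueError(f"expected (N, C, D, H, W) input, got shape {x.shape}")
        return x

    def forward(self, batch: Union[np.ndarray, Sequence[ModelInput]],
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Logits (batch x n_classes).  Eval mode is deterministic."""
        x = self._batch_array(batch)
        if x.shape[1] != self.config.n_channels:
            raise ValueError(
                f"model expects {self.config.n_channels} channel(s), input has {x.shape[1]}"
            )
        logits = self.net.forward(x, train=(self.mode == "train"), rng=rng)
        if not np.isfinite(logits).all():
            raise FloatingPointError("non-finite logits")
        return logits

    def predict_proba(self, batch) -> np.ndarray:
        return nn.softmax(self.forward(batch))

    def predict(self, batch) -> np.ndarray:
        return self.forward(batch).argmax(axis=1)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Write parameters (.npz) and config (.yaml) side by side."""
        path = Path(path)
        flat: dict[str, np.ndarray] = {}
        for i, layer_state in enumerate(self.net.state()):
            for k, v in layer_state.items():
                flat[f"{i}.{k}"] = v
        np.savez(path.with_suffix(".npz"), **flat)
        self.config.to_yaml(path.with_suffix(".yaml"))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ClassifierModel":
        path = Path(path)
        config = ModelConfig.from_yaml(path.with_suffix(".yaml"))
        model = build_model(config)
        with np.load(path.with_suffix(".npz")) as data:
            state: list[dict[str, np.ndarray]] = [dict() for _ in model.net.layers]
            for key in data.files:
                i, name = key.split(".", 1)
                state[int(i)][name] = data[key]
        for layer, s in zip(model.net.layers, state):
            if s:
                layer.load_state(s)
        return model


def build_model(config: ModelConfig) -> ClassifierModel:
    """Assemble the conv stack and FC head from a config.

    Weight initialization is He-normal drawn from ``config.init_seed`` so
    that two builds with the same config are bit-identical.
    """
    rng = np.random.default_rng(config.init_seed)
    layers: list[nn.Layer] = []
    in_ch = config.n_channels
    for i, out_ch in enumerate(config.conv_filters, start=1):
        layers.append(nn.Conv3d(in_ch, out_ch, config.kernel_size, config.stride,
                                config.padding, rng=rng, name=f"conv{i}"))
        layers.append(nn.BatchNorm3d(out_ch, name=f"bn{i}"))
        layers.append(nn.ReLU(name=f"relu{i}"))
        if i in config.pool_stages:
            layers.append(nn.MaxPool3d(config.pool_size, config.pool_stride, name=f"pool{i}"))
        in_ch = out_ch
    layers.append(nn.AdaptiveAvgPool3d(config.adaptive_pool_size, name="avgpool"))
    layers.append(nn.Flatten())
    fc_in = config.conv_filters[-1] * config.adaptive_pool_size ** 3
    w1, w2 = config.fc_widths
    layers += [
        nn.Linear(fc_in, w1, rng=rng, name="fc1"),
        nn.ReLU(name="fc1_relu"),
        nn.Dropout(config.dropout_rate, name="fc1_drop"),
        nn.Linear(w1, w2, rng=rng, name="fc2"),
        nn.ReLU(name="fc2_relu"),
        nn.Dropout(config.dropout_rate, name="fc2_drop"),
        nn.Linear(w2, config.n_classes, rng=rng, name="out"),
    ]
    return ClassifierModel(config, nn.Sequential(layers))
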