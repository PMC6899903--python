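"""The contact-prediction network: Maxout input layer, dilated residual
stack, sigmoid output head, symmetrization, and ensembling.

The model is fully convolutional: it accepts a C x L x L tensor for any L
and returns an L x L map.  The 501 input channels are reduced to the
working width by a convolutional Maxout layer followed by instance
normalization; the body is a series of residual blocks of two 5 x 5
convolutions whose dilation rates alternate between 1 and an increasing
schedule (1, 2, 4, ..., 64), growing the receptive field to cover whole
proteins; the head is a single 1 x 1 convolution with instance
normalization before the sigmoid.  Predicted maps are symmetrized by
averaging the (i, j) and (j, i) scores, and final predictions average an
ensemble of independently seeded models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import N_CHANNELS, FeatureTensor
from .nn import Adam, Conv2d, InstanceNorm, Layer, MaxoutConv, Param, ResidualBlock, sigmoid

DEFAULT_DILATIONS = (1, 2, 1, 4, 1, 8, 1, 16, 1, 32, 1, 64, 1, 1, 1, 1, 1, 1)


@dataclass
class ModelConfig:
    in_channels: int = N_CHANNELS
    width: int = 64
    n_blocks: int = 18
    dilation_schedule: tuple[int, ...] = DEFAULT_DILATIONS
    maxout_pieces: int = 2
    kernel: int = 5
    maxout_kernel: int = 1
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.dilation_schedule = tuple(int(d) for d in self.dilation_schedule)
        if len(self.dilation_schedule) != self.n_blocks:
            raise ValueError("dilation_schedule length must equal n_blocks")
        if any(d < 1 for d in self.dilation_schedule):
            raise ValueError("dilation rates must be >= 1")

    def receptive_field(self) -> int:
        """Receptive-field diameter (residues) of the full stack."""
        rf = 1 + (self.maxout_kernel - 1)
        for d in self.dilation_schedule:
            rf += 2 * (self.kernel - 1) * d  # two convs per block
        return rf

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "width": self.width,
            "n_blocks": self.n_blocks,
            "dilation_schedule": list(self.dilation_schedule),
            "maxout_pieces": self.maxout_pieces,
            "kernel": self.kernel,
            "maxout_kernel": self.maxout_kernel,
            "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dilation_schedule"] = tuple(d["dilation_schedule"])
        return cls(**d)


class ContactNetwork:
    """Fully convolutional residue-contact model (single ensemble member)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        dt = np.dtype(cfg.dtype).type
        self.input_layer = MaxoutConv(
            cfg.in_channels, cfg.width, cfg.maxout_pieces, cfg.maxout_kernel, rng=rng, dtype=dt
        )
        self.input_norm = InstanceNorm(cfg.width, dtype=dt)
        self.blocks = [
            ResidualBlock(cfg.width, cfg.kernel, d, rng=rng, dtype=dt)
            for d in cfg.dilation_schedule
        ]
        self.out_conv = Conv2d(cfg.width, 1, 1, rng=rng, dtype=dt)
        self.out_norm = InstanceNorm(1, dtype=dt)
        self._layers: list[Layer] = [self.input_layer, self.input_norm, *self.blocks, self.out_conv, self.out_norm]

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._layers:
            out += layer.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter p{i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray | FeatureTensor) -> np.ndarray:
        """Unnormalized L x L output (pre-sigmoid)."""
        if isinstance(x, FeatureTensor):
            x = x.data
        x = np.asarray(x, dtype=self.cfg.dtype)
        if x.ndim != 3 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, L, L) input, got {x.shape}"
            )
        h = self.input_norm.forward(self.input_layer.forward(x))
        for block in self.blocks:
            h = block.forward(h)
        z = self.out_norm.forward(self.out_conv.forward(h))
        return z[0]

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate a gradient wrt the logits, accumulating into params."""
        d = self.out_norm.backward(dz[None].astype(self.cfg.dtype))
        d = self.out_conv.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        d = self.input_norm.backward(d)
        self.input_layer.backward(d)

    def predict(self, x: np.ndarray | FeatureTensor) -> np.ndarray:
        """Symmetrized contact-probability map in [0, 1]."""
        return symmetrize(sigmoid(self.forward_logits(x)))

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> ContactNetwork:
    """Construct a Xavier-initialized model from a config."""
    return ContactNetwork(cfg or ModelConfig(), np.random.default_rng(seed))


def symmetrize(raw: np.ndarray) -> np.ndarray:
    """Average scores over (i, j) and (j, i)."""
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {raw.shape}")
    return 0.5 * (raw + raw.T)


def ensemble_predict(models: Sequence[ContactNetwork], x: np.ndarray | FeatureTensor) -> np.ndarray:
    """Elementwise mean of the symmetrized predictions of an ensemble."""
    if not models:
        raise ValueError("need at least one model")
    return np.mean([m.predict(x) for m in models], axis=0)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: ContactNetwork, path: str | Path, channel_map: list[str] | None = None) -> None:
    """Portable checkpoint: weights + config + the expected channel map."""
    meta = {"config": model.cfg.to_dict(), "channel_map": channel_map}
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path: str | Path, expect_channel_map: list[str] | None = None) -> ContactNetwork:
    """Load a checkpoint, refusing mismatched channel maps."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    saved_map = meta.get("channel_map")
    if expect_channel_map is not None and saved_map is not None and list(saved_map) != list(expect_channel_map):
        raise ValueError("checkpoint channel map does not match the assembled features")
    model = ContactNetwork(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model
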