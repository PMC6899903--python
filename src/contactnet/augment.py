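"""Training-time data augmentation for contact-map learning.

Three procedures, applied on-the-fly as each batch is prepared:

* **loop sampling** — probabilistically delete loop residues (their rows
  and columns are removed from every input channel and from the contact
  map; the sequence-separation channel is recomposed for the new length);
  applied with probability ``p_loop_apply`` and only to proteins whose
  loop fraction is at most ``max_loop_frac``;
* **feature interpolation** — mix the input tensors built from a deep and
  a shallow alignment of the same protein, ``x' = m*x1 + (1-m)*x2`` with a
  single uniform scalar ``m``; the target contact map is *not*
  interpolated;
* **180-degree flipping** — reverse both spatial axes of the inputs and the
  contact map (chain-direction reversal); when the batch coin succeeds the
  flipped copies are appended to the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import FeatureTensor, separation_channel


@dataclass
class AugmentConfig:
    p_loop_apply: float = 0.5
    p_residue_del: float = 0.3
    max_loop_frac: float = 0.4
    p_flip: float = 0.5
    p_mixup: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_loop_apply", "p_residue_del", "max_loop_frac", "p_flip", "p_mixup"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_loop_apply=0.0, p_residue_del=0.0, p_flip=0.0, p_mixup=0.0)


@dataclass
class TrainingExample:
    """One (input tensor, contact map) pair with loop annotations.

    ``x_alt`` optionally carries the tensor built from a paired shallow
    alignment of the same protein, used by feature interpolation.
    """

    x: FeatureTensor
    y: np.ndarray
    loop_mask: np.ndarray
    x_alt: FeatureTensor | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.loop_mask = np.asarray(self.loop_mask, dtype=bool)
        L = self.x.L
        if self.y.shape != (L, L):
            raise ValueError(f"contact map shape {self.y.shape} != ({L}, {L})")
        if self.loop_mask.shape != (L,):
            raise ValueError("loop_mask length must equal L")
        if not np.array_equal(self.y, self.y.T):
            raise ValueError("contact map must be symmetric")
        if not np.isin(self.y, (0, 1)).all() or np.any(np.diag(self.y) != 0):
            raise ValueError("contact map must be binary with zero diagonal")
        if self.x_alt is not None and self.x_alt.data.shape != self.x.data.shape:
            raise ValueError("paired tensor must match the primary tensor's shape")

    @property
    def L(self) -> int:
        return self.x.L


def _delete_residues(t: FeatureTensor, keep: np.ndarray) -> FeatureTensor:
    data = t.data[:, keep][:, :, keep].copy()
    if "separation" in t.channel_map:
        data[t.channel_map.index("separation")] = separation_channel(int(keep.sum()))
    return FeatureTensor(data, list(t.channel_map), dict(t.metadata))


def loop_sampling(ex: TrainingExample, cfg: AugmentConfig, rng: np.random.Generator) -> TrainingExample:
    """Randomly delete loop residues from an example.

    Returns the input unchanged when the protein is more than
    ``max_loop_frac`` loop, or when the apply-coin fails.  Deleted
    residues' rows and columns are removed from every channel and from the
    contact map, and the separation channel is rebuilt for the new length.
    At least one residue is always retained.
    """
    L = ex.L
    loop_frac = ex.loop_mask.mean()
    if loop_frac > cfg.max_loop_frac:
        return ex
    if rng.random() >= cfg.p_loop_apply:
        return ex
    delete = ex.loop_mask & (rng.random(L) < cfg.p_residue_del)
    if delete.all():  # degenerate all-loop guard
        delete[0] = False
    if not delete.any():
        return ex
    keep = ~delete
    return TrainingExample(
        x=_delete_residues(ex.x, keep),
        y=ex.y[keep][:, keep],
        loop_mask=ex.loop_mask[keep],
        x_alt=None if ex.x_alt is None else _delete_residues(ex.x_alt, keep),
        name=ex.name,
    )


def interpolate_features(x1: FeatureTensor, x2: FeatureTensor, m: float) -> FeatureTensor:
    """Linear mix ``m*x1 + (1-m)*x2`` of two same-shape feature tensors."""
    if x1.data.shape != x2.data.shape:
        raise ValueError(f"shape mismatch: {x1.data.shape} vs {x2.data.shape}")
    if x1.channel_map != x2.channel_map:
        raise ValueError("channel maps differ; tensors are not interpolable")
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"m must be in [0, 1], got {m}")
    if m == 1.0:
        return FeatureTensor(x1.data.copy(), list(x1.channel_map), dict(x1.metadata))
    if m == 0.0:
        return FeatureTensor(x2.data.copy(), list(x2.channel_map), dict(x2.metadata))
    return FeatureTensor(m * x1.data + (1.0 - m) * x2.data, list(x1.channel_map), dict(x1.metadata))


def flip_example(ex: TrainingExample) -> TrainingExample:
    """Reverse the chain direction: flip all spatial axes by 180 degrees."""
    def flip_tensor(t: FeatureTensor) -> FeatureTensor:
        return FeatureTensor(t.data[:, ::-1, ::-1].copy(), list(t.channel_map), dict(t.metadata))

    return TrainingExample(
        x=flip_tensor(ex.x),
        y=ex.y[::-1, ::-1].copy(),
        loop_mask=ex.loop_mask[::-1].copy(),
        x_alt=None if ex.x_alt is None else flip_tensor(ex.x_alt),
        name=ex.name,
    )


def augment_batch(
    batch: list[TrainingExample],
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> list[TrainingExample]:
    """Apply all three augmentations to a batch.

    Per example: loop sampling, then feature interpolation against the
    paired shallow-alignment tensor when one is present (a fresh ``m`` per
    example).  Then one batch-level coin with probability ``p_flip``
    appends the flipped copy of every (already augmented) example.
    Fully reproducible given the generator state.
    """
    if not batch:
        raise ValueError("batch must be nonempty")
    out: list[TrainingExample] = []
    for ex in batch:
        ex = loop_sampling(ex, cfg, rng)
        if ex.x_alt is not None and cfg.p_mixup > 0 and rng.random() < cfg.p_mixup:
            m = rng.random()
            ex = replace(ex, x=interpolate_features(ex.x, ex.x_alt, m))
        out.append(ex)
    if cfg.p_flip > 0 and rng.random() < cfg.p_flip:
        out = out + [flip_example(ex) for ex in out]
    return out
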