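"""Trained-from-scratch 3D vision transformer for binary lesion grading.

A volumetric input x in R^(H x W x Z x C) is cut into non-overlapping
(P, P, Z) patches spanning the full slice depth; each patch is flattened and
linearly projected to an embedding of size D.  A learnable classification
token is prepended, learnable position embeddings are added over the N+1
positions, and L pre-norm transformer encoder blocks (k-head self-attention,
MLP of width d, GELU) process the sequence.  The classification token's
final state is mapped to a single logit; the sigmoid of that logit is the
predicted probability that the lesion is high grade.

The architectures are deliberately small — they are trained from scratch on
cohorts of around a hundred lesions, where an ImageNet-scale transformer
would only memorise.  The canonical grid of 18 configurations varies the
MLP width d in {2048, 3072}, depth L in {4, 6, 8} and the head count
k in {4, 8, 16}, with the embedding size tied to the patch content by
D = P^2 * C / k.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import nn
from .synthetic import LesionVolume

__all__ = [
    "ViTConfig", "TrainSpec", "architecture_grid", "derive_hidden_size",
    "derive_mlp_size", "patchify", "unpatchify", "ViT3D",
    "build_base_model", "predict_proba", "train_base",
]


def derive_hidden_size(P: int, C: int, k: int) -> int:
    """Embedding size tied to patch content: D = P^2 * C / k.

    Keeps the total embedding capacity equal to the in-plane patch pixel
    count regardless of how many attention heads split it.
    """
    num = P * P * C
    if num % k != 0:
        raise ValueError(f"k={k} does not divide P^2*C={num}")
    return num // k


def derive_mlp_size(P: int, C: int, N: int) -> int:
    """MLP width rule d = P^2 * C * N.

    Provided as a documented helper only: for the canonical 128 x 128 crop it
    yields 16384, whereas the canonical grid deliberately uses the literal
    values d in {2048, 3072} (the larger matching the original ViT-Base MLP).
    """
    if P <= 0 or C <= 0 or N <= 0:
        raise ValueError("all arguments must be positive")
    return P * P * C * N


@dataclass(frozen=True)
class ViTConfig:
    """One row of the 18-configuration architecture grid."""

    config_id: int
    d: int
    L: int
    D: int
    k: int
    P: int = 16
    C: int = 1
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.D % self.k != 0:
            raise ValueError(f"D={self.D} not divisible by k={self.k}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def from_id(cls, config_id: int) -> "ViTConfig":
        for row in _load_grid():
            if row["config_id"] == config_id:
                return cls(**row)
        raise KeyError(f"no canonical configuration with id {config_id}")


def _load_grid() -> list[dict]:
    text = (importlib.resources.files("vitstack") / "data"
            / "architecture_grid.yaml").read_text()
    return yaml.safe_load(text)


def architecture_grid() -> list[ViTConfig]:
    """The canonical 18 base configurations."""
    return [ViTConfig(**row) for row in _load_grid()]


@dataclass(frozen=True)
class TrainSpec:
    """Base-model training hyperparameters (fixed, not tuned per run)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    max_steps: int = 1000
    batch_size: int = 4
    warmup_steps: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("learning_rate", "weight_decay", "max_steps",
                     "batch_size", "warmup_steps"):
            if getattr(self, name) <= 0 and name != "weight_decay":
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")

    def lr_at(self, step: int) -> float:
        """Learning rate at 1-based ``step`` under the linear warmup ramp."""
        scale = min(1.0, step / self.warmup_steps)
        return self.learning_rate * scale


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, LesionVolume):
        return np.asarray(volume.voxels, dtype=np.float64)
    return np.asarray(volume, dtype=np.float64)


def patchify(volume, P: int) -> np.ndarray:
    """Flatten a (H, W, Z, C) volume into N = HW/P^2 rows of length P^2*Z*C.

    Patches are non-overlapping (P, P, Z) blocks spanning the full depth,
    taken in row-major raster order in-plane; each row is the C-order
    flattening of its block.  The map is a bijection (see
    :func:`unpatchify`).
    """
    x = _as_array(volume)
    h, w, z, c = x.shape
    if h % P or w % P:
        raise ValueError(f"in-plane size {h}x{w} not divisible by P={P}")
    gh, gw = h // P, w // P
    # (gh, P, gw, P, Z, C) -> (gh, gw, P, P, Z, C) -> (N, P^2*Z*C)
    blocks = x.reshape(gh, P, gw, P, z, c).transpose(0, 2, 1, 3, 4, 5)
    return blocks.reshape(gh * gw, P * P * z * c)


def unpatchify(patches: np.ndarray, shape: tuple[int, int, int, int],
               P: int) -> np.ndarray:
    """Inverse of :func:`patchify` for a volume of the given shape."""
    h, w, z, c = shape
    gh, gw = h // P, w // P
    blocks = patches.reshape(gh, gw, P, P, z, c).transpose(0, 2, 1, 3, 4, 5)
    return blocks.reshape(h, w, z, c)


class _Block(nn.Module):
    def __init__(self, rng, D, k, d, dropout):
        self.ln1 = nn.LayerNorm(D)
        self.attn = nn.MultiHeadSelfAttention(rng, D, k)
        self.drop1 = nn.Dropout(dropout)
        self.ln2 = nn.LayerNorm(D)
        self.fc1 = nn.Linear(rng, D, d)
        self.act = nn.GELU()
        self.fc2 = nn.Linear(rng, d, D)
        self.drop2 = nn.Dropout(dropout)

    def forward(self, x, *, train=False, rng=None):
        x = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x)),
                                   train=train, rng=rng)
        x = x + self.drop2.forward(
            self.fc2.forward(self.act.forward(self.fc1.forward(self.ln2.forward(x)))),
            train=train, rng=rng)
        return x

    def backward(self, g):
        gb = self.ln2.backward(self.fc1.backward(self.act.backward(
            self.fc2.backward(self.drop2.backward(g)))))
        g = g + gb
        ga = self.ln1.backward(self.attn.backward(self.drop1.backward(g)))
        return g + ga


class ViT3D(nn.Module):
    """Base 3D vision transformer with a classification-token sigmoid head."""

    def __init__(self, cfg: ViTConfig,
                 input_shape: tuple[int, int, int, int] = (128, 128, 5, 1),
                 seed: int = 42):
        h, w, z, c = input_shape
        if h % cfg.P or w % cfg.P:
            raise ValueError(f"patch size {cfg.P} does not divide {h}x{w}")
        if c != cfg.C:
            raise ValueError(f"config expects C={cfg.C} channels, input has {c}")
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        self.n_patches = (h // cfg.P) * (w // cfg.P)
        patch_dim = cfg.P * cfg.P * z * c

        rng = np.random.default_rng(seed)
        self.patch_proj = nn.Linear(rng, patch_dim, cfg.D)
        self.cls_token = nn.Parameter(nn.trunc_normal(rng, (1, 1, cfg.D)))
        self.pos_embed = nn.Parameter(
            nn.trunc_normal(rng, (1, self.n_patches + 1, cfg.D)))
        self.blocks = [_Block(rng, cfg.D, cfg.k, cfg.d, cfg.dropout)
                       for _ in range(cfg.L)]
        self.norm = nn.LayerNorm(cfg.D)
        self.head = nn.Linear(rng, cfg.D, 1)
        self._cache = None

    # -- forward / backward over batches of patch sequences ---------------

    def forward(self, patch_batch: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a (B, N, P^2*Z*C) batch of patch sequences."""
        b, n, _ = patch_batch.shape
        if n != self.n_patches:
            raise ValueError(f"expected {self.n_patches} patches, got {n}")
        tok = self.patch_proj.forward(patch_batch)
        cls = np.broadcast_to(self.cls_token.value, (b, 1, self.cfg.D))
        x = np.concatenate([cls, tok], axis=1) + self.pos_embed.value
        for blk in self.blocks:
            x = blk.forward(x, train=train, rng=rng)
        x = self.norm.forward(x)
        self._cls_state = x[:, 0, :]
        logits = self.head.forward(self._cls_state)[:, 0]
        return logits

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits[:, None])
        g_seq = np.zeros((g.shape[0], self.n_patches + 1, self.cfg.D))
        g_seq[:, 0, :] = g
        g_seq = self.norm.backward(g_seq)
        for blk in reversed(self.blocks):
            g_seq = blk.backward(g_seq)
        self.pos_embed.grad += g_seq.sum(axis=0, keepdims=True)
        self.cls_token.grad += g_seq[:, :1, :].sum(axis=0, keepdims=True)
        self.patch_proj.backward(g_seq[:, 1:, :])

    # -- convenience API on volumes ---------------------------------------

    def _batch(self, volumes: Sequence) -> np.ndarray:
        return np.stack([patchify(v, self.cfg.P) for v in volumes])

    def logits(self, volumes: Sequence) -> np.ndarray:
        """Deterministic (eval-mode) logits for a list of volumes."""
        return self.forward(self._batch(volumes))

    def embeddings(self, volumes: Sequence) -> np.ndarray:
        """Final classification-token states, (B, D)."""
        self.forward(self._batch(volumes))
        return self._cls_state.copy()


def build_base_model(cfg: ViTConfig,
                     input_shape: tuple[int, int, int, int] = (128, 128, 5, 1),
                     seed: int = 42) -> ViT3D:
    return ViT3D(cfg, input_shape, seed)


def predict_proba(model: ViT3D, volumes) -> np.ndarray:
    """Predicted positive-class (high grade) probabilities, each in (0, 1)."""
    single = isinstance(volumes, (LesionVolume, np.ndarray)) and not (
        isinstance(volumes, np.ndarray) and volumes.ndim == 5)
    vols = [volumes] if single else list(volumes)
    p = nn.sigmoid(model.logits(vols))
    return p[0] if single else p


def expected_parameter_count(cfg: ViTConfig,
                             input_shape: tuple[int, int, int, int]) -> int:
    """Closed-form trainable-parameter count for a config and input shape."""
    h, w, z, c = input_shape
    n = (h // cfg.P) * (w // cfg.P)
    pdim = cfg.P * cfg.P * z * c
    d_model, d_mlp = cfg.D, cfg.d
    per_block = (4 * (d_model * d_model + d_model)      # qkv (3D) + proj
                 + 2 * 2 * d_model                      # two layer norms
                 + d_model * d_mlp + d_mlp              # fc1
                 + d_mlp * d_model + d_model)           # fc2
    return (pdim * d_model + d_model                    # patch projection
            + d_model                                   # class token
            + (n + 1) * d_model                         # position embeddings
            + cfg.L * per_block
            + 2 * d_model                               # final norm
            + d_model + 1)                              # head


def train_base(model: ViT3D, train_set: Sequence, val_set: Sequence = (),
               spec: TrainSpec = TrainSpec()) -> tuple[ViT3D, pd.DataFrame]:
    """Train a base model with Adam + binary cross-entropy.

    Runs exactly ``spec.max_steps`` optimisation steps with a linear
    learning-rate warmup over ``spec.warmup_steps`` (when warmup equals the
    step budget the schedule is a pure linear ramp).  Minibatches cycle
    through seeded reshuffles of the training set.  The returned history has
    one row per step (loss, learning rate) plus a final validation loss
    column entry when a validation set is given.  Fully deterministic for a
    fixed spec and model seed.
    """
    train_set = list(train_set)
    if not train_set:
        raise ValueError("training set is empty")
    patches = model._batch(train_set)
    labels = np.array([v.label for v in train_set], dtype=np.float64)

    rng = np.random.default_rng(spec.seed)
    opt = nn.Adam(model.parameters(), lr=spec.learning_rate,
                  weight_decay=spec.weight_decay)
    order = rng.permutation(len(train_set))
    cursor = 0
    rows = []
    for step in range(1, spec.max_steps + 1):
        if cursor + spec.batch_size > len(order):
            order = rng.permutation(len(train_set))
            cursor = 0
        idx = order[cursor:cursor + spec.batch_size]
        cursor += spec.batch_size
        logits = model.forward(patches[idx], train=model.cfg.dropout > 0,
                               rng=rng)
        loss, g = nn.bce_with_logits(logits, labels[idx])
        model.zero_grad()
        model.backward(g)
        opt.step(lr_scale=min(1.0, step / spec.warmup_steps))
        rows.append((step, loss, spec.lr_at(step)))

    history = pd.DataFrame(rows, columns=["step", "loss", "lr"])
    if len(val_set):
        val_logits = model.logits(list(val_set))
        val_labels = np.array([v.label for v in val_set], dtype=np.float64)
        history.attrs["val_loss"] = nn.bce_with_logits(val_logits, val_labels)[0]
    return model, history
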