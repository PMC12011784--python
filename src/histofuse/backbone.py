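"""Dual-branch cross-attention vision transformer.

The backbone processes one image through two parallel token streams: a
small-patch branch capturing fine detail and a large-patch branch capturing
global context.  Per branch, the image is cut into non-overlapping ``P x P``
patches, each flattened and linearly embedded; a learned CLS token is
prepended and a learned positional encoding added:

    X_patch = Linear(patch(I));   X_0 = [X_cls, X_patch] + X_pos

Each encoder layer applies pre-norm multi-head self-attention and a GELU
feed-forward block with residual connections:

    Y = X + MSA(LN(X));   X' = Y + FFN(LN(Y))

After the encoder stacks, the branches exchange information through
bidirectional cross-attention rounds.  To update the large-branch CLS token
from the small branch, the CLS is projected into the small-branch width
(``f``), concatenated in front of the small-branch patch tokens, and used as
the sole query of a scaled-dot-product attention over that sequence:

    x' = [f(cls) || patches];   z = softmax(LN(x') Wq (LN(x') Wk)^T / sqrt(dk)) LN(x') Wv

The attended CLS receives a residual add in the projected space and is then
projected back to the large-branch width (``g``); the mirrored update (small
CLS attending over large patches) uses its own parameter set.  Both updates
within a round read the pre-round branch states.  Cross-attention applies no
feed-forward block after the residual.

Classification: each branch's final (layer-normalised) CLS vector passes
through its own linear head and the two head outputs are averaged
elementwise to form the fused logits.

All parameters live in a flat ``{name: Tensor}`` dictionary, which doubles as
the self-describing weight-archive schema (saved as ``.npz``), enabling
partial loading of pretrained weights by tensor name and shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "BackboneConfig",
    "PAPER",
    "TINY",
    "DeepFeatures",
    "LogitPair",
    "init_params",
    "embed_patches",
    "encoder_layer",
    "cross_attention_fuse",
    "forward_features",
    "forward_logits",
    "fuse_logits",
    "train_backbone",
    "save_params",
    "load_pretrained",
    "LoadReport",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of the dual-branch backbone."""

    image_size: int = 240
    patch_small: int = 12
    patch_large: int = 16
    dim_small: int = 384
    dim_large: int = 768
    depth: int = 2
    heads: int = 6
    mlp_ratio: float = 4.0
    n_cross_rounds: int = 1
    n_classes: int = 2

    def __post_init__(self):
        for p in (self.patch_small, self.patch_large):
            if self.image_size % p != 0:
                raise ValueError(
                    f"image_size {self.image_size} not divisible by patch size {p}")
        for d in (self.dim_small, self.dim_large):
            if d % self.heads != 0:
                raise ValueError(f"dim {d} not divisible by heads {self.heads}")

    def n_patches(self, patch: int) -> int:
        return (self.image_size // patch) ** 2


#: preset honouring the printed per-branch CLS widths 384 / 768
PAPER = BackboneConfig()
#: small CPU-friendly preset for tests and synthetic end-to-end runs
TINY = BackboneConfig(image_size=64, patch_small=8, patch_large=16,
                      dim_small=32, dim_large=64, depth=2, heads=2,
                      mlp_ratio=2.0, n_cross_rounds=1)

PRESETS = {"paper": PAPER, "tiny": TINY}


def config_from_dict(doc: dict) -> BackboneConfig:
    """Build a config from ``{"preset": name, **overrides}`` (YAML-friendly)."""
    doc = dict(doc)
    base = PRESETS[doc.pop("preset", "paper")]
    return replace(base, **doc) if doc else base


@dataclass
class DeepFeatures:
    """Final per-branch CLS vectors (batch-major numpy arrays)."""

    z_cls_small: np.ndarray
    z_cls_large: np.ndarray


@dataclass
class LogitPair:
    """Per-branch head outputs plus their elementwise mean."""

    logits_small: np.ndarray
    logits_large: np.ndarray
    fused: np.ndarray


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

_INIT_STD = 0.02


def _init_encoder(params, prefix, dim, mlp_hidden, rng):
    params[f"{prefix}.ln1.g"] = ad.parameter(np.ones(dim))
    params[f"{prefix}.ln1.b"] = ad.parameter(np.zeros(dim))
    for w in ("wq", "wk", "wv", "wo"):
        params[f"{prefix}.attn.{w}"] = ad.parameter((dim, dim), rng, _INIT_STD)
        params[f"{prefix}.attn.b{w[1]}"] = ad.parameter(np.zeros(dim))
    params[f"{prefix}.ln2.g"] = ad.parameter(np.ones(dim))
    params[f"{prefix}.ln2.b"] = ad.parameter(np.zeros(dim))
    params[f"{prefix}.ffn.w1"] = ad.parameter((dim, mlp_hidden), rng, _INIT_STD)
    params[f"{prefix}.ffn.b1"] = ad.parameter(np.zeros(mlp_hidden))
    params[f"{prefix}.ffn.w2"] = ad.parameter((mlp_hidden, dim), rng, _INIT_STD)
    params[f"{prefix}.ffn.b2"] = ad.parameter(np.zeros(dim))


def _init_cross(params, prefix, dim_src, dim_other, rng):
    """Block updating one branch's CLS from the other branch's patches."""
    params[f"{prefix}.f.w"] = ad.parameter((dim_src, dim_other), rng, _INIT_STD)
    params[f"{prefix}.f.b"] = ad.parameter(np.zeros(dim_other))
    params[f"{prefix}.ln.g"] = ad.parameter(np.ones(dim_other))
    params[f"{prefix}.ln.b"] = ad.parameter(np.zeros(dim_other))
    for w in ("wq", "wk", "wv"):
        params[f"{prefix}.{w}"] = ad.parameter((dim_other, dim_other), rng, _INIT_STD)
        params[f"{prefix}.b{w[1]}"] = ad.parameter(np.zeros(dim_other))
    params[f"{prefix}.g.w"] = ad.parameter((dim_other, dim_src), rng, _INIT_STD)
    params[f"{prefix}.g.b"] = ad.parameter(np.zeros(dim_src))


def init_params(config: BackboneConfig, seed: int) -> dict[str, Tensor]:
    """Gaussian(0, 0.02) weight init, zero biases, unit layer-norm scales."""
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    branches = (("small", config.patch_small, config.dim_small),
                ("large", config.patch_large, config.dim_large))
    mlp = config.mlp_ratio
    for name, patch, dim in branches:
        n = config.n_patches(patch)
        params[f"{name}.embed.w"] = ad.parameter((patch * patch * 3, dim), rng, _INIT_STD)
        params[f"{name}.embed.b"] = ad.parameter(np.zeros(dim))
        params[f"{name}.cls"] = ad.parameter((1, 1, dim), rng, _INIT_STD)
        params[f"{name}.pos"] = ad.parameter((1, 1 + n, dim), rng, _INIT_STD)
        for k in range(config.depth):
            _init_encoder(params, f"{name}.enc{k}", dim, int(mlp * dim), rng)
        params[f"{name}.norm.g"] = ad.parameter(np.ones(dim))
        params[f"{name}.norm.b"] = ad.parameter(np.zeros(dim))
    for r in range(config.n_cross_rounds):
        _init_cross(params, f"cross{r}.large", config.dim_large, config.dim_small, rng)
        _init_cross(params, f"cross{r}.small", config.dim_small, config.dim_large, rng)
    params["head.small.w"] = ad.parameter((config.dim_small, config.n_classes), rng, _INIT_STD)
    params["head.small.b"] = ad.parameter(np.zeros(config.n_classes))
    params["head.large.w"] = ad.parameter((config.dim_large, config.n_classes), rng, _INIT_STD)
    params["head.large.b"] = ad.parameter(np.zeros(config.n_classes))
    return params


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------

def normalize_images(images) -> np.ndarray:
    """uint8 batch (B,H,W,3) or single image -> float in [-1, 1]."""
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    return (arr / 255.0 - 0.5) / 0.5


def patchify(images: np.ndarray, patch: int) -> np.ndarray:
    """(B,H,W,3) -> (B, N, patch*patch*3), row-major patch order."""
    B, H, W, C = images.shape
    if H % patch or W % patch:
        raise ValueError(f"image size {H}x{W} not divisible by patch {patch}")
    x = images.reshape(B, H // patch, patch, W // patch, patch, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, (H // patch) * (W // patch), patch * patch * C)


def embed_patches(images, patch: int, params: dict[str, Tensor],
                  branch: str) -> Tensor:
    """Patch-embed a normalised image batch: tokens = [CLS, patches] + pos."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    flat = patchify(images, patch)
    B = flat.shape[0]
    tokens = ad.linear(Tensor(flat), params[f"{branch}.embed.w"],
                       params[f"{branch}.embed.b"])
    cls = ad.broadcast_to(params[f"{branch}.cls"],
                          (B, 1, tokens.shape[2]))
    x = ad.concat([cls, tokens], axis=1)
    return ad.add(x, params[f"{branch}.pos"])


def _multi_head_attention(q: Tensor, kv: Tensor, heads: int, wq, bq, wk, bk,
                          wv, bv, wo=None, bo=None):
    """Scaled dot-product attention; returns (output, attention weights)."""
    B, Tq, D = q.shape
    Tk = kv.shape[1]
    dk = D // heads
    def split(t, T):
        return ad.transpose(ad.reshape(t, (B, T, heads, dk)), (0, 2, 1, 3))
    qh = split(ad.linear(q, wq, bq), Tq)
    kh = split(ad.linear(kv, wk, bk), Tk)
    vh = split(ad.linear(kv, wv, bv), Tk)
    scores = ad.matmul(qh, ad.transpose(kh, (0, 1, 3, 2))) / math.sqrt(dk)
    attn = ad.softmax(scores, axis=-1)
    out = ad.matmul(attn, vh)
    out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (B, Tq, D))
    if wo is not None:
        out = ad.linear(out, wo, bo)
    return out, attn.data


def encoder_layer(x: Tensor, params: dict[str, Tensor], prefix: str,
                  heads: int, return_attn: bool = False):
    """Pre-norm transformer encoder layer: Y = X + MSA(LN X); X' = Y + FFN(LN Y)."""
    if x.shape[2] != params[f"{prefix}.ln1.g"].shape[0]:
        raise ValueError("token dimension does not match layer parameters")
    p = params
    u = ad.layer_norm(x, p[f"{prefix}.ln1.g"], p[f"{prefix}.ln1.b"])
    msa, attn = _multi_head_attention(
        u, u, heads,
        p[f"{prefix}.attn.wq"], p[f"{prefix}.attn.bq"],
        p[f"{prefix}.attn.wk"], p[f"{prefix}.attn.bk"],
        p[f"{prefix}.attn.wv"], p[f"{prefix}.attn.bv"],
        p[f"{prefix}.attn.wo"], p[f"{prefix}.attn.bo"])
    y = ad.add(x, msa)
    v = ad.layer_norm(y, p[f"{prefix}.ln2.g"], p[f"{prefix}.ln2.b"])
    h = ad.gelu(ad.linear(v, p[f"{prefix}.ffn.w1"], p[f"{prefix}.ffn.b1"]))
    out = ad.add(y, ad.linear(h, p[f"{prefix}.ffn.w2"], p[f"{prefix}.ffn.b2"]))
    if return_attn:
        return out, attn
    return out


def cross_attention_fuse(cls_src: Tensor, patches_other: Tensor,
                         params: dict[str, Tensor], prefix: str,
                         heads: int = 1, return_attn: bool = False):
    """Update one branch's CLS token by attending over the other branch.

    ``cls_src`` is (B, 1, dim_src); ``patches_other`` is (B, N, dim_other)
    with N >= 0.  The CLS is projected to dim_other (``f``), concatenated in
    front of the patch tokens, attends over the 1+N positions as the sole
    query, receives a residual add, and is projected back (``g``).
    """
    p = params
    if cls_src.shape[2] != p[f"{prefix}.f.w"].shape[0]:
        raise ValueError("CLS dimension does not match projection f")
    if patches_other.shape[1] > 0 and \
            patches_other.shape[2] != p[f"{prefix}.f.w"].shape[1]:
        raise ValueError("patch dimension does not match projection f")
    h = ad.linear(cls_src, p[f"{prefix}.f.w"], p[f"{prefix}.f.b"])
    if patches_other.shape[1] > 0:
        x = ad.concat([h, patches_other], axis=1)
    else:
        x = h
    u = ad.layer_norm(x, p[f"{prefix}.ln.g"], p[f"{prefix}.ln.b"])
    q = u[:, 0:1, :]
    out, attn = _multi_head_attention(
        q, u, heads,
        p[f"{prefix}.wq"], p[f"{prefix}.bq"],
        p[f"{prefix}.wk"], p[f"{prefix}.bk"],
        p[f"{prefix}.wv"], p[f"{prefix}.bv"])
    z = ad.add(h, out)
    new_cls = ad.linear(z, p[f"{prefix}.g.w"], p[f"{prefix}.g.b"])
    if return_attn:
        return new_cls, attn
    return new_cls


def _forward_tokens(images, config: BackboneConfig, params: dict[str, Tensor]):
    """Run both branch stacks + cross rounds; returns final CLS Tensors."""
    x_s = embed_patches(images, config.patch_small, params, "small")
    x_l = embed_patches(images, config.patch_large, params, "large")
    for k in range(config.depth):
        x_s = encoder_layer(x_s, params, f"small.enc{k}", config.heads)
        x_l = encoder_layer(x_l, params, f"large.enc{k}", config.heads)
    for r in range(config.n_cross_rounds):
        # both updates read the pre-round states (simultaneous exchange)
        new_l = cross_attention_fuse(x_l[:, 0:1, :], x_s[:, 1:, :], params,
                                     f"cross{r}.large", config.heads)
        new_s = cross_attention_fuse(x_s[:, 0:1, :], x_l[:, 1:, :], params,
                                     f"cross{r}.small", config.heads)
        x_l = ad.concat([new_l, x_l[:, 1:, :]], axis=1)
        x_s = ad.concat([new_s, x_s[:, 1:, :]], axis=1)
    z_s = ad.layer_norm(x_s[:, 0, :], params["small.norm.g"], params["small.norm.b"])
    z_l = ad.layer_norm(x_l[:, 0, :], params["large.norm.g"], params["large.norm.b"])
    return z_s, z_l


def forward_features(images, config: BackboneConfig,
                     params: dict[str, Tensor]) -> DeepFeatures:
    """Per-branch CLS feature vectors for a uint8 image or batch."""
    single = np.asarray(images).ndim == 3
    z_s, z_l = _forward_tokens(normalize_images(images), config, params)
    zs, zl = z_s.data, z_l.data
    if single:
        zs, zl = zs[0], zl[0]
    return DeepFeatures(z_cls_small=zs, z_cls_large=zl)


def _logits_tensor(images, config, params) -> Tensor:
    z_s, z_l = _forward_tokens(normalize_images(images), config, params)
    ls = ad.linear(z_s, params["head.small.w"], params["head.small.b"])
    ll = ad.linear(z_l, params["head.large.w"], params["head.large.b"])
    return ad.mul(ad.add(ls, ll), 0.5)


def fuse_logits(features: DeepFeatures, head_small, head_large) -> LogitPair:
    """Average the two branch-head outputs: fused = (W_l z_l + W_s z_s)/2.

    ``head_small``/``head_large`` are ``(W, b)`` pairs mapping the branch
    dims to the class count.
    """
    w_s, b_s = head_small
    w_l, b_l = head_large
    z_s = np.atleast_2d(features.z_cls_small)
    z_l = np.atleast_2d(features.z_cls_large)
    if z_s.shape[1] != np.asarray(w_s).shape[0] or \
            z_l.shape[1] != np.asarray(w_l).shape[0]:
        raise ValueError("head weight shapes do not match branch dimensions")
    ls = z_s @ w_s + b_s
    ll = z_l @ w_l + b_l
    squeeze = np.asarray(features.z_cls_small).ndim == 1
    if squeeze:
        ls, ll = ls[0], ll[0]
    return LogitPair(logits_small=ls, logits_large=ll, fused=0.5 * (ls + ll))


def forward_logits(images, config: BackboneConfig,
                   params: dict[str, Tensor]) -> np.ndarray:
    """Fused class logits (numpy) for a uint8 image batch."""
    return _logits_tensor(images, config, params).data


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_backbone(images, labels, config: BackboneConfig,
                   params: dict[str, Tensor], *, steps: int | None = None,
                   epochs: int = 1, batch_size: int = 16, lr: float = 1e-3,
                   seed: int = 0) -> list[float]:
    """Minibatch Adam on the fused-logit cross-entropy; returns per-step losses.

    ``labels`` use the package coding {1, 2} and are shifted to {0, 1}
    class indices internally.  If ``steps`` is given it overrides ``epochs``
    and repeatedly cycles minibatches.
    """
    images = np.asarray(images)
    y = np.asarray(labels, dtype=int) - 1
    n = len(y)
    opt = ad.Adam(list(params.values()), lr=lr)
    rng = np.random.default_rng(seed)
    losses: list[float] = []

    def run_batch(idx) -> float:
        opt.zero_grad()
        loss = ad.cross_entropy(_logits_tensor(images[idx], config, params), y[idx])
        loss.backward()
        opt.step()
        return float(loss.data)

    if steps is not None:
        order = rng.permutation(n)
        pos = 0
        for _ in range(steps):
            if pos + batch_size > n:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos:pos + min(batch_size, n)]
            pos += batch_size
            losses.append(run_batch(idx))
    else:
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                losses.append(run_batch(order[start:start + batch_size]))
    return losses


# ---------------------------------------------------------------------------
# weight archives
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    """Outcome of a partial weight load."""

    matched: list[str]
    unmatched_archive: list[str]
    unmatched_model: list[str]


def save_params(params: dict[str, Tensor], path) -> None:
    """Write the parameter dictionary as a named-tensor ``.npz`` archive."""
    np.savez(Path(path), **{k: v.data for k, v in params.items()})


def load_pretrained(params: dict[str, Tensor], archive_path) -> LoadReport:
    """Load tensors by name from an ``.npz`` archive into ``params``.

    Tensors present in both and shape-compatible are copied; archive tensors
    whose names are absent from the model are reported unmatched.  A name
    match with a shape conflict raises, naming the tensor.
    """
    with np.load(Path(archive_path)) as archive:
        matched, unmatched_archive = [], []
        for name in archive.files:
            if name not in params:
                unmatched_archive.append(name)
                continue
            value = archive[name]
            if value.shape != params[name].shape:
                raise ValueError(
                    f"shape conflict for tensor {name!r}: archive "
                    f"{value.shape} vs model {params[name].shape}")
            params[name].data = value.astype(np.float64)
            matched.append(name)
    unmatched_model = [k for k in params if k not in matched]
    return LoadReport(matched=matched, unmatched_archive=unmatched_archive,
                      unmatched_model=unmatched_model)
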