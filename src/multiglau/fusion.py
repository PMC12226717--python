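"""The two multimodal fusion networks and their sklearn-style estimators.

Freeze-Missing (binary pre-diagnosis, tier 2) extracts each present
image modality with a 7x7 conv + max-pool + three Se-Conv blocks, fuses
the image feature maps (mean | concat, optionally through another
Se-Conv), and blends the fused image feature with the numerical-branch
feature through an MLP ending in a sigmoid.  When a modality is absent
the branch receives a zero indicator, its output feature is forced to
exact zeros before fusion, and its parameters receive exactly zero
gradient from that sample — samples with missing images therefore never
perturb the missing branch ("freeze").  Mechanically, each branch
processes only the samples that carry it (gather), and the results are
scattered back into a zero feature tensor, so nullity and gradient
freezing hold by construction, and batch-norm statistics are never
updated from zero-substituted passes.

M3-VF (four-class definitive diagnosis, tier 3) uses a 7x7 conv +
batch-norm + max-pool + nine CBAM-residual blocks + 1x1 conv per image
branch, a fully connected numerical branch, and fuses the four modality
tokens with a transformer encoder before an MLP softmax head.  CBAM and
the encoder can each be ablated; single-stream baselines take one image
modality only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .core.types import ClinicalRecord, Dataset, ImageBundle, MODALITIES, SeverityStage
from .nn import (
    MLP,
    Adam,
    BatchNorm2d,
    CBAMResidualBlock,
    Conv2d,
    Linear,
    Module,
    SEConvBlock,
    Tensor,
    TransformerEncoderLayer,
    concat,
)
from .staging import binarize_stage

__all__ = [
    "NetConfig",
    "BranchMaskState",
    "FreezeMissingNet",
    "M3VFNet",
    "FreezeMissingClassifier",
    "M3VFClassifier",
    "freeze_missing_forward",
    "m3vf_forward",
    "train_net",
    "prediag_labels",
    "bundles_to_arrays",
]

_STREAMS = ("all", "global_only", "focused_only", "rnfl_only")
_FUSIONS = ("mean", "concat", "seconv_mean", "seconv_concat")


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters; every width is config-exposed."""

    variant: str = "freeze_missing"          # "freeze_missing" | "m3vf"
    fusion: str = "seconv_concat"            # freeze_missing image fusion
    use_cbam: bool = True                    # m3vf ablations
    use_transformer: bool = True
    stream: str = "all"
    widths: tuple = (32, 64, 128)
    reduction: int = 8
    embed_dim: int = 128
    n_heads: int = 4
    encoder_depth: int = 1
    n_blocks: int = 9                        # CBAM-residual depth (m3vf)
    numeric_hidden: int = 32
    head_hidden: int = 64
    spatial_kernel: int = 7
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("freeze_missing", "m3vf"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.fusion not in _FUSIONS:
            raise ValueError(f"fusion must be one of {_FUSIONS}")
        if self.stream not in _STREAMS:
            raise ValueError(f"stream must be one of {_STREAMS}")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")


@dataclass(frozen=True)
class BranchMaskState:
    """Per-branch bookkeeping of the missing-modality mechanism."""

    presence: tuple
    substituted_zero: tuple
    frozen: tuple

    def __post_init__(self) -> None:
        for p, z, f in zip(self.presence, self.substituted_zero, self.frozen):
            if not p and not (z and f):
                raise ValueError("absent branch must be zero-substituted and frozen")


def _scatter_rows(rows: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Place rows (k, d...) into a zero (n, d...) tensor at positions idx.

    Implemented as a constant selection-matrix product so gradients flow
    only to the contributing rows; every other row is exactly zero.
    """
    k = rows.shape[0]
    S = np.zeros((n, k))
    S[idx, np.arange(k)] = 1.0
    flat = rows.reshape(k, int(np.prod(rows.shape[1:])))
    return (Tensor(S) @ flat).reshape((n,) + tuple(rows.shape[1:]))


class _ImageBranchFM(Module):
    """Freeze-Missing image extractor: 7x7 conv, max-pool, 3 Se-Conv blocks."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        w0, w1, w2 = cfg.widths
        self.conv = Conv2d(1, w0, 7, rng, stride=2, padding=3)
        self.block1 = SEConvBlock(w0, w1, rng, stride=2, reduction=cfg.reduction)
        self.block2 = SEConvBlock(w1, w2, rng, stride=2, reduction=cfg.reduction)
        self.block3 = SEConvBlock(w2, w2, rng, stride=1, reduction=cfg.reduction)

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x).relu().maxpool2d(2)
        return self.block3(self.block2(self.block1(x)))


class _ImageBranchM3(Module):
    """M3-VF image extractor: 7x7 conv, BN, max-pool, n CBAM-residual
    blocks, 1x1 conv."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        w0, w1, w2 = cfg.widths
        self.conv = Conv2d(1, w0, 7, rng, stride=2, padding=3)
        self.bn = BatchNorm2d(w0)
        blocks = []
        width = w0
        for b in range(cfg.n_blocks):
            stride = 2 if b in (1, 4) else 1
            out_w = w1 if b == 1 else (w2 if b == 4 else width)
            blocks.append(CBAMResidualBlock(
                width, out_w, rng, stride=stride, reduction=cfg.reduction,
                use_cbam=cfg.use_cbam, spatial_kernel=cfg.spatial_kernel))
            width = out_w
        self.blocks = blocks
        self.conv1x1 = Conv2d(width, width, 1, rng)
        self.out_width = width

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv(x)).relu().maxpool2d(2)
        for blk in self.blocks:
            x = blk(x)
        return self.conv1x1(x)


class FreezeMissingNet(Module):
    """Missing-modality-robust binary pre-diagnosis network."""

    def __init__(self, cfg: NetConfig):
        super().__init__()
        if cfg.variant != "freeze_missing":
            raise ValueError("cfg.variant must be 'freeze_missing'")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        w2 = cfg.widths[2]
        self.branch_global = _ImageBranchFM(cfg, rng)
        self.branch_focused = _ImageBranchFM(cfg, rng)
        self.branch_rnfl = _ImageBranchFM(cfg, rng)
        n_img = 3
        if cfg.fusion == "seconv_concat":
            self.fuse_seconv = SEConvBlock(n_img * w2, w2, rng, reduction=cfg.reduction)
            img_feat = w2
        elif cfg.fusion == "seconv_mean":
            self.fuse_seconv = SEConvBlock(w2, w2, rng, reduction=cfg.reduction)
            img_feat = w2
        elif cfg.fusion == "concat":
            self.fuse_seconv = None
            img_feat = n_img * w2
        else:  # mean
            self.fuse_seconv = None
            img_feat = w2
        self.numeric = MLP([5, cfg.numeric_hidden, cfg.numeric_hidden], rng)
        self.head = MLP([img_feat + cfg.numeric_hidden, cfg.head_hidden, 1], rng)

    def _branches(self):
        return [self.branch_global, self.branch_focused, self.branch_rnfl]

    def forward(self, images: Sequence[Optional[np.ndarray]], presence: np.ndarray,
                numeric: np.ndarray) -> Tensor:
        """Batch forward.

        ``images[i]`` is the (n, 1, H, W) stack for modality i (rows for
        absent samples may hold anything — they are never read);
        ``presence`` is (n, 3) boolean; ``numeric`` is the standardized
        (n, 5) feature matrix.  Returns the serious-class probability
        (n,) as a Tensor.
        """
        n = numeric.shape[0]
        presence = np.asarray(presence, dtype=bool)
        maps = []
        for i, branch in enumerate(self._branches()):
            idx = np.flatnonzero(presence[:, i])
            if idx.size == 0:
                maps.append(None)
                continue
            im = images[i]
            branch_in = im[idx] if isinstance(im, Tensor) else Tensor(np.asarray(im)[idx])
            out = branch(branch_in)
            maps.append(_scatter_rows(out, idx, n))
        shape_ref = next((m for m in maps if m is not None), None)
        if shape_ref is None:
            w2 = self.cfg.widths[2]
            s = max(1, self.cfg.image_size // 16)
            zero = Tensor(np.zeros((n, w2, s, s)))
            maps = [zero, zero, zero]
        else:
            maps = [m if m is not None else Tensor(np.zeros(shape_ref.shape))
                    for m in maps]

        if self.cfg.fusion in ("mean", "seconv_mean"):
            # renormalized mean over present branches only
            denom = np.maximum(presence.sum(axis=1), 1).astype(float)
            summed = maps[0] + maps[1] + maps[2]
            fused = summed * Tensor((1.0 / denom).reshape(n, 1, 1, 1))
        else:
            fused = concat(maps, axis=1)
        if self.fuse_seconv is not None:
            fused = self.fuse_seconv(fused)
        img_vec = fused.mean(axis=(2, 3))
        num_vec = self.numeric(Tensor(numeric)).relu()
        logit = self.head(concat([img_vec, num_vec], axis=1))
        return logit.reshape(n).sigmoid()


class M3VFNet(Module):
    """Four-class definitive-diagnosis network (complete modalities)."""

    def __init__(self, cfg: NetConfig):
        super().__init__()
        if cfg.variant != "m3vf":
            raise ValueError("cfg.variant must be 'm3vf'")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        D = cfg.embed_dim
        self.image_streams = [m for m in MODALITIES
                              if cfg.stream in ("all", f"{m}_only")]
        for m in self.image_streams:
            setattr(self, f"branch_{m}", _ImageBranchM3(cfg, rng))
            setattr(self, f"token_{m}",
                    Linear(getattr(self, f"branch_{m}").out_width, D, rng))
        self.use_numeric = cfg.stream == "all"
        if self.use_numeric:
            self.numeric = MLP([5, cfg.numeric_hidden, D], rng)
        if cfg.use_transformer:
            self.encoder = [TransformerEncoderLayer(D, cfg.n_heads, rng)
                            for _ in range(cfg.encoder_depth)]
        else:
            self.encoder = []
        n_tokens = len(self.image_streams) + int(self.use_numeric)
        self.head = MLP([n_tokens * D, cfg.head_hidden, 4], rng)

    def forward(self, images: dict, numeric: np.ndarray) -> Tensor:
        """Softmax probabilities over the four severity stages, (n, 4)."""
        n = numeric.shape[0]
        tokens = []
        for m in self.image_streams:
            if images.get(m) is None:
                raise ValueError(
                    f"modality {m!r} absent: the definitive-diagnosis tier needs "
                    "complete data; route the sample to the pre-diagnosis tier")
            im = images[m]
            fmap = getattr(self, f"branch_{m}")(
                im if isinstance(im, Tensor) else Tensor(np.asarray(im)))
            tokens.append(getattr(self, f"token_{m}")(fmap.mean(axis=(2, 3))))
        if self.use_numeric:
            tokens.append(self.numeric(Tensor(numeric)))
        M = len(tokens)
        D = self.cfg.embed_dim
        toks = concat([t.reshape(n, 1, D) for t in tokens], axis=1)
        for layer in self.encoder:
            toks = layer(toks)
        logits = self.head(toks.reshape(n, M * D))
        return logits.softmax(axis=-1)

    def parameter_audit(self) -> dict:
        """Parameter count per top-level named submodule (structural audit)."""
        counts: dict[str, int] = {}
        for name, p in self.named_parameters():
            top = name.split(".")[0]
            counts[top] = counts.get(top, 0) + p.data.size
        return counts


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def _to_plane(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def bundles_to_arrays(ds: Dataset) -> tuple[dict, np.ndarray]:
    """Stack bundles into per-modality (n,1,H,W) arrays + (n,3) presence.

    Absent rasters are represented by zero planes; the presence mask is
    what decides whether a row is ever consumed.
    """
    n = len(ds)
    presence = np.array([b.presence for b in ds.bundles], dtype=bool)
    shapes = [b.get(m).shape[:2] for b in ds.bundles for m in MODALITIES
              if b.get(m) is not None]
    size = shapes[0] if shapes else (1, 1)
    arrays = {}
    for i, m in enumerate(MODALITIES):
        stack = np.zeros((n, 1, *size))
        for j, b in enumerate(ds.bundles):
            img = b.get(m)
            if img is not None:
                stack[j, 0] = _to_plane(img)
        arrays[m] = stack
    return arrays, presence


def _standardize(numeric: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (numeric - mean) / np.where(std > 0, std, 1.0)


def prediag_labels(ds: Dataset) -> np.ndarray:
    """Binary pre-diagnosis target: 1 = serious (moderate/advanced/severe)."""
    y = []
    for r in ds.records:
        if r.stage_label is None:
            raise ValueError(f"{r.sample_id}: stage_label required for pre-diagnosis")
        y.append(int(binarize_stage(r.stage_label) == "serious"))
    return np.asarray(y, dtype=int)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class OptimConfig:
    lr: float = 1e-4
    batch_size: int = 16
    epochs: int = 30
    patience: int = 10
    seed: int = 0


def _binary_ce(p: Tensor, y: np.ndarray) -> Tensor:
    eps = 1e-9
    yv = Tensor(y.astype(float))
    return -((p + eps).log() * yv + (1.0 - p + eps).log() * (1.0 - yv)).mean()


def _multiclass_ce(proba: Tensor, y: np.ndarray) -> Tensor:
    eps = 1e-9
    picked = proba[np.arange(len(y)), y]
    return -((picked + eps).log()).mean()


def train_net(net: Module, forward_fn, loss_fn, n_train: int,
              val_fn=None, optim_cfg: OptimConfig = None) -> dict:
    """Generic mini-batch training loop with early stopping.

    ``forward_fn(idx)`` runs the net on the given training indices and
    returns the loss Tensor; ``val_fn()`` returns the validation loss as
    a float.  Fully seeded; history of per-epoch losses is returned.
    """
    if n_train == 0:
        raise ValueError("empty training set")
    cfg = optim_cfg or OptimConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, wait = np.inf, None, 0
    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss = forward_fn(idx)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if val_fn is not None:
            net.eval()
            vl = float(val_fn())
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val, wait = vl, 0
                best_state = [p.data.copy() for p in net.parameters()]
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
    if best_state is not None:
        for p, s in zip(net.parameters(), best_state):
            p.data = s
    net.eval()
    return history


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class FreezeMissingClassifier(BaseEstimator):
    """Sklearn-style wrapper training :class:`FreezeMissingNet` on a Dataset.

    ``fit`` consumes a :class:`~multiglau.core.types.Dataset` whose
    records carry stage labels; the binary target is serious
    (moderate/advanced/severe) vs early.  Image modalities may be
    missing per sample; numerical features must be complete (impute
    first).
    """

    def __init__(self, fusion: str = "seconv_concat", widths: tuple = (32, 64, 128),
                 reduction: int = 8, numeric_hidden: int = 32, head_hidden: int = 64,
                 image_size: int = 64, lr: float = 1e-4, batch_size: int = 16,
                 epochs: int = 30, patience: int = 10, val_fraction: float = 0.2,
                 seed: int = 0):
        self.fusion = fusion
        self.widths = widths
        self.reduction = reduction
        self.numeric_hidden = numeric_hidden
        self.head_hidden = head_hidden
        self.image_size = image_size
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def _config(self) -> NetConfig:
        return NetConfig(variant="freeze_missing", fusion=self.fusion,
                         widths=tuple(self.widths), reduction=self.reduction,
                         numeric_hidden=self.numeric_hidden,
                         head_hidden=self.head_hidden,
                         image_size=self.image_size, seed=self.seed)

    def fit(self, ds: Dataset, y: Optional[np.ndarray] = None):
        if len(ds) == 0:
            raise ValueError("empty training set")
        y = prediag_labels(ds) if y is None else np.asarray(y, dtype=int)
        X = ds.feature_matrix()
        if np.isnan(X).any():
            raise ValueError("numerical features incomplete; impute first")
        self.mean_, self.std_ = X.mean(axis=0), X.std(axis=0)
        numeric = _standardize(X, self.mean_, self.std_)
        arrays, presence = bundles_to_arrays(ds)
        images = [arrays[m] for m in MODALITIES]

        rng = np.random.default_rng(self.seed)
        n = len(ds)
        n_val = max(1, int(round(n * self.val_fraction)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        self.net_ = FreezeMissingNet(self._config())

        def fwd(batch):
            idx = tr_idx[batch]
            p = self.net_([im[idx] for im in images], presence[idx], numeric[idx])
            return _binary_ce(p, y[idx])

        def val():
            p = self.net_([im[val_idx] for im in images], presence[val_idx],
                          numeric[val_idx])
            return _binary_ce(p, y[val_idx]).data

        self.history_ = train_net(
            self.net_, fwd, _binary_ce, len(tr_idx), val,
            OptimConfig(lr=self.lr, batch_size=self.batch_size,
                        epochs=self.epochs, patience=self.patience, seed=self.seed))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, ds: Dataset) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        X = ds.feature_matrix()
        numeric = _standardize(X, self.mean_, self.std_)
        arrays, presence = bundles_to_arrays(ds)
        self.net_.eval()
        out = []
        for start in range(0, len(ds), 64):
            sl = slice(start, start + 64)
            p = self.net_([arrays[m][sl] for m in MODALITIES], presence[sl],
                          numeric[sl]).data
            out.append(p)
        p1 = np.concatenate(out)
        return np.stack([1 - p1, p1], axis=1)

    def predict(self, ds: Dataset) -> np.ndarray:
        return (self.predict_proba(ds)[:, 1] >= 0.5).astype(int)


class M3VFClassifier(BaseEstimator):
    """Sklearn-style wrapper training :class:`M3VFNet` on a complete Dataset."""

    def __init__(self, use_cbam: bool = True, use_transformer: bool = True,
                 stream: str = "all", widths: tuple = (32, 64, 128),
                 reduction: int = 8, embed_dim: int = 128, n_heads: int = 4,
                 encoder_depth: int = 1, n_blocks: int = 9,
                 numeric_hidden: int = 32, head_hidden: int = 64,
                 spatial_kernel: int = 7, image_size: int = 64, lr: float = 1e-4,
                 batch_size: int = 16, epochs: int = 30, patience: int = 10,
                 val_fraction: float = 0.2, seed: int = 0):
        self.use_cbam = use_cbam
        self.use_transformer = use_transformer
        self.stream = stream
        self.widths = widths
        self.reduction = reduction
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.encoder_depth = encoder_depth
        self.n_blocks = n_blocks
        self.numeric_hidden = numeric_hidden
        self.head_hidden = head_hidden
        self.spatial_kernel = spatial_kernel
        self.image_size = image_size
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def _config(self) -> NetConfig:
        return NetConfig(variant="m3vf", use_cbam=self.use_cbam,
                         use_transformer=self.use_transformer, stream=self.stream,
                         widths=tuple(self.widths), reduction=self.reduction,
                         embed_dim=self.embed_dim, n_heads=self.n_heads,
                         encoder_depth=self.encoder_depth, n_blocks=self.n_blocks,
                         numeric_hidden=self.numeric_hidden,
                         head_hidden=self.head_hidden,
                         spatial_kernel=self.spatial_kernel,
                         image_size=self.image_size, seed=self.seed)

    def _marshal(self, ds: Dataset):
        arrays, presence = bundles_to_arrays(ds)
        needed = [m for m in MODALITIES
                  if self.stream in ("all", f"{m}_only")]
        for i, m in enumerate(MODALITIES):
            if m in needed and not presence[:, i].all():
                raise ValueError(
                    f"modality {m!r} missing for some samples: the definitive-"
                    "diagnosis tier needs complete data; route incomplete samples "
                    "to the pre-diagnosis tier")
        return {m: arrays[m] for m in needed}

    def fit(self, ds: Dataset, y: Optional[np.ndarray] = None):
        if len(ds) == 0:
            raise ValueError("empty training set")
        y = ds.labels("stage") if y is None else np.asarray(y, dtype=int)
        X = ds.feature_matrix()
        if np.isnan(X).any():
            raise ValueError("numerical features incomplete; impute first")
        self.mean_, self.std_ = X.mean(axis=0), X.std(axis=0)
        numeric = _standardize(X, self.mean_, self.std_)
        images = self._marshal(ds)

        rng = np.random.default_rng(self.seed)
        n = len(ds)
        n_val = max(1, int(round(n * self.val_fraction)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        self.net_ = M3VFNet(self._config())

        def fwd(batch):
            idx = tr_idx[batch]
            proba = self.net_({m: im[idx] for m, im in images.items()}, numeric[idx])
            return _multiclass_ce(proba, y[idx])

        def val():
            proba = self.net_({m: im[val_idx] for m, im in images.items()},
                              numeric[val_idx])
            return _multiclass_ce(proba, y[val_idx]).data

        self.history_ = train_net(
            self.net_, fwd, _multiclass_ce, len(tr_idx), val,
            OptimConfig(lr=self.lr, batch_size=self.batch_size,
                        epochs=self.epochs, patience=self.patience, seed=self.seed))
        self.classes_ = np.arange(4)
        return self

    def predict_proba(self, ds: Dataset) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        numeric = _standardize(ds.feature_matrix(), self.mean_, self.std_)
        images = self._marshal(ds)
        self.net_.eval()
        out = []
        for start in range(0, len(ds), 64):
            sl = slice(start, start + 64)
            out.append(self.net_({m: im[sl] for m, im in images.items()},
                                 numeric[sl]).data)
        return np.concatenate(out)

    def predict(self, ds: Dataset) -> np.ndarray:
        return np.argmax(self.predict_proba(ds), axis=1)


# ---------------------------------------------------------------------------
# single-sample forward convenience functions
# ---------------------------------------------------------------------------

def freeze_missing_forward(net: FreezeMissingNet, bundle: ImageBundle,
                           record: ClinicalRecord,
                           mean: np.ndarray = None, std: np.ndarray = None
                           ) -> tuple[float, BranchMaskState]:
    """Forward one sample; absent branches are zero-substituted and frozen."""
    if record.missing_features():
        raise ValueError(f"{record.sample_id}: numerical features incomplete "
                         f"({record.missing_features()}); impute first")
    presence = np.asarray([bundle.presence], dtype=bool)
    size = net.cfg.image_size
    images = []
    for m in MODALITIES:
        img = bundle.get(m)
        plane = np.zeros((1, 1, size, size)) if img is None else \
            _to_plane(img)[None, None]
        images.append(plane)
    X = record.feature_vector()[None, :]
    if mean is not None:
        X = _standardize(X, mean, std)
    net.eval()
    p = float(net(images, presence, X).data[0])
    pres = bundle.presence
    state = BranchMaskState(presence=pres,
                            substituted_zero=tuple(not x for x in pres),
                            frozen=tuple(not x for x in pres))
    return p, state


def m3vf_forward(net: M3VFNet, bundle: ImageBundle, record: ClinicalRecord,
                 mean: np.ndarray = None, std: np.ndarray = None) -> np.ndarray:
    """Forward one complete sample; returns 4 stage probabilities."""
    images = {}
    for m in net.image_streams:
        img = bundle.get(m)
        if img is None:
            raise ValueError(
                f"{record.sample_id}: modality {m!r} absent — the definitive-"
                "diagnosis tier assumes complete data; use the pre-diagnosis tier")
        images[m] = _to_plane(img)[None, None]
    X = record.feature_vector()[None, :]
    if mean is not None:
        X = _standardize(X, mean, std)
    net.eval()
    return net(images, X).data[0]
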