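"""The two learnable pipeline components and their losses.

* ``ResClass`` — a slice-level ovary-presence classifier: a ResNet18-style
  network truncated to two residual stages of basic blocks with 8 and 16
  channels, global average pooling, dropout 0.2 and a single logit, trained
  with sigmoid cross-entropy plus L2 regularisation.
* ``AttUSeg`` — a four-level 2D attention U-Net (16/32/64/128 features, an
  attention gate on every skip connection, sigmoid output map), trained with
  the focal Tversky loss (alpha = 0.8 weights false negatives, beta = 0.2
  false positives, focal exponent gamma = 1.33 applied as (1 - TI)^(1/gamma)).

Both run on the package's NumPy autograd engine; training is single-threaded
and fully reproducible from the seed in :class:`TrainConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import DegenerateInputError, DomainError, ShapeError
from .nn.autograd import Tensor, sigmoid_ce_with_logits

__all__ = [
    "ClassifierConfig",
    "SegmenterConfig",
    "TverskyParams",
    "TrainConfig",
    "focal_tversky_loss",
    "sigmoid_ce_loss",
    "build_classifier",
    "build_segmenter",
    "train_classifier",
    "train_segmenter",
    "classifier_logits",
    "segmenter_probs",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    stage_features: tuple[int, ...] = (8, 16)
    dropout_p: float = 0.2
    weight_decay: float = 1e-4
    input_size: int = 512

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_p < 1.0):
            raise DomainError("dropout_p must be in [0, 1)")


@dataclass(frozen=True)
class SegmenterConfig:
    level_features: tuple[int, ...] = (16, 32, 64, 128)
    attention_gates: bool = True

    def __post_init__(self) -> None:
        f = self.level_features
        if any(b <= a for a, b in zip(f, f[1:])):
            raise DomainError("level_features must be strictly increasing")


@dataclass(frozen=True)
class TverskyParams:
    alpha: float = 0.8  # false-negative weight
    beta: float = 0.2  # false-positive weight
    gamma: float = 1.33  # focal exponent; loss = (1 - TI)^(1/gamma)
    smooth: float = 1e-6

    def __post_init__(self) -> None:
        if self.gamma < 1.0:
            raise DomainError("gamma must be >= 1")
        if self.smooth <= 0:
            raise DomainError("smooth must be > 0")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 10
    val_fraction: float = 0.25
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def focal_tversky_loss(
    pred: np.ndarray, target: np.ndarray, p: TverskyParams = TverskyParams()
) -> float:
    """Focal Tversky loss on per-pixel probabilities against a binary mask.

    Soft counts TP = sum(pred * target), FN = sum((1 - pred) * target),
    FP = sum(pred * (1 - target)); Tversky index
    TI = (TP + eps) / (TP + alpha * FN + beta * FP + eps);
    loss = (1 - TI)^(1/gamma).  Lies in [0, 1] for pred in [0, 1].
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ShapeError(f"pred {pred.shape} vs target {target.shape}")
    tp = float((pred * target).sum())
    fn = float(((1.0 - pred) * target).sum())
    fp = float((pred * (1.0 - target)).sum())
    ti = (tp + p.smooth) / (tp + p.alpha * fn + p.beta * fp + p.smooth)
    return float((1.0 - ti) ** (1.0 / p.gamma))


def _focal_tversky_t(pred: Tensor, target: np.ndarray, p: TverskyParams) -> Tensor:
    """Autograd counterpart of :func:`focal_tversky_loss` used in training."""
    t = np.asarray(target, dtype=np.float32)
    tp = (pred * t).sum()
    fn = ((pred * -1.0 + 1.0) * t).sum()
    fp = (pred * (1.0 - t)).sum()
    ti = (tp + p.smooth) / (tp + fn * p.alpha + fp * p.beta + p.smooth)
    return (ti * -1.0 + 1.0).pow(1.0 / p.gamma)


def sigmoid_ce_loss(logit, label) -> float:
    """Numerically stable binary cross-entropy with logits, averaged.

    Computes -[y log sigma(z) + (1 - y) log(1 - sigma(z))] without overflow
    for |z| up to at least 1e4, via max(z, 0) - z y + log(1 + e^{-|z|}).
    """
    z = np.asarray(logit, dtype=np.float64)
    y = np.asarray(label, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    """Two 3x3 conv-BN pairs with an identity (or projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, *, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, padding=0,
                                  bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = x if self.proj is None else self.proj_bn(self.proj(x))
        return (out + skip).relu()


class ResClass(nn.Module):
    """Slice-presence classifier: stem + two residual stages + pooled logit."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f1, f2 = cfg.stage_features
        self.stem = nn.ConvBNReLU(1, f1, 3, rng=rng)
        self.stage1 = [_BasicBlock(f1, f1, rng=rng), _BasicBlock(f1, f1, rng=rng)]
        self.stage2 = [_BasicBlock(f1, f2, stride=2, rng=rng), _BasicBlock(f2, f2, rng=rng)]
        self.pool = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(cfg.dropout_p, rng=np.random.default_rng(seed + 1))
        self.head = nn.Linear(f2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N,) logits."""
        h = self.stem(x)
        for blk in self.stage1:
            h = blk(h)
        for blk in self.stage2:
            h = blk(h)
        h = self.dropout(self.pool(h))
        return self.head(h).reshape(-1)


class _AttentionGate(nn.Module):
    """Re-weights encoder features x by a mask computed from x and gate g."""

    def __init__(self, x_ch: int, g_ch: int, inter_ch: int, *, rng):
        super().__init__()
        self.wx = nn.Conv2d(x_ch, inter_ch, 1, padding=0, bias=False, rng=rng)
        self.wg = nn.Conv2d(g_ch, inter_ch, 1, padding=0, bias=True, rng=rng)
        self.psi = nn.Conv2d(inter_ch, 1, 1, padding=0, bias=True, rng=rng)

    def forward(self, x, g):
        a = (self.wx(x) + self.wg(g)).relu()
        return x * self.psi(a).sigmoid()


class _DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, *, rng):
        super().__init__()
        self.c1 = nn.ConvBNReLU(in_ch, out_ch, 3, rng=rng)
        self.c2 = nn.ConvBNReLU(out_ch, out_ch, 3, rng=rng)

    def forward(self, x):
        return self.c2(self.c1(x))


class AttUSeg(nn.Module):
    """Four-level 2D attention U-Net producing a sigmoid probability map.

    Spatial input sizes must be divisible by 8 (three 2x poolings).
    """

    def __init__(self, cfg: SegmenterConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.level_features
        self.enc = [_DoubleConv(1, f[0], rng=rng)]
        for a, b in zip(f[:-1], f[1:]):
            self.enc.append(_DoubleConv(a, b, rng=rng))
        self.pool = nn.MaxPool2d()
        self.up = nn.UpsampleNearest2x()
        self.att = []
        self.dec = []
        for i in range(len(f) - 2, -1, -1):  # decoder levels, deep to shallow
            if cfg.attention_gates:
                self.att.append(
                    _AttentionGate(f[i], f[i + 1], max(f[i] // 2, 4), rng=rng)
                )
            self.dec.append(_DoubleConv(f[i + 1] + f[i], f[i], rng=rng))
        self.out_conv = nn.Conv2d(f[0], 1, 1, padding=0, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, 1, H, W) probabilities in [0, 1]."""
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ShapeError(f"input spatial size {h}x{w} must be divisible by 8")
        skips = []
        h_t = x
        for i, enc in enumerate(self.enc):
            if i > 0:
                h_t = self.pool(h_t)
            h_t = enc(h_t)
            skips.append(h_t)
        d = skips[-1]
        for j, dec in enumerate(self.dec):
            skip = skips[len(self.enc) - 2 - j]
            g = self.up(d)
            s = self.att[j](skip, g) if self.cfg.attention_gates else skip
            d = dec(nn.concat([g, s], axis=1))
        return self.out_conv(d).sigmoid()


def build_classifier(cfg: ClassifierConfig = ClassifierConfig(), seed: int = 0) -> ResClass:
    return ResClass(cfg, seed=seed)


def build_segmenter(cfg: SegmenterConfig = SegmenterConfig(), seed: int = 0) -> AttUSeg:
    return AttUSeg(cfg, seed=seed)


def n_parameters(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _split(n: int, val_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 1 else 0
    return idx[n_val:], idx[:n_val]


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_classifier(
    pairs,
    cfg: TrainConfig,
    ccfg: ClassifierConfig = ClassifierConfig(),
    val_pairs=None,
) -> tuple[ResClass, dict]:
    """Train the slice-presence classifier on (slice, {0,1} label) pairs.

    Minimises sigmoid cross-entropy plus ``weight_decay`` L2; keeps the
    parameters of the epoch with the best validation loss.  Raises
    :class:`DegenerateInputError` when the training set is empty or contains
    a single class.
    """
    if not len(pairs):
        raise DegenerateInputError("empty training set")
    X = np.stack([np.asarray(s, dtype=np.float32) for s, _ in pairs])
    y = np.array([float(l) for _, l in pairs], dtype=np.float32)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("classifier training needs both classes present")

    rng = np.random.default_rng(cfg.seed)
    if val_pairs is None:
        tr, va = _split(len(y), cfg.val_fraction, rng)
        Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]
    else:
        Xtr, ytr = X, y
        Xva = np.stack([np.asarray(s, dtype=np.float32) for s, _ in val_pairs])
        yva = np.array([float(l) for _, l in val_pairs], dtype=np.float32)

    model = build_classifier(ccfg, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=ccfg.weight_decay)
    history: dict = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    since_best = 0
    for _epoch in range(cfg.epochs):
        model.train()
        losses = []
        for idx in _batches(len(ytr), cfg.batch_size, rng):
            opt.zero_grad()
            out = model(Tensor(Xtr[idx][:, None]))
            loss = sigmoid_ce_with_logits(out, ytr[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        vl = _eval_classifier_loss(model, Xva, yva, cfg.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, [a.copy() for a in model.state_arrays()])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best[1] is not None:
        model.load_state_arrays(best[1])
    history["best_val_loss"] = best[0]
    model.eval()
    return model, history


def _eval_classifier_loss(model, X, y, batch_size) -> float:
    losses, ns = [], []
    for idx in _batches(len(y), batch_size, None):
        out = model(Tensor(X[idx][:, None]))
        losses.append(sigmoid_ce_loss(out.data, y[idx]) * len(idx))
        ns.append(len(idx))
    return float(np.sum(losses) / np.sum(ns))


def train_segmenter(
    pairs,
    cfg: TrainConfig,
    scfg: SegmenterConfig = SegmenterConfig(),
    tp: TverskyParams = TverskyParams(),
    val_pairs=None,
) -> tuple[AttUSeg, dict]:
    """Train the attention U-Net on (slice, nonempty mask) pairs.

    Mirrors the cascade's contract that the segmenter sees only slices that
    contain the target: any empty mask in the training set raises
    :class:`DegenerateInputError`.  Minimises the focal Tversky loss; keeps
    the best-validation-loss parameters.
    """
    if not len(pairs):
        raise DegenerateInputError("empty training set")
    X = np.stack([np.asarray(s, dtype=np.float32) for s, _ in pairs])
    M = np.stack([(np.asarray(m) > 0.5).astype(np.float32) for _, m in pairs])
    if (M.reshape(len(M), -1).sum(axis=1) == 0).any():
        raise DegenerateInputError(
            "segmenter training requires every mask to be nonempty"
        )

    rng = np.random.default_rng(cfg.seed)
    if val_pairs is None:
        tr, va = _split(len(M), cfg.val_fraction, rng)
        Xtr, Mtr, Xva, Mva = X[tr], M[tr], X[va], M[va]
    else:
        Xtr, Mtr = X, M
        Xva = np.stack([np.asarray(s, dtype=np.float32) for s, _ in val_pairs])
        Mva = np.stack([(np.asarray(m) > 0.5).astype(np.float32) for _, m in val_pairs])

    model = build_segmenter(scfg, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    since_best = 0
    for _epoch in range(cfg.epochs):
        model.train()
        losses = []
        for idx in _batches(len(Mtr), cfg.batch_size, rng):
            opt.zero_grad()
            pred = model(Tensor(Xtr[idx][:, None]))
            loss = _focal_tversky_t(pred, Mtr[idx][:, None], tp)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        vls = []
        for idx in _batches(len(Mva), cfg.batch_size, None):
            pred = model(Tensor(Xva[idx][:, None]))
            vls.append(focal_tversky_loss(pred.data, Mva[idx][:, None], tp))
        vl = float(np.mean(vls)) if vls else float(np.mean(losses))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, [a.copy() for a in model.state_arrays()])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best[1] is not None:
        model.load_state_arrays(best[1])
    history["best_val_loss"] = best[0]
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def classifier_logits(model: ResClass, slices: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Logits for a stack of (n, H, W) slices."""
    model.eval()
    out = []
    X = np.asarray(slices, dtype=np.float32)
    for i in range(0, len(X), batch_size):
        out.append(model(Tensor(X[i : i + batch_size][:, None])).data)
    return np.concatenate(out) if out else np.empty(0)


def segmenter_probs(model: AttUSeg, slices: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Probability maps for a stack of (n, H, W) slices."""
    model.eval()
    out = []
    X = np.asarray(slices, dtype=np.float32)
    for i in range(0, len(X), batch_size):
        out.append(model(Tensor(X[i : i + batch_size][:, None])).data[:, 0])
    return np.concatenate(out) if out else np.empty((0,) + X.shape[1:])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Module, path: str | Path, *, history: dict | None = None,
                    seed: int | None = None) -> Path:
    """Save model weights (.npz) plus a JSON sidecar with config and history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = model.state_arrays()
    np.savez(path, *arrays)
    kind = "classifier" if isinstance(model, ResClass) else "segmenter"
    meta = {
        "kind": kind,
        "config": asdict(model.cfg),
        "seed": seed,
        "history": history or {},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    return path


def load_checkpoint(path: str | Path) -> nn.Module:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    if meta["kind"] == "classifier":
        cfg = ClassifierConfig(**{**meta["config"],
                                  "stage_features": tuple(meta["config"]["stage_features"])})
        model: nn.Module = ResClass(cfg)
    else:
        cfg = SegmenterConfig(**{**meta["config"],
                                 "level_features": tuple(meta["config"]["level_features"])})
        model = AttUSeg(cfg)
    with np.load(path) as data:
        arrays = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
    model.load_state_arrays(arrays)
    model.eval()
    return model
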