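"""Configurable compact Vision Transformer and its training loop.

The model maps batches of image_size x image_size x 3 inputs to per-class
probabilities: a strided patch projection (the linear map equivalent to a
convolution whose kernel and stride equal the patch size), learnable 1-D
positional embeddings, a pre-norm encoder stack (multi-head self-attention
and GELU MLP blocks with residuals), global-average-pool or class-token
aggregation, and an MLP head with softmax output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError, HistomagError
from .autodiff import Tensor


# ---------------------------------------------------------------------------
# Configuration and arithmetic
# ---------------------------------------------------------------------------

def num_patches(image_size: int, patch_size: int) -> int:
    """Token count N = (H / p) * (W / p) for square images."""
    if image_size % patch_size != 0:
        raise ConfigError(f"image_size {image_size} not divisible by patch_size {patch_size}")
    side = image_size // patch_size
    return side * side


def patch_flatten_dim(patch_size: int, channels: int) -> int:
    """Flattened patch vector length p^2 * c."""
    if patch_size < 1 or channels < 1:
        raise ConfigError("patch_size and channels must be positive")
    return patch_size * patch_size * channels


@dataclass
class ViTConfig:
    image_size: int = 224
    patch_size: int = 16
    channels: int = 3
    projection_dim: int = 128
    num_heads: int = 8
    key_dim: int = 16
    depth: int = 6
    mlp_hidden: int | None = None  # transformer-block MLP width; None -> 2 * projection_dim
    head_hidden: tuple[int, ...] = (256, 128)
    attention_dropout: float = 0.10
    mlp_dropout: float = 0.10
    head_dropout: float = 0.50
    aggregation: str = "gap"  # or "cls_token"
    num_classes: int = 2

    @property
    def attention_width(self) -> int:
        return self.num_heads * self.key_dim

    @property
    def mlp_width(self) -> int:
        return self.mlp_hidden if self.mlp_hidden is not None else 2 * self.projection_dim


def validate_config(cfg: ViTConfig) -> ViTConfig:
    """Return cfg unchanged if every invariant holds; raise ConfigError otherwise."""
    if cfg.image_size % cfg.patch_size != 0:
        raise ConfigError("image_size must be divisible by patch_size")
    if cfg.projection_dim % cfg.num_heads != 0:
        raise ConfigError("projection_dim must be divisible by num_heads")
    for name in ("attention_dropout", "mlp_dropout", "head_dropout"):
        v = getattr(cfg, name)
        if not 0.0 <= v < 1.0:
            raise ConfigError(f"{name} must be in [0, 1)")
    if cfg.depth < 1:
        raise ConfigError("depth must be >= 1")
    if not cfg.head_hidden:
        raise ConfigError("head_hidden must be nonempty")
    if cfg.aggregation not in ("gap", "cls_token"):
        raise ConfigError("aggregation must be 'gap' or 'cls_token'")
    if cfg.num_classes < 2:
        raise ConfigError("num_classes must be >= 2")
    return cfg


def count_parameters(cfg: ViTConfig) -> int:
    """Closed-form trainable parameter count of the constructed model."""
    validate_config(cfg)
    d = cfg.projection_dim
    a = cfg.attention_width
    n = num_patches(cfg.image_size, cfg.patch_size)
    flat = patch_flatten_dim(cfg.patch_size, cfg.channels)
    total = flat * d + d  # patch projection
    tokens = n
    if cfg.aggregation == "cls_token":
        total += d  # class token
        tokens += 1
    total += tokens * d  # positional embeddings
    per_layer = (
        2 * d  # pre-attention layer norm
        + 3 * (d * a + a)  # q, k, v projections
        + (a * d + d)  # attention output projection
        + 2 * d  # pre-MLP layer norm
        + (d * cfg.mlp_width + cfg.mlp_width)  # MLP in
        + (cfg.mlp_width * d + d)  # MLP out
    )
    total += cfg.depth * per_layer
    total += 2 * d  # final layer norm
    dims = (d, *cfg.head_hidden, cfg.num_classes)
    total += sum(i * o + o for i, o in zip(dims[:-1], dims[1:]))
    return total


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def prepare_inputs(images: np.ndarray, I0: float = 240.0) -> np.ndarray:
    """Canonical model input transform: optical density, then standardization.

    Working in OD space makes pixel values linear in stain concentration,
    which is the signal the classifier must read; standardization (global
    mean/std) gives the optimizer a well-scaled problem.
    """
    od = -np.log(np.clip(np.asarray(images, float), 1.0, 255.0) / I0)
    return (od - od.mean()) / od.std()


def _patchify(images: np.ndarray, patch: int) -> np.ndarray:
    """(B, H, W, C) -> (B, N, p*p*C); identical to a stride-p conv's input tiling."""
    b, h, w, c = images.shape
    gh, gw = h // patch, w // patch
    x = images.reshape(b, gh, patch, gw, patch, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, gh * gw, patch * patch * c)


class ViT:
    """Compact Vision Transformer over a NumPy autodiff graph."""

    def __init__(self, cfg: ViTConfig, seed: int = 0):
        validate_config(cfg)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        d = cfg.projection_dim
        a = cfg.attention_width
        n = num_patches(cfg.image_size, cfg.patch_size)
        flat = patch_flatten_dim(cfg.patch_size, cfg.channels)

        def glorot(name, fan_in, fan_out, shape=None):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.params[name] = Tensor(
                rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)),
                requires_grad=True,
            )

        def zeros(name, shape):
            self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name, shape):
            self.params[name] = Tensor(np.ones(shape), requires_grad=True)

        glorot("patch.W", flat, d)
        zeros("patch.b", (d,))
        tokens = n
        if cfg.aggregation == "cls_token":
            zeros("cls", (1, 1, d))
            tokens += 1
        self.params["pos"] = Tensor(rng.normal(0.0, 0.02, size=(1, tokens, d)),
                                    requires_grad=True)
        for layer in range(cfg.depth):
            p = f"enc{layer}."
            ones(p + "ln1.g", (d,))
            zeros(p + "ln1.b", (d,))
            for nm in ("q", "k", "v"):
                glorot(p + f"attn.W{nm}", d, a)
                zeros(p + f"attn.b{nm}", (a,))
            glorot(p + "attn.Wo", a, d)
            zeros(p + "attn.bo", (d,))
            ones(p + "ln2.g", (d,))
            zeros(p + "ln2.b", (d,))
            glorot(p + "mlp.W1", d, cfg.mlp_width)
            zeros(p + "mlp.b1", (cfg.mlp_width,))
            glorot(p + "mlp.W2", cfg.mlp_width, d)
            zeros(p + "mlp.b2", (d,))
        ones("ln_f.g", (d,))
        zeros("ln_f.b", (d,))
        dims = (d, *cfg.head_hidden, cfg.num_classes)
        last = len(dims) - 2
        for i, (fi, fo) in enumerate(zip(dims[:-1], dims[1:])):
            if i == last:
                zeros(f"head{i}.W", (fi, fo))  # zero-init classifier: calibrated start
            else:
                glorot(f"head{i}.W", fi, fo)
            zeros(f"head{i}.b", (fo,))

    # -- forward -----------------------------------------------------------

    def embed_patches(self, images: np.ndarray, positional: bool = True) -> np.ndarray:
        """Projected patch tokens (numpy, no grad); used by diagnostics/tests."""
        x = _patchify(np.asarray(images, float), self.cfg.patch_size)
        tok = x @ self.params["patch.W"].data + self.params["patch.b"].data
        if positional:
            start = 1 if self.cfg.aggregation == "cls_token" else 0
            tok = tok + self.params["pos"].data[:, start:start + tok.shape[1]]
        return tok

    def _attention(self, x: Tensor, layer: int, rng) -> Tensor:
        cfg = self.cfg
        p = self.params
        pre = f"enc{layer}.attn."
        b, n, _ = x.shape
        heads, kd = cfg.num_heads, cfg.key_dim

        def split(nm):
            t = x @ p[pre + f"W{nm}"] + p[pre + f"b{nm}"]
            return t.reshape(b, n, heads, kd).transpose((0, 2, 1, 3))

        q, k, v = split("q"), split("k"), split("v")
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(kd))
        attn = scores.softmax().dropout(cfg.attention_dropout, rng)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, n, heads * kd)
        return out @ p[pre + "Wo"] + p[pre + "bo"]

    def forward(self, images: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a batch; pass an rng to enable dropout (training mode)."""
        cfg = self.cfg
        p = self.params
        x_np = _patchify(np.asarray(images, float), cfg.patch_size)
        x = Tensor(x_np) @ p["patch.W"] + p["patch.b"]
        if cfg.aggregation == "cls_token":
            x = Tensor.concat_token(p["cls"], x)
        x = x + p["pos"]
        for layer in range(cfg.depth):
            pre = f"enc{layer}."
            h = x.layer_norm(p[pre + "ln1.g"], p[pre + "ln1.b"])
            x = x + self._attention(h, layer, rng)
            h = x.layer_norm(p[pre + "ln2.g"], p[pre + "ln2.b"])
            h = (h @ p[pre + "mlp.W1"] + p[pre + "mlp.b1"]).gelu()
            h = h.dropout(cfg.mlp_dropout, rng)
            h = h @ p[pre + "mlp.W2"] + p[pre + "mlp.b2"]
            x = x + h.dropout(cfg.mlp_dropout, rng)
        x = x.layer_norm(p["ln_f.g"], p["ln_f.b"])
        pooled = x.take_token(0) if cfg.aggregation == "cls_token" else x.mean_axis(1)
        h = pooled
        n_head_layers = len(cfg.head_hidden) + 1
        for i in range(n_head_layers):
            h = h @ p[f"head{i}.W"] + p[f"head{i}.b"]
            if i < n_head_layers - 1:
                h = h.gelu().dropout(cfg.head_dropout, rng)
        return h

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-class probabilities (rows sum to 1); dropout disabled."""
        outs = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(images[start:start + batch_size]).data
            z = logits - logits.max(axis=-1, keepdims=True)
            e = np.exp(z)
            outs.append(e / e.sum(axis=-1, keepdims=True))
        return np.concatenate(outs, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(cfg: ViTConfig, seed: int = 0) -> ViT:
    return ViT(validate_config(cfg), seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    early_stopping_patience: int = 8
    plateau_factor: float = 0.5
    plateau_patience: int = 4
    min_lr: float = 1e-6
    checkpoint_best: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": np.arange(1, self.epochs_run + 1),
             "train_loss": self.train_loss, "train_acc": self.train_acc,
             "val_loss": self.val_loss, "val_acc": self.val_acc,
             "lr": self.learning_rates}
        )


class _AdamW:
    """Adam with decoupled weight decay on matrix-shaped parameters."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and p.data.ndim >= 2:
                p.data -= self.lr * self.wd * p.data


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def evaluate(model: ViT, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> tuple[float, float]:
    """(mean cross-entropy loss, accuracy) with dropout disabled."""
    proba = model.predict_proba(images, batch_size=batch_size)
    eps = 1e-12
    loss = float(-np.mean(np.log(proba[np.arange(len(labels)), labels] + eps)))
    acc = float(np.mean(proba.argmax(axis=1) == labels))
    return loss, acc


def train(
    model: ViT,
    train_split: tuple[np.ndarray, np.ndarray],
    val_split: tuple[np.ndarray, np.ndarray],
    tcfg: TrainConfig,
) -> TrainingHistory:
    """Mini-batch AdamW training with the three stability callbacks.

    EarlyStopping and ReduceLROnPlateau both watch the validation loss;
    when ``checkpoint_best`` is set the best-validation-loss weights are
    restored at the end.  Seeded and reproducible.
    """
    x_train, y_train = train_split
    x_val, y_val = val_split
    if len(x_train) == 0 or len(x_val) == 0:
        raise HistomagError("empty train or validation split")
    y_train = np.asarray(y_train, int)
    y_val = np.asarray(y_val, int)
    onehot = _one_hot(y_train, model.cfg.num_classes)

    rng = np.random.default_rng(tcfg.seed)
    opt = _AdamW(model.params, tcfg.learning_rate, tcfg.weight_decay)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.state_dict() if tcfg.checkpoint_best else None
    epochs_since_best = 0
    plateau_wait = 0

    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            logits = model.forward(x_train[idx], rng=rng)
            loss = logits.cross_entropy(onehot[idx])
            if not np.isfinite(loss.data):
                raise HistomagError(
                    f"NaN/inf loss at epoch {epoch + 1}; last finite train loss: "
                    f"{losses[-1] if losses else 'none'}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())

        val_loss, val_acc = evaluate(model, x_val, y_val)
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(correct / len(x_train))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.learning_rates.append(opt.lr)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            history.best_epoch = epoch
            epochs_since_best = 0
            plateau_wait = 0
            if tcfg.checkpoint_best:
                best_state = model.state_dict()
        else:
            epochs_since_best += 1
            plateau_wait += 1
            if plateau_wait >= tcfg.plateau_patience:
                opt.lr = max(opt.lr * tcfg.plateau_factor, tcfg.min_lr)
                plateau_wait = 0
            if epochs_since_best >= tcfg.early_stopping_patience:
                history.stopped_early = True
                break

    if tcfg.checkpoint_best and best_state is not None:
        model.load_state_dict(best_state)
    return history
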