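"""1D residual CNN regression backbone, implemented directly on NumPy.

The network maps a preprocessed spectrum (one channel, L wavelengths) to a
scalar density. Architecture: four stages of residual basic blocks (two
blocks per stage, two 3-wide convolutions per block, batch normalisation,
ReLU, identity or 1-wide projection shortcuts), a flatten, four fully
connected layers (512/128/64/32, ReLU) and a linear scalar output. The
first convolution of each stage downsamples with stride 2.

Forward and backward passes, the Adam optimiser, learning-rate reduction
on plateau and early stopping are implemented here explicitly; training is
bit-reproducible for a fixed seed because every source of randomness is a
seeded NumPy generator. Convolution layers can be frozen individually
(their parameters receive no updates), which supports transfer by
fine-tuning: initialise from source-domain weights, freeze the first L
main-path convolutions, and retrain the rest on target-domain spectra.
The flatten-layer activations ("bottleneck features") are exposed for use
as inputs to a downstream kernel regressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResnetConfig",
    "TrainConfig",
    "TrainedBackbone",
    "build_backbone",
    "train",
    "fine_tune",
    "bottleneck_features",
]


# ---------------------------------------------------------------------------
# parameters and primitive layers
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad", "frozen")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.frozen = False


class Conv1d:
    """1-D convolution with 'same' (ceil-mode) padding and stride."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (cin * k))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin * k)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self._cache = None

    def out_len(self, L: int) -> int:
        return -(-L // self.stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        L_out = self.out_len(L)
        pad_total = max((L_out - 1) * self.stride + self.k - L, 0)
        pl = pad_total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pad_total - pl)))
        idx = np.arange(self.k)[:, None] + self.stride * np.arange(L_out)[None, :]
        cols = xp[:, :, idx].reshape(B, C * self.k, L_out)
        y = np.matmul(self.W.value, cols) + self.b.value[:, None]
        self._cache = (cols, L, xp.shape[2], pl, L_out)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, L, Lp, pl, L_out = self._cache
        B = dy.shape[0]
        self.W.grad += np.einsum("bol,bkl->ok", dy, cols)
        self.b.grad += dy.sum(axis=(0, 2))
        dcols = np.einsum("ok,bol->bkl", self.W.value, dy)
        dcols = dcols.reshape(B, self.cin, self.k, L_out)
        dxp = np.zeros((B, self.cin, Lp))
        for ki in range(self.k):
            dxp[:, :, ki + self.stride * np.arange(L_out)] += dcols[:, :, ki, :]
        return dxp[:, :, pl : pl + L]

    def params(self, prefix: str) -> dict[str, Param]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


class BatchNorm1d:
    """Batch normalisation over (batch, length) per channel."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        B, C, L = dy.shape
        N = B * L
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[None, :, None] / N) * (N * dxhat - s1 - xhat * s2)

    def params(self, prefix: str) -> dict[str, Param]:
        return {f"{prefix}.gamma": self.gamma, f"{prefix}.beta": self.beta}

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Linear:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / fin)
        self.W = Param(rng.normal(0.0, scale, size=(fout, fin)))
        self.b = Param(np.zeros(fout))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value

    def params(self, prefix: str) -> dict[str, Param]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


class BasicBlock:
    """Conv-BN-ReLU-Conv-BN plus shortcut, then ReLU."""

    def __init__(self, cin: int, cout: int, stride: int, k: int, rng: np.random.Generator):
        self.conv1 = Conv1d(cin, cout, k, stride, rng)
        self.bn1 = BatchNorm1d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(cout, cout, k, 1, rng)
        self.bn2 = BatchNorm1d(cout)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.proj = Conv1d(cin, cout, 1, stride, rng)
            self.proj_bn = BatchNorm1d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), training))
        out = self.bn2.forward(self.conv2.forward(out), training)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x), training)
        else:
            sc = x
        return self.relu_out.forward(out + sc)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu_out.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dy))))
        )
        if self.proj is not None:
            dsc = self.proj.backward(self.proj_bn.backward(dy))
        else:
            dsc = dy
        return dmain + dsc

    def main_convs(self) -> list[Conv1d]:
        return [self.conv1, self.conv2]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ResnetConfig:
    n_stages: int = 4
    basic_blocks_per_stage: int = 2
    convs_per_basic_block: int = 2
    channels: tuple[int, ...] = (64, 128, 256, 512)
    kernel_size: int = 3
    fc_sizes: tuple[int, ...] = (512, 128, 64, 32)
    downsample_stride_per_stage: tuple[int, ...] = (2, 2, 2, 2)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.fc_sizes = tuple(self.fc_sizes)
        self.downsample_stride_per_stage = tuple(self.downsample_stride_per_stage)
        if len(self.channels) != self.n_stages:
            raise ValueError("channels length must equal n_stages")
        if len(self.downsample_stride_per_stage) != self.n_stages:
            raise ValueError("stride list length must equal n_stages")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.convs_per_basic_block != 2:
            raise ValueError("basic blocks use exactly 2 convolutions")

    @property
    def n_conv_layers(self) -> int:
        """Main-path convolutions (projection shortcuts not counted)."""
        return self.n_stages * self.basic_blocks_per_stage * self.convs_per_basic_block

    def to_dict(self) -> dict:
        return {
            "n_stages": self.n_stages,
            "basic_blocks_per_stage": self.basic_blocks_per_stage,
            "convs_per_basic_block": self.convs_per_basic_block,
            "channels": list(self.channels),
            "kernel_size": self.kernel_size,
            "fc_sizes": list(self.fc_sizes),
            "downsample_stride_per_stage": list(self.downsample_stride_per_stage),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResnetConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    batch_size: int = 5
    initial_lr: float = 1e-3
    lr_reduce_factor: float = 0.5
    lr_patience: int = 10
    early_stop_patience: int = 30
    max_epochs: int = 500
    seed: int = 0
    normalize_y: bool = True
    val_fraction: float = 0.0  # 0 -> monitor training loss
    min_delta: float = 1e-6

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_reduce_factor < 1:
            raise ValueError("lr_reduce_factor must be in (0, 1)")


# ---------------------------------------------------------------------------
# the backbone
# ---------------------------------------------------------------------------


class TrainedBackbone:
    """The assembled network plus optimisation/bookkeeping state."""

    def __init__(self, input_len: int, config: ResnetConfig, seed: int = 0):
        stride_prod = int(np.prod(config.downsample_stride_per_stage))
        if input_len < stride_prod:
            raise ValueError(
                f"input_len={input_len} shorter than total downsampling {stride_prod}"
            )
        self.input_len = input_len
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[BasicBlock] = []
        cin = 1
        L = input_len
        for s in range(config.n_stages):
            cout = config.channels[s]
            for b in range(config.basic_blocks_per_stage):
                stride = config.downsample_stride_per_stage[s] if b == 0 else 1
                blk = BasicBlock(cin, cout, stride, config.kernel_size, rng)
                self.blocks.append(blk)
                L = -(-L // stride)
                cin = cout
        self.flatten_dim = cin * L
        self.fc: list[Linear] = []
        self.fc_relu: list[ReLU] = []
        fin = self.flatten_dim
        for size in config.fc_sizes:
            self.fc.append(Linear(fin, size, rng))
            self.fc_relu.append(ReLU())
            fin = size
        self.out = Linear(fin, 1, rng)
        self.training_history: list[float] = []
        self.y_mean = 0.0
        self.y_std = 1.0
        self._flat_shape = None

    # -- structure ---------------------------------------------------------

    @property
    def conv_layers(self) -> list[Conv1d]:
        """Main-path convolutions in forward order."""
        out = []
        for blk in self.blocks:
            out.extend(blk.main_convs())
        return out

    @property
    def freeze_mask(self) -> list[bool]:
        return [c.W.frozen for c in self.conv_layers]

    def set_frozen_convs(self, n_frozen: int) -> None:
        """Freeze the first ``n_frozen`` main-path convolutions.

        A projection-shortcut convolution is frozen exactly when both
        main-path convolutions of its block are frozen.
        """
        convs = self.conv_layers
        if not 0 <= n_frozen <= len(convs):
            raise ValueError(f"n_frozen must be in [0, {len(convs)}]")
        for i, c in enumerate(convs):
            for p in (c.W, c.b):
                p.frozen = i < n_frozen
        i = 0
        for blk in self.blocks:
            frozen_block = all(c.W.frozen for c in blk.main_convs())
            if blk.proj is not None:
                for p in (blk.proj.W, blk.proj.b):
                    p.frozen = frozen_block
            i += 2

    def named_params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for bi, blk in enumerate(self.blocks):
            out.update(blk.conv1.params(f"b{bi}.conv1"))
            out.update(blk.bn1.params(f"b{bi}.bn1"))
            out.update(blk.conv2.params(f"b{bi}.conv2"))
            out.update(blk.bn2.params(f"b{bi}.bn2"))
            if blk.proj is not None:
                out.update(blk.proj.params(f"b{bi}.proj"))
                out.update(blk.proj_bn.params(f"b{bi}.proj_bn"))
        for fi, lin in enumerate(self.fc):
            out.update(lin.params(f"fc{fi}"))
        out.update(self.out.params("out"))
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        """All parameters plus BN running statistics, copied."""
        w = {k: p.value.copy() for k, p in self.named_params().items()}
        for bi, blk in enumerate(self.blocks):
            for name, bn in (("bn1", blk.bn1), ("bn2", blk.bn2), ("proj_bn", blk.proj_bn)):
                if bn is None:
                    continue
                for sk, sv in bn.state().items():
                    w[f"b{bi}.{name}.{sk}"] = sv.copy()
        w["__y_mean__"] = np.array(self.y_mean)
        w["__y_std__"] = np.array(self.y_std)
        return w

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        bad = []
        for k, p in params.items():
            if k not in weights:
                bad.append(k)
            elif weights[k].shape != p.value.shape:
                bad.append(f"{k} (shape {weights[k].shape} vs {p.value.shape})")
        if bad:
            raise ValueError(f"weight mismatch for layers: {bad}")
        for k, p in params.items():
            p.value = weights[k].copy()
            p.grad = np.zeros_like(p.value)
        for bi, blk in enumerate(self.blocks):
            for name, bn in (("bn1", blk.bn1), ("bn2", blk.bn2), ("proj_bn", blk.proj_bn)):
                if bn is None:
                    continue
                bn.running_mean = weights[f"b{bi}.{name}.running_mean"].copy()
                bn.running_var = weights[f"b{bi}.{name}.running_var"].copy()
        if "__y_mean__" in weights:
            self.y_mean = float(weights["__y_mean__"])
            self.y_std = float(weights["__y_std__"])

    # -- forward / backward ------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.shape[2] != self.input_len:
            raise ValueError(
                f"expected input length {self.input_len}, got {X.shape[2]}"
            )
        return X

    def forward_features(self, X: np.ndarray, training: bool) -> np.ndarray:
        h = self._check_input(X)
        for blk in self.blocks:
            h = blk.forward(h, training)
        self._flat_shape = h.shape
        return h.reshape(h.shape[0], -1)

    def forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        h = self.forward_features(X, training)
        for lin, act in zip(self.fc, self.fc_relu):
            h = act.forward(lin.forward(h))
        return self.out.forward(h).ravel()

    def backward(self, dpred: np.ndarray) -> None:
        dh = self.out.backward(dpred[:, None])
        for lin, act in zip(reversed(self.fc), reversed(self.fc_relu)):
            dh = lin.backward(act.backward(dh))
        dh = dh.reshape(self._flat_shape)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)

    def zero_grad(self) -> None:
        for p in self.named_params().values():
            p.grad[...] = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode scalar predictions on the label scale."""
        return self.forward(X, training=False) * self.y_std + self.y_mean

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.get_weights())
        sidecar = {"input_len": self.input_len, "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "TrainedBackbone":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(sidecar["input_len"], ResnetConfig.from_dict(sidecar["config"]))
        with np.load(path.with_suffix(".npz")) as data:
            model.set_weights({k: data[k] for k in data.files})
        return model


def build_backbone(input_len: int, config: ResnetConfig | None = None, seed: int = 0) -> TrainedBackbone:
    """Construct an untrained backbone with seeded He initialisation."""
    return TrainedBackbone(input_len, config or ResnetConfig(), seed=seed)


# ---------------------------------------------------------------------------
# optimiser and training loop
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: dict[str, Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, p in self.params.items():
            if p.frozen:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p.value -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def train(model: TrainedBackbone, X: np.ndarray, y: np.ndarray, tc: TrainConfig) -> TrainedBackbone:
    """Minimise MSE with Adam; LR reduction on plateau and early stopping.

    The monitored signal is the epoch-mean training loss (or held-out loss
    when ``val_fraction`` > 0). Training mutates and returns ``model``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rng = np.random.default_rng(tc.seed)

    if tc.normalize_y:
        model.y_mean = float(y.mean())
        model.y_std = float(y.std()) or 1.0
    else:
        model.y_mean, model.y_std = 0.0, 1.0
    yn = (y - model.y_mean) / model.y_std

    if tc.val_fraction > 0:
        n_val = max(1, int(round(tc.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, tr_idx = None, np.arange(n)

    opt = Adam(model.named_params(), tc.initial_lr)
    best = np.inf
    lr_wait = 0
    stop_wait = 0
    for _epoch in range(tc.max_epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, len(order), tc.batch_size):
            bidx = order[start : start + tc.batch_size]
            pred = model.forward(X[bidx], training=True)
            resid = pred - yn[bidx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}: {loss}; "
                    "reduce the learning rate or check the input scaling"
                )
            model.zero_grad()
            model.backward(2.0 * resid / len(bidx))
            opt.step()
            losses.append(loss)
        if val_idx is not None:
            vp = model.forward(X[val_idx], training=False)
            monitored = float(np.mean((vp - yn[val_idx]) ** 2))
        else:
            monitored = float(np.mean(losses))
        model.training_history.append(monitored)

        if monitored < best - tc.min_delta:
            best = monitored
            lr_wait = 0
            stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait >= tc.lr_patience:
                opt.lr = max(opt.lr * tc.lr_reduce_factor, 1e-7)
                lr_wait = 0
            if stop_wait >= tc.early_stop_patience:
                break
    return model


def fine_tune(
    model: TrainedBackbone,
    source_weights: dict[str, np.ndarray],
    n_frozen_conv: int,
    X: np.ndarray,
    y: np.ndarray,
    tc: TrainConfig,
) -> TrainedBackbone:
    """Warm-start from source weights, freeze the first L convolutions, retrain.

    ``n_frozen_conv`` counts main-path convolutions in forward order;
    projection shortcuts follow their block's status.
    """
    model.set_weights(source_weights)
    model.set_frozen_convs(n_frozen_conv)
    return train(model, X, y, tc)


def bottleneck_features(model: TrainedBackbone, spectra: np.ndarray) -> np.ndarray:
    """Flatten-layer activations in inference mode (deterministic)."""
    return model.forward_features(spectra, training=False)
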