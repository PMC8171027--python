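"""The two-branch classifier network and its shape chain.

The sequence branch treats the 150 x 4 one-hot map as a 1-D signal of length
150 with 4 input channels: conv(k=4, s=1) -> 2 channels -> ReLU ->
conv(k=4, s=1) -> 4 channels -> ReLU -> dropout -> max-pool(k=2, s=2),
leaving a dense 4 x 72 feature map.  Its 288 values are concatenated with the
43 tabular features and passed through fully-connected layers of sizes 40
(batch-norm + ReLU + dropout), 10 (batch-norm + ReLU) and 2, a final ReLU,
and a softmax over the two class units.

The implementation is a small, self-contained numpy network (float64, seeded,
hand-written backward passes): the architecture is tiny and CPU-bound, and an
explicit implementation keeps every training run bit-reproducible, which the
semi-supervised-versus-supervised comparisons rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-5          # batch-norm variance floor
_BN_MOMENTUM = 0.1   # running-statistics update rate


class ConfigurationError(ValueError):
    """A ModelConfig that cannot produce a valid layer geometry."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters fixing the network geometry.

    The defaults give the reference geometry: conv output channels (2, 4),
    kernel length 4 at stride 1 twice, pool 2/2, so the pooled sequence map is
    4 channels x 72 positions and the first FC layer sees 288 + 43 = 331
    inputs.
    """

    conv_channels: tuple[int, int] = (2, 4)
    conv_kernel_lengths: tuple[int, int] = (4, 4)
    conv_strides: tuple[int, int] = (1, 1)
    pool_kernel: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, int, int] = (40, 10, 2)
    dropout_conv: float = 0.5
    dropout_fc1: float = 0.5
    tabular_dim: int = 43
    seq_shape: tuple[int, int] = (150, 4)
    seed: int = 0

    @classmethod
    def literal_text_geometry(cls, **kw) -> "ModelConfig":
        """Alternative preset reading the conv filters as length-axis kernels
        1 and 2 with the stride 2 on the second convolution.

        Its chain is 150 -> 150 -> 75 -> pooled 37, i.e. it does *not* end in
        the 72-position pooled map of the reference geometry; it is kept only
        so both readings of the filter sizes are available.
        """
        return cls(conv_kernel_lengths=(1, 2), conv_strides=(1, 2), **kw)

    def __post_init__(self) -> None:
        if self.fc_sizes[-1] != 2:
            raise ConfigurationError("final layer must have exactly 2 units")
        if not (0 <= self.dropout_conv < 1 and 0 <= self.dropout_fc1 < 1):
            raise ConfigurationError("dropout rates must be in [0, 1)")


def _conv_len(length: int, kernel: int, stride: int) -> int:
    if kernel > length:
        raise ConfigurationError(f"kernel {kernel} exceeds input length {length}")
    out = (length - kernel) // stride + 1
    if out <= 0:
        raise ConfigurationError(f"non-positive output length {out}")
    return out


def shape_chain(config: ModelConfig) -> list:
    """Per-layer output shapes from the one-hot input to the 2-unit output.

    Returns ``[(C_in, L), (C1, L1), (C2, L2), (C2, L_pool), flat,
    flat + tabular_dim, fc1, fc2, 2]`` where every length follows
    ``floor((L - k) / s) + 1``.
    """
    length, width = config.seq_shape
    chain: list = [(width, length)]
    l = length
    for ch, k, s in zip(config.conv_channels, config.conv_kernel_lengths, config.conv_strides):
        l = _conv_len(l, k, s)
        chain.append((ch, l))
    l = _conv_len(l, config.pool_kernel, config.pool_stride)
    chain.append((config.conv_channels[-1], l))
    flat = config.conv_channels[-1] * l
    chain += [flat, flat + config.tabular_dim, *config.fc_sizes]
    return chain


def _im2col(x: np.ndarray, k: int, s: int) -> np.ndarray:
    # x: (N, C, L) -> (N, L_out, C*k)
    win = sliding_window_view(x, k, axis=2)[:, :, ::s, :]  # (N, C, L_out, k)
    n, c, l_out, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(n, l_out, c * k)


def _col2im(dcol: np.ndarray, in_shape: tuple, k: int, s: int) -> np.ndarray:
    n, c, length = in_shape
    l_out = dcol.shape[1]
    dx = np.zeros((n, c, length))
    dw = dcol.reshape(n, l_out, c, k).transpose(0, 2, 1, 3)  # (N, C, L_out, k)
    for i in range(k):
        dx[:, :, i: i + s * l_out: s] += dw[:, :, :, i]
    return dx


class Network:
    """The classifier f_theta with explicit forward/backward passes.

    Parameters are float64 numpy arrays initialised from a seeded generator
    with the conventional uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) scheme.
    ``forward`` in evaluation mode is deterministic (dropout off, batch-norm
    on running statistics); training mode draws dropout masks from the caller-
    supplied generator so the whole training loop owns one random stream.
    """

    def __init__(self, config: Optional[ModelConfig] = None):
        self.config = config or ModelConfig()
        self.chain = shape_chain(self.config)  # validates geometry
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        def uniform(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        c_in = cfg.seq_shape[1]
        c1, c2 = cfg.conv_channels
        k1, k2 = cfg.conv_kernel_lengths
        flat = self.chain[3][0] * self.chain[3][1]
        f1, f2, f3 = cfg.fc_sizes
        p: dict[str, np.ndarray] = {}
        p["conv1_W"] = uniform((c1, c_in * k1), c_in * k1)
        p["conv1_b"] = uniform((c1,), c_in * k1)
        p["conv2_W"] = uniform((c2, c1 * k2), c1 * k2)
        p["conv2_b"] = uniform((c2,), c1 * k2)
        p["fc1_W"] = uniform((f1, flat + cfg.tabular_dim), flat + cfg.tabular_dim)
        p["fc1_b"] = uniform((f1,), flat + cfg.tabular_dim)
        p["bn1_gamma"] = np.ones(f1)
        p["bn1_beta"] = np.zeros(f1)
        p["fc2_W"] = uniform((f2, f1), f1)
        p["fc2_b"] = uniform((f2,), f1)
        p["bn2_gamma"] = np.ones(f2)
        p["bn2_beta"] = np.zeros(f2)
        p["fc3_W"] = uniform((f3, f2), f2)
        p["fc3_b"] = uniform((f3,), f2)
        self.params = p
        self.running = {
            "bn1_mean": np.zeros(f1), "bn1_var": np.ones(f1),
            "bn2_mean": np.zeros(f2), "bn2_var": np.ones(f2),
        }

    # ------------------------------------------------------------------ forward

    def forward(
        self,
        onehot: np.ndarray,
        tabular: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[np.ndarray, dict]:
        """Class probabilities (N, 2) and the cache needed for ``backward``."""
        cfg = self.config
        if onehot.ndim != 3 or onehot.shape[1:] != cfg.seq_shape:
            raise ValueError(f"onehot shape {onehot.shape} != (N, {cfg.seq_shape})")
        if tabular.shape != (onehot.shape[0], cfg.tabular_dim):
            raise ValueError(
                f"tabular shape {tabular.shape} != (N, {cfg.tabular_dim})"
            )
        if training and rng is None:
            raise ValueError("training-mode forward needs a random generator")
        p = self.params
        cache: dict = {"training": training}
        x = np.ascontiguousarray(onehot.transpose(0, 2, 1))  # (N, 4, 150)
        cache["x_shape"] = x.shape

        # conv1 + ReLU
        col1 = _im2col(x, cfg.conv_kernel_lengths[0], cfg.conv_strides[0])
        z1 = col1 @ p["conv1_W"].T + p["conv1_b"]             # (N, L1, C1)
        a1 = np.maximum(z1, 0.0)
        cache.update(col1=col1, z1=z1)

        # conv2 + ReLU
        a1c = np.ascontiguousarray(a1.transpose(0, 2, 1))     # (N, C1, L1)
        cache["a1_shape"] = a1c.shape
        col2 = _im2col(a1c, cfg.conv_kernel_lengths[1], cfg.conv_strides[1])
        z2 = col2 @ p["conv2_W"].T + p["conv2_b"]             # (N, L2, C2)
        a2 = np.maximum(z2, 0.0)
        cache.update(col2=col2, z2=z2)

        # dropout on the conv feature map
        a2c = np.ascontiguousarray(a2.transpose(0, 2, 1))     # (N, C2, L2)
        a2c, cache["drop_conv"] = self._dropout(a2c, cfg.dropout_conv, training, rng)

        # max-pool
        pw = sliding_window_view(a2c, cfg.pool_kernel, axis=2)[:, :, ::cfg.pool_stride, :]
        pool_idx = pw.argmax(axis=3)
        pooled = pw.max(axis=3)                               # (N, C2, Lp)
        cache.update(pool_idx=pool_idx, pool_in_shape=a2c.shape)

        # flatten + concatenate tabular features
        flat = pooled.reshape(len(pooled), -1)
        h = np.concatenate([flat, tabular], axis=1)           # (N, 331)
        cache["h"] = h

        # FC1 -> batch-norm -> ReLU -> dropout
        z3 = h @ p["fc1_W"].T + p["fc1_b"]
        b3, bn1 = self._batchnorm(z3, "bn1", training)
        a3 = np.maximum(b3, 0.0)
        a3, cache["drop_fc1"] = self._dropout(a3, cfg.dropout_fc1, training, rng)
        cache.update(bn1=bn1, b3=b3, a3=a3)

        # FC2 -> batch-norm -> ReLU
        z4 = a3 @ p["fc2_W"].T + p["fc2_b"]
        b4, bn2 = self._batchnorm(z4, "bn2", training)
        a4 = np.maximum(b4, 0.0)
        cache.update(bn2=bn2, b4=b4, a4=a4)

        # FC3 -> ReLU -> softmax
        z5 = a4 @ p["fc3_W"].T + p["fc3_b"]
        a5 = np.maximum(z5, 0.0)
        e = np.exp(a5 - a5.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        cache.update(z5=z5, probs=probs)
        return probs, cache

    @staticmethod
    def _dropout(x, rate, training, rng):
        if not training or rate == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * mask, mask

    def _batchnorm(self, x, name, training):
        gamma, beta = self.params[f"{name}_gamma"], self.params[f"{name}_beta"]
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running[f"{name}_mean"] *= 1.0 - _BN_MOMENTUM
            self.running[f"{name}_mean"] += _BN_MOMENTUM * mu
            self.running[f"{name}_var"] *= 1.0 - _BN_MOMENTUM
            self.running[f"{name}_var"] += _BN_MOMENTUM * var
        else:
            mu = self.running[f"{name}_mean"]
            var = self.running[f"{name}_var"]
        inv_std = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * inv_std
        return gamma * xhat + beta, {"xhat": xhat, "inv_std": inv_std}

    # ----------------------------------------------------------------- backward

    def loss_and_grads(
        self,
        onehot: np.ndarray,
        tabular: np.ndarray,
        targets: np.ndarray,
        training: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
        """Mean cross-entropy of a batch and its parameter gradients.

        Returns ``(loss, grads, probs)``; ``grads`` has one entry per entry of
        ``self.params``.
        """
        probs, cache = self.forward(onehot, tabular, training=training, rng=rng)
        n = len(targets)
        loss = float(-np.log(np.clip(probs[np.arange(n), targets], 1e-12, None)).mean())
        grads = self._backward(cache, tabular, targets)
        return loss, grads, probs

    def _backward(self, cache, tabular, targets):
        cfg, p = self.config, self.params
        n = len(targets)
        g: dict[str, np.ndarray] = {}

        onehot_t = np.zeros_like(cache["probs"])
        onehot_t[np.arange(n), targets] = 1.0
        da5 = (cache["probs"] - onehot_t) / n
        dz5 = da5 * (cache["z5"] > 0)

        g["fc3_W"] = dz5.T @ cache["a4"]
        g["fc3_b"] = dz5.sum(axis=0)
        da4 = dz5 @ p["fc3_W"]
        db4 = da4 * (cache["b4"] > 0)
        dz4 = self._bn_backward(db4, "bn2", cache["bn2"], g, cache["training"])

        g["fc2_W"] = dz4.T @ cache["a3"]
        g["fc2_b"] = dz4.sum(axis=0)
        da3 = dz4 @ p["fc2_W"]
        if cache["drop_fc1"] is not None:
            da3 = da3 * cache["drop_fc1"]
        db3 = da3 * (cache["b3"] > 0)
        dz3 = self._bn_backward(db3, "bn1", cache["bn1"], g, cache["training"])

        g["fc1_W"] = dz3.T @ cache["h"]
        g["fc1_b"] = dz3.sum(axis=0)
        dh = dz3 @ p["fc1_W"]

        flat_dim = self.chain[3][0] * self.chain[3][1]
        dpooled = dh[:, :flat_dim].reshape(n, *self.chain[3])

        # un-pool: route gradient to each window's argmax position
        da2c = np.zeros(cache["pool_in_shape"])
        idx = cache["pool_idx"]                                # (N, C, Lp)
        n_, c_, lp = idx.shape
        pos = np.arange(lp) * cfg.pool_stride + idx            # absolute positions
        ni = np.repeat(np.arange(n_), c_ * lp)
        ci = np.tile(np.repeat(np.arange(c_), lp), n_)
        np.add.at(da2c, (ni, ci, pos.ravel()), dpooled.ravel())

        if cache["drop_conv"] is not None:
            da2c = da2c * cache["drop_conv"]
        da2 = da2c.transpose(0, 2, 1)                          # (N, L2, C2)
        dz2 = da2 * (cache["z2"] > 0)

        g["conv2_W"] = np.einsum("nlo,nlk->ok", dz2, cache["col2"])
        g["conv2_b"] = dz2.sum(axis=(0, 1))
        dcol2 = dz2 @ p["conv2_W"]
        da1c = _col2im(dcol2, cache["a1_shape"],
                       cfg.conv_kernel_lengths[1], cfg.conv_strides[1])
        dz1 = da1c.transpose(0, 2, 1) * (cache["z1"] > 0)

        g["conv1_W"] = np.einsum("nlo,nlk->ok", dz1, cache["col1"])
        g["conv1_b"] = dz1.sum(axis=(0, 1))
        return g

    def _bn_backward(self, dy, name, bn_cache, grads, training):
        gamma = self.params[f"{name}_gamma"]
        xhat, inv_std = bn_cache["xhat"], bn_cache["inv_std"]
        grads[f"{name}_gamma"] = (dy * xhat).sum(axis=0)
        grads[f"{name}_beta"] = dy.sum(axis=0)
        dxhat = dy * gamma
        if not training:
            return dxhat * inv_std
        n = len(dy)
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    # ------------------------------------------------------------------- update

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        for name, grad in grads.items():
            self.params[name] -= lr * grad

    def predict_proba(self, onehot, tabular, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode probabilities, batched; deterministic."""
        out = np.empty((len(onehot), 2))
        for i in range(0, len(onehot), batch_size):
            out[i:i + batch_size] = self.forward(
                onehot[i:i + batch_size], tabular[i:i + batch_size]
            )[0]
        return out

    # -------------------------------------------------------------- persistence

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {**{f"param_{k}": v for k, v in self.params.items()},
                **{f"running_{k}": v for k, v in self.running.items()}}

    def save(self, path, extra: Optional[dict] = None) -> None:
        """Checkpoint: parameters, running stats, config and any extra JSON blob."""
        meta = {"config": asdict(self.config), "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state_arrays())

    @classmethod
    def load(cls, path) -> tuple["Network", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            for key in ("conv_channels", "conv_kernel_lengths", "conv_strides",
                        "fc_sizes", "seq_shape"):
                cfg_d[key] = tuple(cfg_d[key])
            net = cls(ModelConfig(**cfg_d))
            for k in net.params:
                net.params[k] = data[f"param_{k}"]
            for k in net.running:
                net.running[k] = data[f"running_{k}"]
        return net, meta["extra"]
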