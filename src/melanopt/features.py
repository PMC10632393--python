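"""CNN feature extractor for lesion ROIs, implemented in numpy.

Architecture: two convolution blocks (conv -> ReLU -> 2x2 max-pool) followed
by three fully connected layers that funnel the flattened activations down
to a 100-dimensional embedding. The default profile matches the full design
(150x150 input, 64 filters of 7x7 then 64 of 5x5, FC sizes 500/250/100);
``CNNConfig.reduced()`` gives a 64x64 / 16-filter profile sized for CPU
runs. Training attaches a temporary 2-class softmax head minimized with
cross-entropy (Adam); feature extraction afterwards reads the third fully
connected layer with the head removed.

All convolution arithmetic is im2col + BLAS matmul in float32; convolutions
use "same" zero padding with odd kernels, so spatial size is preserved and
each pool halves it (floor). Everything is deterministic given the config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CNNConfig",
    "FeatureExtractor",
    "build_feature_extractor",
    "train_feature_extractor",
    "extract_features",
    "output_shapes",
]


@dataclass(frozen=True)
class CNNConfig:
    input_side: int = 150
    in_channels: int = 3
    conv1_filters: int = 64
    conv1_size: int = 7
    conv2_filters: int = 64
    conv2_size: int = 5
    fc_sizes: tuple = (500, 250, 100)
    pool_size: int = 2
    pool_stride: int = 2
    padding: str = "same"
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(b >= a for a, b in zip(self.fc_sizes, self.fc_sizes[1:])) or len(
            self.fc_sizes
        ) != 3:
            raise ValueError("fc_sizes must be three strictly decreasing sizes")
        if max(self.conv1_filters, self.conv2_filters) > 64:
            raise ValueError("more than 64 filters per layer overfits; refusing")
        if self.conv1_size % 2 == 0 or self.conv2_size % 2 == 0:
            raise ValueError("'same' padding requires odd kernel sizes")
        if self.padding != "same":
            raise ValueError("only 'same' padding is implemented")
        if self.pool_size != 2 or self.pool_stride != 2:
            raise ValueError("pooling is fixed at 2x2, stride 2")
        if self.input_side // 4 < 1:
            raise ValueError("input too small for two pooling stages")

    @classmethod
    def reduced(cls, **overrides) -> "CNNConfig":
        """CPU-scale profile: 64x64 input, 16 filters, 256/128/100 FCs."""
        base = dict(
            input_side=64,
            conv1_filters=16,
            conv2_filters=16,
            fc_sizes=(256, 128, 100),
            epochs=25,
            weight_decay=1e-3,
        )
        base.update(overrides)
        return cls(**base)


def output_shapes(config: CNNConfig) -> dict:
    """Closed-form layer output shapes (H, W, C) for the configured chain."""
    s = config.input_side
    shapes = {"input": (s, s, config.in_channels)}
    shapes["conv1"] = (s, s, config.conv1_filters)
    s1 = s // 2
    shapes["pool1"] = (s1, s1, config.conv1_filters)
    shapes["conv2"] = (s1, s1, config.conv2_filters)
    s2 = s1 // 2
    shapes["pool2"] = (s2, s2, config.conv2_filters)
    shapes["flatten"] = (s2 * s2 * config.conv2_filters,)
    for i, n in enumerate(config.fc_sizes, start=1):
        shapes[f"fc{i}"] = (n,)
    return shapes


# ---------------------------------------------------------------- layers --

def _conv_forward(x, w, b):
    """Same-padding stride-1 convolution. x: (N,H,W,Cin), w: (Cout,Cin,k,k)."""
    k = w.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,Cin,k,k)
    n, h, wd = cols.shape[:3]
    cols = np.ascontiguousarray(cols).reshape(n * h * wd, -1)
    wm = w.reshape(w.shape[0], -1)
    out = cols @ wm.T + b
    return out.reshape(n, h, wd, -1), cols


def _conv_backward(dout, cols, w, x_shape):
    n, h, wd, cout = dout.shape
    dflat = dout.reshape(-1, cout)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    # dx = same-padding convolution of dout with the flipped, transposed kernel
    w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = _conv_forward(dout, w_t, np.zeros(w_t.shape[0], dtype=w.dtype))
    return dx, dw, db


def _pool_forward(x):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2, :]
    x4 = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
        n, h2, w2, c, 4
    )
    idx = np.argmax(x4, axis=-1)
    out = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout, cache):
    idx, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dx4 = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dx4, idx[..., None], dout[..., None], axis=-1)
    dxc = dx4.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
        n, h2 * 2, w2 * 2, c
    )
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : h2 * 2, : w2 * 2, :] = dxc
    return dx


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ----------------------------------------------------------------- model --

class FeatureExtractor:
    """Parameter container + forward/backward passes for the Fig-style CNN."""

    def __init__(self, config: CNNConfig):
        self.config = config
        self.trained = False
        rng = np.random.default_rng(config.seed)
        shapes = output_shapes(config)
        flat = shapes["flatten"][0]
        f1, f2, f3 = config.fc_sizes

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
                np.float32
            )

        c = config
        self.params = {
            "conv1_w": he((c.conv1_filters, c.in_channels, c.conv1_size, c.conv1_size),
                          c.in_channels * c.conv1_size**2),
            "conv1_b": np.zeros(c.conv1_filters, dtype=np.float32),
            "conv2_w": he((c.conv2_filters, c.conv1_filters, c.conv2_size, c.conv2_size),
                          c.conv1_filters * c.conv2_size**2),
            "conv2_b": np.zeros(c.conv2_filters, dtype=np.float32),
            "fc1_w": he((f1, flat), flat),
            "fc1_b": np.zeros(f1, dtype=np.float32),
            "fc2_w": he((f2, f1), f1),
            "fc2_b": np.zeros(f2, dtype=np.float32),
            "fc3_w": he((f3, f2), f2),
            "fc3_b": np.zeros(f3, dtype=np.float32),
            # temporary classification head; removed for feature extraction
            "head_w": (0.01 * rng.normal(size=(2, f3))).astype(np.float32),
            "head_b": np.zeros(2, dtype=np.float32),
        }

    # -- forward ----------------------------------------------------------
    def _forward(self, x, with_cache=False):
        p = self.params
        cache = {}
        a1, cols1 = _conv_forward(x, p["conv1_w"], p["conv1_b"])
        r1 = np.maximum(a1, 0)
        p1, pc1 = _pool_forward(r1)
        a2, cols2 = _conv_forward(p1, p["conv2_w"], p["conv2_b"])
        r2 = np.maximum(a2, 0)
        p2, pc2 = _pool_forward(r2)
        flat = p2.reshape(x.shape[0], -1)
        z1 = flat @ p["fc1_w"].T + p["fc1_b"]
        h1 = np.maximum(z1, 0)
        z2 = h1 @ p["fc2_w"].T + p["fc2_b"]
        h2 = np.maximum(z2, 0)
        feats = h2 @ p["fc3_w"].T + p["fc3_b"]  # linear embedding layer
        if with_cache:
            cache = dict(x=x, a1=a1, cols1=cols1, pc1=pc1, p1=p1, a2=a2,
                         cols2=cols2, pc2=pc2, p2_shape=p2.shape, flat=flat,
                         z1=z1, h1=h1, z2=z2, h2=h2)
        return feats, cache

    def features(self, x) -> np.ndarray:
        feats, _ = self._forward(np.asarray(x, dtype=np.float32))
        return feats

    def logits(self, feats) -> np.ndarray:
        p = self.params
        return feats @ p["head_w"].T + p["head_b"]

    # -- backward ---------------------------------------------------------
    def _backward(self, dfeats, cache):
        p = self.params
        g = {}
        g["fc3_w"] = dfeats.T @ cache["h2"]
        g["fc3_b"] = dfeats.sum(axis=0)
        dh2 = dfeats @ p["fc3_w"]
        dz2 = dh2 * (cache["z2"] > 0)
        g["fc2_w"] = dz2.T @ cache["h1"]
        g["fc2_b"] = dz2.sum(axis=0)
        dh1 = dz2 @ p["fc2_w"]
        dz1 = dh1 * (cache["z1"] > 0)
        g["fc1_w"] = dz1.T @ cache["flat"]
        g["fc1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ p["fc1_w"]
        dp2 = dflat.reshape(cache["p2_shape"])
        dr2 = _pool_backward(dp2, cache["pc2"])
        da2 = dr2 * (cache["a2"] > 0)
        dp1, g["conv2_w"], g["conv2_b"] = _conv_backward(
            da2, cache["cols2"], p["conv2_w"], cache["p1"].shape
        )
        dr1 = _pool_backward(dp1, cache["pc1"])
        da1 = dr1 * (cache["a1"] > 0)
        _, g["conv1_w"], g["conv1_b"] = _conv_backward(
            da1, cache["cols1"], p["conv1_w"], cache["x"].shape
        )
        return g


    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint (npz) of config fields and parameters."""
        from dataclasses import asdict

        meta = asdict(self.config)
        meta["fc_sizes"] = list(meta["fc_sizes"])
        np.savez(path, __meta__=np.array([repr(meta)]),
                 __trained__=np.array([self.trained]), **self.params)

    @classmethod
    def load(cls, path) -> "FeatureExtractor":
        import ast

        data = np.load(path, allow_pickle=False)
        meta = ast.literal_eval(str(data["__meta__"][0]))
        meta["fc_sizes"] = tuple(meta["fc_sizes"])
        model = cls(CNNConfig(**meta))
        for k in model.params:
            model.params[k] = data[k]
        model.trained = bool(data["__trained__"][0])
        return model


def build_feature_extractor(config: CNNConfig | None = None) -> FeatureExtractor:
    """Instantiate the CNN with seeded initial parameters (untrained)."""
    if config is None:
        config = CNNConfig()
    return FeatureExtractor(config)


def train_feature_extractor(model: FeatureExtractor, images, labels,
                            epochs: int | None = None):
    """Fit the temporary softmax head with cross-entropy + Adam.

    ``images``: (N, side, side, 3) float array in [0, 1]; ``labels``: (N,)
    ints in {0, 1}, both classes present (>= 2 samples each). Returns
    (model, history) where history has one dict per epoch with the mean
    minibatch cross-entropy and training accuracy of that epoch.
    """
    x = np.asarray(images, dtype=np.float32)
    y = np.asarray(labels, dtype=int)
    cfg = model.config
    if x.ndim != 4 or x.shape[1] != cfg.input_side or x.shape[2] != cfg.input_side:
        raise ValueError(f"expected images of shape (N, {cfg.input_side}, "
                         f"{cfg.input_side}, {cfg.in_channels})")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    n_epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed + 1)
    lr = cfg.learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    history = []
    for _ in range(n_epochs):
        order = rng.permutation(x.shape[0])
        losses, hits, seen = [], 0, 0
        for start in range(0, x.shape[0], cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            feats, cache = model._forward(xb, with_cache=True)
            logits = model.logits(feats)
            probs = _softmax(logits)
            batch = xb.shape[0]
            loss = -np.mean(np.log(probs[np.arange(batch), yb] + 1e-12))
            losses.append(float(loss))
            hits += int(np.sum(np.argmax(probs, axis=1) == yb))
            seen += batch
            dlogits = probs.copy()
            dlogits[np.arange(batch), yb] -= 1.0
            dlogits /= batch
            grads = {
                "head_w": dlogits.T @ feats,
                "head_b": dlogits.sum(axis=0),
            }
            dfeats = dlogits @ model.params["head_w"]
            grads.update(model._backward(dfeats.astype(np.float32), cache))
            step += 1
            for k, gk in grads.items():
                gk = gk.astype(np.float32)
                if cfg.weight_decay and k.endswith("_w"):
                    gk = gk + np.float32(cfg.weight_decay) * model.params[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gk
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gk**2
                mhat = m_state[k] / (1 - beta1**step)
                vhat = v_state[k] / (1 - beta2**step)
                model.params[k] = model.params[k] - lr * mhat / (np.sqrt(vhat) + eps)
        history.append({"loss": float(np.mean(losses)),
                        "accuracy": hits / seen})
    model.trained = True
    return model, history


def extract_features(model: FeatureExtractor, roi) -> np.ndarray:
    """Third-FC-layer embedding of one ROI or a batch of ROIs (head removed).

    A (side, side, C) input returns a 1-D feature vector of length
    ``fc_sizes[-1]``; a (N, side, side, C) batch returns (N, features).
    """
    x = np.asarray(roi, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    cfg = model.config
    if x.shape[1:] != (cfg.input_side, cfg.input_side, cfg.in_channels):
        raise ValueError(
            f"ROI shape {x.shape[1:]} does not match the model input "
            f"({cfg.input_side}, {cfg.input_side}, {cfg.in_channels})"
        )
    feats = model.features(x)
    return feats[0] if single else feats
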