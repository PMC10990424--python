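"""The exchangeable CNN discriminator, implemented directly on NumPy.

The network maps an (n, S, 2) haplotype-window tensor to a single probability.
Both convolutions act along the SNP axis only (kernels of size 1x5, unpadded,
each followed by ReLU and 1x2 max-pooling), so every haplotype row is
processed identically; summing the resulting per-haplotype feature maps over
the haplotype axis makes the output exactly invariant to row permutations.
Two 128-unit dense layers (ReLU, dropout 0.5 during training) and a logistic
output head follow.  At S=36 with 2 input channels the SNP axis evolves
36 -> 32 -> 16 -> 12 -> 6, giving a 6*64 = 384-feature vector and a total of
76,577 trainable parameters.

Training uses mean binary cross-entropy with Adam; gradients are computed by
hand-written backpropagation through the same ops.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

_FORMAT_VERSION = 1
_WEIGHT_KEYS = ("W1", "b1", "W2", "b2", "Wd1", "bd1", "Wd2", "bd2", "Wo", "bo")


@dataclasses.dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the exchangeable CNN."""

    S: int = 36
    channels: int = 2
    conv_filters: tuple[int, int] = (32, 64)
    kernel: int = 5
    pool: int = 2
    dense_units: tuple[int, int] = (128, 128)
    dropout: float = 0.5

    def snp_axis_extents(self) -> list[int]:
        """SNP-axis length after each conv/pool stage."""
        extents = [self.S]
        length = self.S
        for _ in self.conv_filters:
            length = length - self.kernel + 1
            if length < 1:
                raise ValueError(
                    f"S={self.S} too small for the convolution stack")
            extents.append(length)
            length = length // self.pool
            if length < 1:
                raise ValueError(
                    f"S={self.S} too small for the pooling stack")
            extents.append(length)
        return extents

    @property
    def feature_len(self) -> int:
        return self.snp_axis_extents()[-1] * self.conv_filters[-1]

    def parameter_count(self) -> int:
        c1, c2 = self.conv_filters
        d1, d2 = self.dense_units
        total = self.kernel * self.channels * c1 + c1
        total += self.kernel * c1 * c2 + c2
        total += self.feature_len * d1 + d1
        total += d1 * d2 + d2
        total += d2 + 1
        return total

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class AdamState:
    """Adam optimizer state (step 1e-3 by default)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    t: int = 0
    m: dict = dataclasses.field(default_factory=dict)
    v: dict = dataclasses.field(default_factory=dict)

    def update(self, weights: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(weights[k])
                self.v[k] = np.zeros_like(weights[k])
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            weights[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclasses.dataclass
class DiscriminatorState:
    """Weights plus provenance for one discriminator."""

    spec: DiscriminatorSpec
    weights: dict
    provenance: dict = dataclasses.field(default_factory=dict)

    def copy(self) -> "DiscriminatorState":
        return DiscriminatorState(
            spec=self.spec,
            weights={k: v.copy() for k, v in self.weights.items()},
            provenance=dict(self.provenance),
        )


def build_discriminator(
    spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int | None = None
) -> DiscriminatorState:
    """Randomly initialize a discriminator (Glorot-uniform, seeded)."""
    spec.snp_axis_extents()  # validates S against the conv/pool stack
    rng = np.random.default_rng(seed)
    c1, c2 = spec.conv_filters
    d1, d2 = spec.dense_units

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(np.float32)

    k = spec.kernel
    weights = {
        "W1": glorot((k, spec.channels, c1), k * spec.channels, c1),
        "b1": np.zeros(c1, dtype=np.float32),
        "W2": glorot((k, c1, c2), k * c1, c2),
        "b2": np.zeros(c2, dtype=np.float32),
        "Wd1": glorot((spec.feature_len, d1), spec.feature_len, d1),
        "bd1": np.zeros(d1, dtype=np.float32),
        "Wd2": glorot((d1, d2), d1, d2),
        "bd2": np.zeros(d2, dtype=np.float32),
        "Wo": glorot((d2, 1), d2, 1),
        "bo": np.zeros(1, dtype=np.float32),
    }
    assert sum(w.size for w in weights.values()) == spec.parameter_count()
    provenance = {"training_seed": seed, "source_population": None,
                  "gan_trained": False, "fine_tuned": None}
    return DiscriminatorState(spec=spec, weights=weights,
                              provenance=provenance)


# ---------------------------------------------------------------------------
# Forward / backward primitives (SNP axis is the second-to-last axis)
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1D convolution along the SNP axis.  x: (..., S, Cin).

    Computed as one GEMM per kernel tap on strided views, avoiding an
    im2col copy: y[..., j, :] = sum_k x[..., j+k, :] @ W[k].
    """
    K, cin, cout = W.shape
    out_len = x.shape[-2] - K + 1
    y = np.empty(x.shape[:-2] + (out_len, cout), dtype=x.dtype)
    np.copyto(y, b)
    for k in range(K):
        y += x[..., k : k + out_len, :] @ W[k]
    return y, x


def _conv_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray):
    K, cin, cout = W.shape
    out_len = dy.shape[-2]
    dyf = dy.reshape(-1, out_len, cout)
    xf = x.reshape(-1, x.shape[-2], cin)
    dW = np.empty_like(W)
    for k in range(K):
        dW[k] = np.tensordot(
            xf[:, k : k + out_len, :], dyf, axes=([0, 1], [0, 1]))
    db = dyf.sum(axis=(0, 1))
    dx = np.zeros(x.shape, dtype=dy.dtype)
    WT = W.transpose(0, 2, 1)
    for k in range(K):
        dx[..., k : k + out_len, :] += dy @ WT[k]
    return dx, dW, db


def _pool_forward(x: np.ndarray, pool: int):
    """1 x 2 max-pooling along the SNP axis (truncating a ragged end)."""
    if pool != 2:  # general (slower) path
        length = (x.shape[-2] // pool) * pool
        xt = x[..., :length, :].reshape(
            x.shape[:-2] + (length // pool, pool, x.shape[-1]))
        idx = xt.argmax(axis=-2)
        y = np.take_along_axis(xt, idx[..., None, :], axis=-2).squeeze(-2)
        return y, (None, idx, x.shape, length)
    length = (x.shape[-2] // 2) * 2
    a = x[..., 0:length:2, :]
    b = x[..., 1:length:2, :]
    left = a >= b  # ties take the left element
    y = np.where(left, a, b)
    return y, (left, None, x.shape, length)


def _pool_backward(dy: np.ndarray, cache, pool: int):
    left, idx, x_shape, length = cache
    dx = np.zeros(x_shape, dtype=dy.dtype)
    if pool == 2:
        dx[..., 0:length:2, :] = np.where(left, dy, 0)
        dx[..., 1:length:2, :] = np.where(left, 0, dy)
        return dx
    dxt = np.zeros(dy.shape[:-1] + (pool, dy.shape[-1]), dtype=dy.dtype)
    np.put_along_axis(dxt, idx[..., None, :], dy[..., None, :], axis=-2)
    dx[..., :length, :] = dxt.reshape(x_shape[:-2] + (length, x_shape[-1]))
    return dx


def _forward(
    state: DiscriminatorState,
    x: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward pass.  x: (B, n, S, C) float; returns (prob, hidden2, cache)."""
    spec, w = state.spec, state.weights
    if x.ndim != 4:
        raise ValueError("batch must have shape (B, n, S, channels)")
    if x.shape[2] != spec.S or x.shape[3] != spec.channels:
        raise ValueError(
            f"input SNP axis/channels {x.shape[2:]} do not match spec "
            f"({spec.S}, {spec.channels})")
    cache: dict = {}
    a1, v1 = _conv_forward(x, w["W1"], w["b1"])
    r1 = np.maximum(a1, 0.0)
    p1, pc1 = _pool_forward(r1, spec.pool)
    a2, v2 = _conv_forward(p1, w["W2"], w["b2"])
    r2 = np.maximum(a2, 0.0)
    p2, pc2 = _pool_forward(r2, spec.pool)
    # permutation-invariant reduction along the haplotype axis
    feat = p2.sum(axis=1).reshape(x.shape[0], -1)
    z1 = feat @ w["Wd1"] + w["bd1"]
    h1 = np.maximum(z1, 0.0)
    if train:
        keep = 1.0 - spec.dropout
        mask1 = ((rng.random(h1.shape) < keep) / keep).astype(x.dtype)
        h1d = h1 * mask1
    else:
        mask1 = None
        h1d = h1
    z2 = h1d @ w["Wd2"] + w["bd2"]
    h2 = np.maximum(z2, 0.0)
    if train:
        keep = 1.0 - spec.dropout
        mask2 = ((rng.random(h2.shape) < keep) / keep).astype(x.dtype)
        h2d = h2 * mask2
    else:
        mask2 = None
        h2d = h2
    logit = np.clip((h2d @ w["Wo"] + w["bo"]).ravel(), -60.0, 60.0)
    prob = 1.0 / (1.0 + np.exp(-logit))
    cache.update(
        x=x, v1=v1, a1=a1, r1=r1, pc1=pc1, p1=p1, v2=v2, a2=a2, r2=r2,
        pc2=pc2, p2=p2, feat=feat, z1=z1, h1d=h1d, z2=z2, h2d=h2d,
        mask1=mask1, mask2=mask2, prob=prob,
    )
    return prob, h2, cache


def _backward(state: DiscriminatorState, cache: dict, y: np.ndarray) -> dict:
    """Gradients of mean binary cross-entropy wrt all weights."""
    spec, w = state.spec, state.weights
    B = y.shape[0]
    dlogit = ((cache["prob"] - y) / B).astype(cache["prob"].dtype)
    grads = {}
    grads["Wo"] = cache["h2d"].T @ dlogit[:, None]
    grads["bo"] = np.array([dlogit.sum()])
    dh2d = dlogit[:, None] @ w["Wo"].T
    if cache["mask2"] is not None:
        dh2d = dh2d * cache["mask2"]
    dz2 = dh2d * (cache["z2"] > 0)
    grads["Wd2"] = cache["h1d"].T @ dz2
    grads["bd2"] = dz2.sum(axis=0)
    dh1d = dz2 @ w["Wd2"].T
    if cache["mask1"] is not None:
        dh1d = dh1d * cache["mask1"]
    dz1 = dh1d * (cache["z1"] > 0)
    grads["Wd1"] = cache["feat"].T @ dz1
    grads["bd1"] = dz1.sum(axis=0)
    dfeat = dz1 @ w["Wd1"].T
    B_, n = cache["x"].shape[:2]
    f_len, c2 = cache["p2"].shape[-2], cache["p2"].shape[-1]
    dp2 = np.broadcast_to(
        dfeat.reshape(B_, 1, f_len, c2), cache["p2"].shape)
    dr2 = _pool_backward(dp2, cache["pc2"], spec.pool)
    da2 = dr2 * (cache["a2"] > 0)
    dp1, grads["W2"], grads["b2"] = _conv_backward(da2, cache["v2"], w["W2"])
    dr1 = _pool_backward(dp1, cache["pc1"], spec.pool)
    da1 = dr1 * (cache["a1"] > 0)
    _, grads["W1"], grads["b1"] = _conv_backward(da1, cache["v1"], w["W1"])
    return grads


def _canonical_row_order(x: np.ndarray) -> np.ndarray:
    """Reorder haplotype rows of each region into a canonical (sorted) order.

    Summation order over the haplotype axis then no longer depends on the
    presented row order, making inference exactly permutation invariant.
    """
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        keys = tuple(x[i, :, j, 0] for j in range(x.shape[2] - 1, -1, -1))
        out[i] = x[i][np.lexsort(keys)]
    return out


def predict(state: DiscriminatorState, batch: np.ndarray) -> np.ndarray:
    """Probabilities in (0, 1) for a (B, n, S, 2) batch; dropout disabled."""
    x = _canonical_row_order(np.asarray(batch, dtype=np.float32))
    prob, _, _ = _forward(state, x, train=False)
    return np.clip(prob, 1e-15, 1 - 1e-15)


def hidden_activations(state: DiscriminatorState, batch: np.ndarray) -> np.ndarray:
    """Post-ReLU activations of the last 128-unit hidden layer (dropout off)."""
    x = _canonical_row_order(np.asarray(batch, dtype=np.float32))
    _, h2, _ = _forward(state, x, train=False)
    return h2


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(np.asarray(probs, dtype=np.float64), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=np.float64)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_step(
    state: DiscriminatorState,
    batch: np.ndarray,
    labels: np.ndarray,
    opt: AdamState,
    rng: np.random.Generator,
) -> float:
    """One Adam update on mean binary cross-entropy (dropout active).

    Mutates ``state.weights`` and ``opt`` in place; returns the batch loss.
    """
    x = np.asarray(batch, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    prob, _, cache = _forward(state, x, train=True, rng=rng)
    loss = bce_loss(prob, y)
    grads = _backward(state, cache, y)
    opt.update(state.weights, grads)
    return loss


def train_step_real_fake(
    state: DiscriminatorState,
    real_batch: np.ndarray,
    fake_batch: np.ndarray,
    opt: AdamState,
    rng: np.random.Generator,
) -> float:
    """GAN-phase update: real labelled 1, simulated-neutral labelled 0."""
    if real_batch.shape[0] == 0 or fake_batch.shape[0] == 0:
        raise ValueError("empty batch")
    x = np.concatenate([real_batch, fake_batch], axis=0)
    y = np.concatenate([
        np.ones(real_batch.shape[0]), np.zeros(fake_batch.shape[0])])
    return train_step(state, x, y, opt, rng)


def is_degenerate(
    state: DiscriminatorState,
    probe_batch: np.ndarray,
    tolerance: float = 1e-4,
) -> bool:
    """Flag a discriminator that outputs (nearly) the same value everywhere.

    ``probe_batch`` should contain a diverse set of regions (e.g. neutral
    simulations at distinct parameter draws).
    """
    probs = predict(state, probe_batch)
    return bool(probs.max() - probs.min() < tolerance)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_discriminator(state: DiscriminatorState, path: str) -> None:
    """Write spec, weights and provenance to a self-describing .disc file."""
    np.savez(
        path if str(path).endswith(".npz") else str(path),
        format_version=_FORMAT_VERSION,
        spec=json.dumps(state.spec.to_dict()),
        provenance=json.dumps(state.provenance, default=str),
        **state.weights,
    )


def load_discriminator(path: str, expected_S: int | None = None) -> DiscriminatorState:
    with np.load(path, allow_pickle=False) as npz:
        if int(npz["format_version"]) != _FORMAT_VERSION:
            raise ValueError("discriminator file version mismatch")
        spec_dict = json.loads(str(npz["spec"]))
        for key in ("conv_filters", "dense_units"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = DiscriminatorSpec(**spec_dict)
        if expected_S is not None and spec.S != expected_S:
            raise ValueError(
                f"discriminator was built for S={spec.S}, expected {expected_S}")
        weights = {k: npz[k].copy() for k in _WEIGHT_KEYS}
        provenance = json.loads(str(npz["provenance"]))
    return DiscriminatorState(spec=spec, weights=weights, provenance=provenance)
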