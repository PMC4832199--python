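"""Single denoising autoencoder: corruption, encode/decode, loss, gradients, SGD.

The layer maps inputs in [0,1]^d through a sigmoid encoder to a hidden code
and back through a (tied-weight) sigmoid decoder; training minimizes the mean
cross-entropy between the clean input and the reconstruction of a corrupted
copy.  Corruption is masking noise: an exact fraction of coordinates, chosen
uniformly without replacement, is zeroed.  All gradients are analytic and are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DaeLayer",
    "TrainSpec",
    "init_layer",
    "corrupt",
    "encode",
    "reconstruct",
    "loss",
    "grad",
    "train_dae",
]

_EPS = 1e-7  # reconstruction clipping for finite cross-entropy


def sigmoid(a: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow for large |a|
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class DaeLayer:
    """Weights of one denoising autoencoder layer (tied decoder by default)."""

    W: np.ndarray  # d_hidden x d_in
    b_enc: np.ndarray  # d_hidden
    b_dec: np.ndarray  # d_in
    corruption_level: float = 0.3
    tied: bool = True
    W_dec: np.ndarray | None = None  # d_in x d_hidden, used when not tied

    def __post_init__(self) -> None:
        if not (0.0 <= self.corruption_level <= 1.0):
            raise ValueError("corruption_level must lie in [0, 1]")
        if not self.tied and self.W_dec is None:
            self.W_dec = self.W.T.copy()

    @property
    def d_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def d_in(self) -> int:
        return self.W.shape[1]


@dataclass
class TrainSpec:
    """SGD hyperparameters for one training stage."""

    learning_rate: float = 0.1
    epochs: int = 15
    batch_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("learning_rate and batch_size must be positive, epochs >= 0")


def init_layer(
    d_in: int,
    d_hidden: int,
    rng: np.random.Generator,
    corruption_level: float = 0.3,
    tied: bool = True,
) -> DaeLayer:
    """Uniform(-r, r) weights with r = 4*sqrt(6/(d_in+d_hidden)), zero biases."""
    r = 4.0 * np.sqrt(6.0 / (d_in + d_hidden))
    W = rng.uniform(-r, r, size=(d_hidden, d_in))
    return DaeLayer(
        W=W,
        b_enc=np.zeros(d_hidden),
        b_dec=np.zeros(d_in),
        corruption_level=corruption_level,
        tied=tied,
    )


def corrupt(x: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    """Masking noise: exactly floor(level*d) distinct coordinates set to zero."""
    if not (0.0 <= level <= 1.0):
        raise ValueError("corruption level must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    n_mask = int(np.floor(level * d))
    out = x.copy()
    if n_mask == 0:
        return out
    if x.ndim == 1:
        idx = rng.choice(d, size=n_mask, replace=False)
        out[idx] = 0.0
    else:
        for row in out:
            idx = rng.choice(d, size=n_mask, replace=False)
            row[idx] = 0.0
    return out


def encode(layer: DaeLayer, x: np.ndarray) -> np.ndarray:
    """h = sigmoid(W x + b_enc); accepts a vector or a (n, d_in) batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.d_in:
        raise ValueError(f"expected input dim {layer.d_in}, got {x.shape[-1]}")
    return sigmoid(x @ layer.W.T + layer.b_enc)


def reconstruct(layer: DaeLayer, h: np.ndarray) -> np.ndarray:
    """z = sigmoid(W^T h + b_dec) (tied) or sigmoid(W_dec h + b_dec)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != layer.d_hidden:
        raise ValueError(f"expected hidden dim {layer.d_hidden}, got {h.shape[-1]}")
    dec = layer.W.T if layer.tied else layer.W_dec
    return sigmoid(h @ dec.T + layer.b_dec)


def loss(x: np.ndarray, z: np.ndarray) -> float:
    """Mean cross-entropy -(1/d) sum x log z + (1-x) log(1-z), z clipped to [eps, 1-eps]."""
    x = np.asarray(x, dtype=float)
    z = np.clip(np.asarray(z, dtype=float), _EPS, 1.0 - _EPS)
    ce = -(x * np.log(z) + (1.0 - x) * np.log(1.0 - z))
    return float(ce.mean())


def grad(layer: DaeLayer, x_clean: np.ndarray, x_corrupt: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of loss(x_clean, reconstruct(encode(x_corrupt))).

    Supports single vectors or (n, d) batches; batch gradients are the mean
    over samples.  For sigmoid output + cross-entropy the pre-activation
    residual is (z - x)/d, so the b_dec gradient is exactly the mean residual
    divided by d.
    """
    x_clean = np.atleast_2d(np.asarray(x_clean, dtype=float))
    x_corrupt = np.atleast_2d(np.asarray(x_corrupt, dtype=float))
    n, d = x_clean.shape
    h = encode(layer, x_corrupt)  # n x d_h
    z = reconstruct(layer, h)  # n x d
    delta_out = (z - x_clean) / d  # n x d
    dec = layer.W.T if layer.tied else layer.W_dec  # d x d_h
    delta_hidden = (delta_out @ dec) * h * (1.0 - h)  # n x d_h

    g_b_dec = delta_out.mean(axis=0)
    g_b_enc = delta_hidden.mean(axis=0)
    g_W_enc = delta_hidden.T @ x_corrupt / n  # d_h x d
    g_W_dec = delta_out.T @ h / n  # d x d_h
    if layer.tied:
        return {"W": g_W_enc + g_W_dec.T, "b_enc": g_b_enc, "b_dec": g_b_dec}
    return {"W": g_W_enc, "W_dec": g_W_dec, "b_enc": g_b_enc, "b_dec": g_b_dec}


def train_dae(
    data: np.ndarray,
    d_hidden: int,
    spec: TrainSpec,
    level: float = 0.3,
    layer: DaeLayer | None = None,
) -> tuple[DaeLayer, list[float]]:
    """Train one DAE with mini-batch SGD; returns the layer and per-epoch mean loss.

    ``data`` is an (n, d) array of clean inputs in [0,1]; each presentation
    corrupts its inputs afresh.  With ``spec.epochs == 0`` the freshly
    initialized layer is returned untouched.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a nonempty (n, d) array")
    rng = np.random.default_rng(spec.seed)
    if layer is None:
        layer = init_layer(data.shape[1], d_hidden, rng, corruption_level=level)
    n = data.shape[0]
    curve: list[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            batch = data[order[start : start + spec.batch_size]]
            noisy = corrupt(batch, level, rng)
            g = grad(layer, batch, noisy)
            layer.W -= spec.learning_rate * g["W"]
            layer.b_enc -= spec.learning_rate * g["b_enc"]
            layer.b_dec -= spec.learning_rate * g["b_dec"]
            if not layer.tied:
                layer.W_dec -= spec.learning_rate * g["W_dec"]
            epoch_losses.append(loss(batch, reconstruct(layer, encode(layer, noisy))))
        curve.append(float(np.mean(epoch_losses)))
    return layer, curve
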