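"""Stacked denoising autoencoder classifier (784 -> 200 -> 100 -> softmax-2).

Training follows the two-stage recipe: greedy layer-wise unsupervised
pretraining of the encoder stack on 28x28 patch vectors, then supervised
fine-tuning of the whole network with backpropagation after grafting on
three auxiliary input neurons (per-axis resize scale factors and the
original aspect ratio) and a 2-class softmax head.  The auxiliary inputs
feed hidden layer 1 through a zero-initialized weight block, so fine-tuning
starts exactly at the pretrained solution.

Class convention: index 0 = benign, index 1 = malignant; a tie at
p = 0.5 resolves to benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dae import DaeLayer, TrainSpec, encode, init_layer, sigmoid, train_dae
from .roi_prep import PATCH_SIZE, AuxStandardizer, RoiSample

__all__ = ["Prediction", "SdaeClassifier", "DEFAULT_HIDDEN"]

DEFAULT_HIDDEN = (200, 100)
CLASSES = ("benign", "malignant")
MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Prediction:
    """Softmax class probabilities and the tie-broken hard label."""

    p_benign: float
    p_malignant: float

    @property
    def hard_label(self) -> str:
        # strict >: a 0.5 tie favors the benign call (higher specificity)
        return "malignant" if self.p_malignant > 0.5 else "benign"


def _labels_to_int(labels) -> np.ndarray:
    try:
        return np.array([CLASSES.index(l) for l in labels], dtype=int)
    except ValueError as e:
        raise ValueError(f"labels must be in {CLASSES}") from e


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=1, keepdims=True))


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


class SdaeClassifier:
    """Two-hidden-layer SDAE with auxiliary geometry inputs and softmax output."""

    def __init__(
        self,
        hidden_sizes: tuple[int, int] = DEFAULT_HIDDEN,
        corruption_levels: tuple[float, float] = (0.3, 0.3),
    ) -> None:
        self.hidden_sizes = tuple(hidden_sizes)
        self.corruption_levels = tuple(corruption_levels)
        self.enc_layers: list[DaeLayer] = []
        self.aux_W: np.ndarray | None = None  # d_h1 x 3
        self.softmax_W: np.ndarray | None = None  # 2 x d_h2
        self.softmax_b: np.ndarray | None = None
        self.aux_standardizer = AuxStandardizer()
        self.pretrain_curves: list[list[float]] = []
        self.finetune_curve: list[float] = []

    # -- data marshalling -----------------------------------------------------

    @staticmethod
    def _patch_matrix(samples: list[RoiSample]) -> np.ndarray:
        return np.array([s.patch.ravel() for s in samples], dtype=float)

    def _aux_matrix(self, samples: list[RoiSample]) -> np.ndarray:
        return self.aux_standardizer.transform(samples)

    # -- unsupervised stage ---------------------------------------------------

    def pretrain(self, samples: list[RoiSample], spec: TrainSpec) -> "SdaeClassifier":
        """Greedy layer-wise DAE training.

        Layer 1 reconstructs corrupted 784-d patch vectors; layer 2 is
        trained on the *clean* layer-1 hidden codes (corruption is applied
        inside layer 2's own denoising objective).
        """
        if not samples:
            raise ValueError("pretrain requires at least one sample")
        X = self._patch_matrix(samples)
        self.enc_layers = []
        self.pretrain_curves = []
        inputs = X
        for i, (d_h, level) in enumerate(zip(self.hidden_sizes, self.corruption_levels)):
            layer_spec = TrainSpec(
                learning_rate=spec.learning_rate,
                epochs=spec.epochs,
                batch_size=spec.batch_size,
                seed=spec.seed + i,
            )
            layer, curve = train_dae(inputs, d_h, layer_spec, level=level)
            self.enc_layers.append(layer)
            self.pretrain_curves.append(curve)
            inputs = encode(layer, inputs)
        return self

    # -- forward pass ---------------------------------------------------------

    def _require_fitted(self) -> None:
        if not self.enc_layers or self.softmax_W is None:
            raise RuntimeError("model is not fitted: run pretrain() and finetune() first")

    def _forward(self, X: np.ndarray, aux: np.ndarray):
        l1, l2 = self.enc_layers
        a1 = X @ l1.W.T + aux @ self.aux_W.T + l1.b_enc
        h1 = sigmoid(a1)
        h2 = sigmoid(h1 @ l2.W.T + l2.b_enc)
        logits = h2 @ self.softmax_W.T + self.softmax_b
        return h1, h2, logits

    def supervised_loss(self, X: np.ndarray, aux: np.ndarray, y: np.ndarray) -> float:
        """Mean softmax cross-entropy of the full network on a batch."""
        _, _, logits = self._forward(X, aux)
        logp = _log_softmax(logits)
        return float(-logp[np.arange(len(y)), y].mean())

    def supervised_grad(self, X: np.ndarray, aux: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Analytic gradients of :meth:`supervised_loss` for every parameter block."""
        n = X.shape[0]
        l1, l2 = self.enc_layers
        h1, h2, logits = self._forward(X, aux)
        p = np.exp(_log_softmax(logits))
        onehot = np.zeros_like(p)
        onehot[np.arange(n), y] = 1.0
        d_logits = (p - onehot) / n
        d_h2 = d_logits @ self.softmax_W
        d_a2 = d_h2 * h2 * (1.0 - h2)
        d_h1 = d_a2 @ l2.W
        d_a1 = d_h1 * h1 * (1.0 - h1)
        return {
            "softmax_W": d_logits.T @ h2,
            "softmax_b": d_logits.sum(axis=0),
            "W2": d_a2.T @ h1,
            "b2": d_a2.sum(axis=0),
            "W1": d_a1.T @ X,
            "aux_W": d_a1.T @ aux,
            "b1": d_a1.sum(axis=0),
        }

    # -- supervised stage -----------------------------------------------------

    def finetune(self, train: list[RoiSample], spec: TrainSpec) -> "SdaeClassifier":
        """Backprop fine-tuning of the full network from the pretrained init.

        The auxiliary standardizer is fitted on ``train`` only.  The softmax
        head starts from small seeded uniform noise and ``aux_W`` from zeros,
        so at epoch 0 the network's hidden representation equals the
        pretrained one.
        """
        if not self.enc_layers:
            raise RuntimeError("finetune requires a pretrained encoder stack")
        y = _labels_to_int([s.label for s in train])
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(spec.seed)
        self.aux_standardizer.fit(train)
        X = self._patch_matrix(train)
        aux = self._aux_matrix(train)
        d_h1, d_h2 = self.hidden_sizes
        self.aux_W = np.zeros((d_h1, 3))
        self.softmax_W = rng.uniform(-0.01, 0.01, size=(2, d_h2))
        self.softmax_b = np.zeros(2)

        l1, l2 = self.enc_layers
        n = X.shape[0]
        self.finetune_curve = []
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                g = self.supervised_grad(X[idx], aux[idx], y[idx])
                lr = spec.learning_rate
                self.softmax_W -= lr * g["softmax_W"]
                self.softmax_b -= lr * g["softmax_b"]
                l2.W -= lr * g["W2"]
                l2.b_enc -= lr * g["b2"]
                l1.W -= lr * g["W1"]
                l1.b_enc -= lr * g["b1"]
                self.aux_W -= lr * g["aux_W"]
                losses.append(self.supervised_loss(X[idx], aux[idx], y[idx]))
            self.finetune_curve.append(float(np.mean(losses)))
        return self

    def fit(
        self,
        train: list[RoiSample],
        pretrain_spec: TrainSpec | None = None,
        finetune_spec: TrainSpec | None = None,
    ) -> "SdaeClassifier":
        """Convenience: pretrain then finetune with the stage defaults."""
        self.pretrain(train, pretrain_spec or TrainSpec(learning_rate=0.1, epochs=15))
        self.finetune(train, finetune_spec or TrainSpec(learning_rate=0.05, epochs=100))
        return self

    # -- inference ------------------------------------------------------------

    def predict_proba(self, samples: list[RoiSample]) -> np.ndarray:
        """(n, 2) array of [p_benign, p_malignant] rows."""
        self._require_fitted()
        X = self._patch_matrix(samples)
        aux = self._aux_matrix(samples)
        _, _, logits = self._forward(X, aux)
        return np.exp(_log_softmax(logits))

    def predict(self, sample: RoiSample) -> Prediction:
        p = self.predict_proba([sample])[0]
        return Prediction(p_benign=float(p[0]), p_malignant=float(p[1]))

    # -- interpretability -----------------------------------------------------

    def layer_patterns(self, layer: int) -> list[np.ndarray]:
        """Reconstruct hidden-unit patterns as min-max-normalized 28x28 images.

        Layer 1: each unit's encoder weight row reshaped to the patch grid.
        Layer 2: for unit j the weighted sum over all first-layer patterns
        with weights W2[j, :], taking every first-layer neuron as activated.
        """
        if not self.enc_layers:
            raise RuntimeError("no pretrained layers available")
        if layer not in (1, 2):
            raise ValueError("layer must be 1 or 2")
        W1 = self.enc_layers[0].W[:, :PATCH_SIZE * PATCH_SIZE]
        if layer == 1:
            return [_minmax(row.reshape(PATCH_SIZE, PATCH_SIZE)) for row in W1]
        W2 = self.enc_layers[1].W
        combined = W2 @ W1  # each row: sum_i W2[j,i] * pattern1_i
        return [_minmax(row.reshape(PATCH_SIZE, PATCH_SIZE)) for row in combined]

    # -- serialization --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist the model to a single ``.npz`` file (versioned format)."""
        self._require_fitted()
        l1, l2 = self.enc_layers
        np.savez(
            path,
            format_version=MODEL_FORMAT_VERSION,
            hidden_sizes=np.array(self.hidden_sizes),
            corruption_levels=np.array(self.corruption_levels),
            W1=l1.W, b1=l1.b_enc, b1_dec=l1.b_dec,
            W2=l2.W, b2=l2.b_enc, b2_dec=l2.b_dec,
            aux_W=self.aux_W, softmax_W=self.softmax_W, softmax_b=self.softmax_b,
            aux_mean=self.aux_standardizer.mean_, aux_std=self.aux_standardizer.std_,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SdaeClassifier":
        with np.load(path) as f:
            if int(f["format_version"]) != MODEL_FORMAT_VERSION:
                raise ValueError("unsupported model format version")
            hidden = tuple(int(v) for v in f["hidden_sizes"])
            levels = tuple(float(v) for v in f["corruption_levels"])
            model = cls(hidden_sizes=hidden, corruption_levels=levels)
            model.enc_layers = [
                DaeLayer(W=f["W1"], b_enc=f["b1"], b_dec=f["b1_dec"], corruption_level=levels[0]),
                DaeLayer(W=f["W2"], b_enc=f["b2"], b_dec=f["b2_dec"], corruption_level=levels[1]),
            ]
            model.aux_W = f["aux_W"]
            model.softmax_W = f["softmax_W"]
            model.softmax_b = f["softmax_b"]
            model.aux_standardizer.mean_ = f["aux_mean"]
            model.aux_standardizer.std_ = f["aux_std"]
        return model
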