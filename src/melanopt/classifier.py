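"""MLP melanoma classifier trained by the gray-wolf optimizer.

The network is a single-hidden-layer perceptron: X inputs (the CNN feature
vector, 100 by default), H tansig (hyperbolic tangent) hidden units with
H in [5, 30], and C = 2 linear outputs passed through a softmax so the
class scores sum to one. Both H and the full weight/bias vector are genes
of one genome; the training objective is the raw misclassification rate
Fit = F / N on the training set, minimized by :func:`melanopt.igwo.optimize`.

Class 0 is non-melanoma, class 1 is melanoma; score ties predict the
conservative non-melanoma class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import igwo

__all__ = [
    "MLPClassifier",
    "forward",
    "predict",
    "fitness_of_genome",
    "train_classifier",
]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MLPClassifier:
    """Decoded network: tanh hidden layer + softmax output."""

    spec: igwo.NetworkSpec

    @property
    def n_inputs(self) -> int:
        return self.spec.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.spec.n_hidden

    @property
    def n_outputs(self) -> int:
        return self.spec.output_weights.shape[0]

    def forward(self, features) -> np.ndarray:
        return forward(self.spec, features)

    def predict(self, features) -> np.ndarray:
        return predict(self.spec, features)

    def scores(self, features) -> np.ndarray:
        """Melanoma-class probability per sample (for ROC curves)."""
        return self.forward(features)[..., 1]

    def to_json(self, path) -> None:
        payload = {
            "n_hidden": self.spec.n_hidden,
            "hidden_weights": self.spec.hidden_weights.tolist(),
            "hidden_biases": self.spec.hidden_biases.tolist(),
            "output_weights": self.spec.output_weights.tolist(),
            "output_biases": self.spec.output_biases.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MLPClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        spec = igwo.NetworkSpec(
            n_hidden=int(payload["n_hidden"]),
            hidden_weights=np.asarray(payload["hidden_weights"], dtype=float),
            hidden_biases=np.asarray(payload["hidden_biases"], dtype=float),
            output_weights=np.asarray(payload["output_weights"], dtype=float),
            output_biases=np.asarray(payload["output_biases"], dtype=float),
        )
        return cls(spec=spec)


def forward(spec: igwo.NetworkSpec, features) -> np.ndarray:
    """Class scores: softmax(W_o tanh(W_h x + b_h) + b_o); sum to 1."""
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != spec.hidden_weights.shape[1]:
        raise ValueError(
            f"feature length {x.shape[-1]} != network inputs "
            f"{spec.hidden_weights.shape[1]}"
        )
    hidden = np.tanh(x @ spec.hidden_weights.T + spec.hidden_biases)
    logits = hidden @ spec.output_weights.T + spec.output_biases
    return _softmax(logits)


def predict(spec: igwo.NetworkSpec, features) -> np.ndarray:
    """Argmax of the class scores; exact ties fall to class 0 (non-melanoma)."""
    return np.argmax(forward(spec, features), axis=-1)


def fitness_of_genome(genome, train_features, train_labels) -> float:
    """Eq.-style training error Fit = F/N: fraction of misclassified samples."""
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    spec = igwo.decode_genome(genome, n_inputs=x.shape[1], n_outputs=2)
    pred = predict(spec, x)
    return float(np.mean(pred != y))


def train_classifier(train_features, train_labels,
                     config: igwo.IGWOConfig | None = None):
    """Jointly optimize H and the weight vector on the training error.

    Returns (MLPClassifier, OptimizeResult).
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels must contain both classes")
    if config is None:
        config = igwo.IGWOConfig()
    bounds = igwo.genome_bounds(n_inputs=x.shape[1], n_outputs=2)

    def fitness(genome):
        return fitness_of_genome(genome, x, y)

    result = igwo.optimize(fitness, config, bounds)
    spec = igwo.decode_genome(result.best_genome, n_inputs=x.shape[1], n_outputs=2)
    return MLPClassifier(spec=spec), result
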