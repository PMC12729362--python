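"""Classification head: sigmoid of an affine map of the fused feature,
trained with mean binary cross-entropy.

The positive class is muscle invasion (MIBC); non-invasive cases are the
negative class.  Probabilities are clamped to [eps, 1-eps] inside the logs
because the cross-entropy is undefined at exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module

__all__ = ["Prediction", "classify", "bce_loss", "bce_loss_grad", "ClassifierHead",
           "PROB_EPS", "DECISION_THRESHOLD"]

PROB_EPS = 1e-7
DECISION_THRESHOLD = 0.5


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


@dataclass(frozen=True)
class Prediction:
    """Invasion probability y_p = sigmoid(logit) with the 0.5-threshold
    hard label."""

    logit: float
    y_p: float
    label_hat: int

    def __post_init__(self) -> None:
        if not 0.0 < self.y_p < 1.0:
            raise ValueError("probability must lie strictly in (0, 1)")


def classify(fo: np.ndarray, w_o: np.ndarray, b_o: float) -> Prediction:
    """y_p = sigmoid(W_o . F_o + b_o) for one fused feature vector."""
    logit = float(np.asarray(w_o).ravel() @ np.asarray(fo).ravel() + b_o)
    y_p = float(np.clip(_sigmoid(np.array(logit)), PROB_EPS, 1.0 - PROB_EPS))
    return Prediction(logit=logit, y_p=y_p, label_hat=int(y_p >= DECISION_THRESHOLD))


def bce_loss(y_p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy
    -(1/N) sum[y log y_p + (1 - y) log(1 - y_p)], probabilities clamped."""
    y_p = np.asarray(y_p, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if y_p.size == 0:
        raise ValueError("empty batch")
    if y_p.size != y.size:
        raise ValueError("predictions and labels differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    p = np.clip(y_p, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_loss_grad(y_p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d loss / d y_p for the clamped mean cross-entropy."""
    y_p = np.asarray(y_p, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.clip(y_p, PROB_EPS, 1.0 - PROB_EPS)
    g = (-(y / p) + (1.0 - y) / (1.0 - p)) / y.size
    g[(y_p <= PROB_EPS) | (y_p >= 1.0 - PROB_EPS)] = 0.0  # clamp region
    return g


class ClassifierHead(Module):
    """Fully connected projection of the fused feature to one logit."""

    def __init__(self, dim: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        self.fc = Linear(dim, 1, rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, fo: np.ndarray) -> np.ndarray:
        """(B, N) fused features -> (B,) probabilities."""
        logits = self.fc(fo)[:, 0]
        y_p = _sigmoid(logits)
        self._cache = y_p
        return y_p

    def backward(self, g_yp: np.ndarray) -> np.ndarray:
        y_p = self._cache
        g_logit = g_yp * y_p * (1.0 - y_p)
        self._cache = None
        return self.fc.backward(g_logit[:, None])
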