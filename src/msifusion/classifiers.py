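"""The two classifier families: MLP and Gaussian MAP.

The MLP is a fully connected network with sigmoid hidden layers, a softmax
output layer and the cross-entropy loss, trained by full-batch
backpropagation with momentum. Training supports a noise curriculum: an
ordered sequence of training sets of increasing noise, each stage
warm-started from the previous stage's weights.

The MAP classifier models each class by a multivariate Gaussian
(sample mean, shrinkage-regularized sample covariance) and assigns a test
vector to the class with the largest posterior probability
``P(w_k | x) ∝ P(x | w_k) P(w_k)``, evaluated through log-discriminants
``g_k = ln P(x | w_k) + ln P(w_k)`` with log-sum-exp normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import log_softmax, softmax

__all__ = [
    "MLPModel",
    "TrainingConfig",
    "MLPTrainResult",
    "GaussianClassConditional",
    "init_mlp",
    "mlp_forward",
    "mlp_gradients",
    "cross_entropy",
    "train_mlp",
    "fit_gaussian_map",
    "map_log_posterior",
    "map_posterior",
    "decide",
]

_LOG_FLOOR = 1e-12  # cap for -log(0) in the cross-entropy


@dataclass
class MLPModel:
    """Weights and biases of a sigmoid-hidden / softmax-output MLP.

    ``weights[m]`` maps layer m to layer m+1; ``biases[m]`` feeds layer
    m+1. The output dimension is the number of classes K.
    """

    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]


@dataclass
class TrainingConfig:
    """Hyperparameters for curriculum MLP training.

    The stopping rule terminates a stage once the mean training
    cross-entropy falls below ``stop_cross_entropy`` (default 0.001);
    ``max_epochs`` caps each stage.
    """

    hidden_sizes: tuple[int, ...] = (32,)
    learning_rate: float = 0.2
    momentum: float = 0.9
    max_epochs: int = 5000
    stop_cross_entropy: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.stop_cross_entropy <= 0:
            raise ValueError("stop_cross_entropy must be positive")


@dataclass
class MLPTrainResult:
    model: MLPModel
    final_cross_entropy: float
    converged: bool
    epochs_per_stage: list[int] = field(default_factory=list)


def init_mlp(
    n_inputs: int, hidden_sizes: tuple[int, ...], n_classes: int, seed: int = 0
) -> MLPModel:
    """Glorot-uniform initial weights, zero biases."""
    sizes = [n_inputs, *hidden_sizes, n_classes]
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (a + b))
        weights.append(rng.uniform(-limit, limit, size=(a, b)))
        biases.append(np.zeros(b))
    return MLPModel(weights=weights, biases=biases)


def _sigmoid(q: np.ndarray) -> np.ndarray:
    out = np.empty_like(q)
    pos = q >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-q[pos]))
    eq = np.exp(q[~pos])
    out[~pos] = eq / (1.0 + eq)
    return out


def _forward_pass(x: np.ndarray, model: MLPModel) -> list[np.ndarray]:
    """Activations per layer; final layer is the softmax posterior."""
    acts = [x]
    h = x
    last = len(model.weights) - 1
    for m, (w, b) in enumerate(zip(model.weights, model.biases)):
        q = h @ w + b
        h = softmax(q, axis=-1) if m == last else _sigmoid(q)
        acts.append(h)
    return acts


def mlp_forward(x: np.ndarray, model: MLPModel) -> np.ndarray:
    """Posterior class probabilities for one input or a batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {x.shape[-1]} != network input "
            f"{model.weights[0].shape[0]}"
        )
    return _forward_pass(x, model)[-1]


def cross_entropy(posterior: np.ndarray, target_class: int | np.ndarray) -> float:
    """Mean cross-entropy -log P(target) under the predicted posterior.

    Posteriors are floored at 1e-12 so a zero probability at the target
    yields a large finite loss instead of infinity.
    """
    p = np.atleast_2d(np.asarray(posterior, dtype=float))
    t = np.atleast_1d(np.asarray(target_class, dtype=int))
    picked = p[np.arange(len(t)), t]
    return float(-np.log(np.maximum(picked, _LOG_FLOOR)).mean())


def mlp_gradients(
    model: MLPModel, x: np.ndarray, targets: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Backpropagated mean-loss gradients (dW, db) and the loss itself."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.asarray(targets, dtype=int)
    n = x.shape[0]
    acts = _forward_pass(x, model)
    onehot = np.zeros((n, model.n_classes))
    onehot[np.arange(n), t] = 1.0
    loss = cross_entropy(acts[-1], t)
    # softmax + cross-entropy: output delta is (y - t) / n
    delta = (acts[-1] - onehot) / n
    grads_w: list[np.ndarray] = [None] * len(model.weights)
    grads_b: list[np.ndarray] = [None] * len(model.biases)
    for m in range(len(model.weights) - 1, -1, -1):
        grads_w[m] = acts[m].T @ delta
        grads_b[m] = delta.sum(axis=0)
        if m > 0:
            h = acts[m]
            delta = (delta @ model.weights[m].T) * h * (1.0 - h)
    return grads_w, grads_b, loss


def train_mlp(
    train_sets_by_stage: list[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> MLPTrainResult:
    """Curriculum backpropagation over stages of increasing noise.

    Stages are trained in order, each warm-started from the previous
    stage's weights (gradient descent with momentum, full batch). A stage
    ends when its mean training cross-entropy drops below the stopping
    threshold or ``max_epochs`` is reached; the convergence flag reports
    whether the final stage met the threshold.
    """
    if not train_sets_by_stage:
        raise ValueError("need at least one training stage")
    x0 = np.atleast_2d(np.asarray(train_sets_by_stage[0][0], dtype=float))
    n_classes = int(max(np.max(y) for _, y in train_sets_by_stage)) + 1
    model = init_mlp(x0.shape[1], config.hidden_sizes, n_classes, config.seed)
    velocity_w = [np.zeros_like(w) for w in model.weights]
    velocity_b = [np.zeros_like(b) for b in model.biases]
    loss = np.inf
    epochs_per_stage = []
    for x, y in train_sets_by_stage:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.asarray(y, dtype=int)
        epoch = 0
        for epoch in range(1, config.max_epochs + 1):
            gw, gb, loss = mlp_gradients(model, x, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            if loss < config.stop_cross_entropy:
                break
            for m in range(len(model.weights)):
                velocity_w[m] = config.momentum * velocity_w[m] - config.learning_rate * gw[m]
                velocity_b[m] = config.momentum * velocity_b[m] - config.learning_rate * gb[m]
                model.weights[m] += velocity_w[m]
                model.biases[m] += velocity_b[m]
        epochs_per_stage.append(epoch)
    return MLPTrainResult(
        model=model,
        final_cross_entropy=float(loss),
        converged=bool(loss < config.stop_cross_entropy),
        epochs_per_stage=epochs_per_stage,
    )


@dataclass
class GaussianClassConditional:
    """Gaussian class-conditional density with prior, for MAP scoring."""

    class_index: int
    mean: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)
    prior: float = 1.0

    def log_likelihood(self, x: np.ndarray) -> np.ndarray:
        d = self.mean.shape[0]
        try:
            chol = np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular covariance for class {self.class_index}; "
                "increase shrinkage or ridge"
            ) from err
        diff = np.atleast_2d(x) - self.mean
        z = scipy.linalg.solve_triangular(chol, diff.T, lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        quad = (z**2).sum(axis=0)
        return -0.5 * (d * np.log(2 * np.pi) + logdet + quad)


def fit_gaussian_map(
    features: np.ndarray,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
    shrinkage: float = 0.1,
    ridge: float = 1e-8,
) -> list[GaussianClassConditional]:
    """Per-class Gaussian estimates with shrinkage regularization.

    The covariance of class k is ``(1 - λ) Σ̂ + λ diag(Σ̂) + ridge·I``,
    which stays invertible even when the per-class sample count is below
    the feature dimension. Priors default to equal (1/K).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    priors = np.asarray(priors, dtype=float)
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    models = []
    for k, p in zip(classes, priors):
        xk = x[y == k]
        if xk.shape[0] < 2:
            raise ValueError(f"class {k} has fewer than 2 samples")
        cov = np.cov(xk, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        reg = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
        reg += ridge * np.eye(cov.shape[0])
        models.append(
            GaussianClassConditional(
                class_index=int(k),
                mean=xk.mean(axis=0),
                covariance=reg,
                prior=float(p),
            )
        )
    return models


def map_log_posterior(
    x: np.ndarray, models: list[GaussianClassConditional]
) -> np.ndarray:
    """Log posterior over classes via log-sum-exp of the discriminants."""
    g = np.stack(
        [m.log_likelihood(x) + np.log(m.prior) for m in models], axis=-1
    )
    return log_softmax(g, axis=-1)


def map_posterior(
    x: np.ndarray, models: list[GaussianClassConditional]
) -> np.ndarray:
    """Exact Bayes posterior under the fitted Gaussian class models."""
    post = np.exp(map_log_posterior(x, models))
    return post[0] if np.asarray(x).ndim == 1 else post


def decide(posterior: np.ndarray) -> int | np.ndarray:
    """Maximum-posterior decision; ties go to the lowest class index."""
    p = np.asarray(posterior, dtype=float)
    return int(np.argmax(p)) if p.ndim == 1 else np.argmax(p, axis=-1)
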