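"""Feature-integrating (FI) and decision-integrating (DI) fusion.

Two architectures combine J unimodal channels:

* **FI** — concatenate the normalized unimodal feature vectors into one
  vector of dimension D = sum(D_j) and classify it with a single
  multimodal classifier (MLP or Gaussian MAP on the fused space). The
  fused MAP covariance is a block matrix whose off-diagonal blocks are
  the cross-modality covariances; it is estimated empirically from the
  fused training vectors.

* **DI** — classify each modality independently, then fuse the unimodal
  outputs with a second-stage classifier. The MLP variant consumes the
  concatenated soft posteriors (dimension K*J); the MAP variant consumes
  the hard unimodal decisions and scores them with a confusion-product
  likelihood ``P(Z | w_k) = prod_j P_j(y_j | w_k)``, where ``P_j(i | k)``
  is the estimated probability that unimodal classifier j decides class
  i when the true class is k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    GaussianClassConditional,
    MLPModel,
    MLPTrainResult,
    TrainingConfig,
    fit_gaussian_map,
    map_posterior,
    mlp_forward,
    train_mlp,
)

__all__ = [
    "FusedFeature",
    "ConfusionModel",
    "fi_concat",
    "fit_fi_map",
    "fi_classify",
    "di_concat_posteriors",
    "train_di_mlp",
    "estimate_confusion",
    "di_map_likelihood",
    "di_map_posterior",
]


@dataclass(frozen=True)
class FusedFeature:
    """Concatenated multimodal feature vector(s) with modality slices."""

    values: np.ndarray = field(repr=False)
    modality_offsets: tuple[int, ...] = ()

    def slice_of(self, j: int) -> np.ndarray:
        offs = (*self.modality_offsets, self.values.shape[-1])
        return self.values[..., offs[j] : offs[j + 1]]


@dataclass
class ConfusionModel:
    """Estimated decision probabilities of one unimodal classifier.

    ``matrix[i, k]`` is P_j(decide class i | true class k); each column
    sums to 1. Laplace smoothing keeps every entry strictly positive so
    the DI-MAP product likelihood never collapses to zero on decision
    patterns absent from the estimation data.
    """

    modality_id: int
    matrix: np.ndarray = field(repr=False)
    smoothing: float = 1.0

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]


def fi_concat(features_by_modality: list[np.ndarray]) -> FusedFeature:
    """Concatenate per-modality feature vectors (or batches) in order."""
    if not features_by_modality:
        raise ValueError("need at least one modality")
    arrs = [np.asarray(f, dtype=float) for f in features_by_modality]
    offsets, total = [], 0
    for a in arrs:
        offsets.append(total)
        total += a.shape[-1]
    return FusedFeature(
        values=np.concatenate(arrs, axis=-1),
        modality_offsets=tuple(offsets),
    )


def fit_fi_map(
    fused_features: np.ndarray | FusedFeature,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
    shrinkage: float = 0.1,
) -> list[GaussianClassConditional]:
    """Gaussian class models on the fused feature space.

    The per-class covariance of the fused vector is a full D x D matrix
    of within- and cross-modality blocks, estimated directly from the
    fused training vectors (the empirical estimate captures any shared
    noise across modalities; with independent channel noise the
    off-diagonal blocks converge to zero).
    """
    values = (
        fused_features.values
        if isinstance(fused_features, FusedFeature)
        else np.asarray(fused_features, dtype=float)
    )
    return fit_gaussian_map(values, labels, priors=priors, shrinkage=shrinkage)


def fi_classify(
    fused: np.ndarray | FusedFeature,
    backend: MLPModel | list[GaussianClassConditional],
) -> np.ndarray:
    """Posterior of the fused classifier (MLP or MAP backend)."""
    values = fused.values if isinstance(fused, FusedFeature) else np.asarray(fused, dtype=float)
    if isinstance(backend, MLPModel):
        return mlp_forward(values, backend)
    return map_posterior(values, backend)


def di_concat_posteriors(posteriors_by_modality: list[np.ndarray]) -> np.ndarray:
    """Concatenate unimodal posterior blocks into the K*J soft vector Z."""
    if not posteriors_by_modality:
        raise ValueError("need at least one modality")
    arrs = [np.asarray(p, dtype=float) for p in posteriors_by_modality]
    k = arrs[0].shape[-1]
    for a in arrs:
        if a.shape[-1] != k:
            raise ValueError("inconsistent number of classes across modalities")
        sums = a.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each block must be a valid posterior (sum to 1)")
    return np.concatenate(arrs, axis=-1)


def train_di_mlp(
    soft_decision_stages: list[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> MLPTrainResult:
    """Train the second-stage MLP on concatenated unimodal posteriors.

    Inputs are the K*J soft decision vectors produced by the already
    trained unimodal MLPs on the training stimuli; training follows the
    same curriculum procedure as the unimodal networks.
    """
    return train_mlp(soft_decision_stages, config)


def estimate_confusion(
    decisions: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    smoothing: float = 1.0,
    modality_id: int = 0,
) -> ConfusionModel:
    """Estimate P_j(decide i | true k) from labeled unimodal decisions.

    Entry (i, k) is ``(count(decide=i, true=k) + eps) / (count(true=k) +
    eps*K)`` — Laplace smoothing with pseudo-count ``eps``. Every true
    class must appear at least once in the estimation data.
    """
    dec = np.asarray(decisions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if dec.shape != lab.shape:
        raise ValueError("decisions and labels length mismatch")
    present = np.unique(lab)
    missing = set(range(n_classes)) - set(present.tolist())
    if missing:
        raise ValueError(f"classes absent from estimation data: {sorted(missing)}")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (dec, lab), 1.0)
    col_n = counts.sum(axis=0)
    matrix = (counts + smoothing) / (col_n + smoothing * n_classes)
    return ConfusionModel(modality_id=modality_id, matrix=matrix, smoothing=smoothing)


def di_map_likelihood(
    hard_decisions: np.ndarray, confusions: list[ConfusionModel]
) -> np.ndarray:
    """Joint likelihood P(Z | w_k) = prod_j P_j(y_j | w_k) for each k.

    ``hard_decisions`` holds one decided class index per modality; for a
    batch, shape (n, J). Returns likelihoods over the K candidate true
    classes (shape (..., K)).
    """
    z = np.atleast_2d(np.asarray(hard_decisions, dtype=int))
    if z.shape[-1] != len(confusions):
        raise ValueError("one decision per modality required")
    k = confusions[0].n_classes
    lik = np.ones((z.shape[0], k))
    for j, cm in enumerate(confusions):
        if cm.n_classes != k:
            raise ValueError("confusion matrices disagree on K")
        lik *= cm.matrix[z[:, j], :]
    return lik


def di_map_posterior(
    hard_decisions: np.ndarray,
    confusions: list[ConfusionModel],
    priors: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior of the discrete second-stage MAP classifier.

    Normalizes the prior-weighted confusion-product likelihood over the
    K candidate classes. Raises when the joint likelihood is identically
    zero, which can only happen with unsmoothed confusion estimates.
    """
    single = np.asarray(hard_decisions).ndim == 1
    lik = di_map_likelihood(hard_decisions, confusions)
    k = lik.shape[-1]
    priors = np.full(k, 1.0 / k) if priors is None else np.asarray(priors, dtype=float)
    joint = lik * priors
    norm = joint.sum(axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError(
            "all-zero joint likelihood; estimate confusions with smoothing > 0"
        )
    post = joint / norm
    return post[0] if single else post
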