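"""Unimodal sensory channel: attenuation, noise, DCT features, normalization.

The processing chain for one modality is

    S  --alpha-->  alpha*S  --+N(0,Psi)-->  S~  --Phi-->  S^  --m,c-->  X

where ``Phi`` is a row-selection of the orthonormal DCT-II basis (features
are the most class-separable DCT coefficients of the raw signal) and
``(m, c)`` is a single affine normalizer per modality mapping the training
feature range onto a fixed interval [a, b].

Because every step is linear, a Gaussian stimulus model propagates in
closed form: for a class prototype S with noise covariance Psi the
classifier input is Gaussian with mean ``m * Phi S + c`` and covariance
``m^2 * Phi Psi Phi^T``. :func:`propagate_density` computes exactly that,
and the Monte-Carlo agreement of this analytic density with simulated
channel outputs is the channel's core correctness property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "ModalitySpec",
    "FeatureTransform",
    "PropagatedDensity",
    "attenuate",
    "add_noise",
    "build_dct_basis",
    "dct_rows",
    "rank_coefficients",
    "extract_features",
    "fit_normalizer",
    "fit_feature_transform",
    "propagate_density",
]


@dataclass
class ModalitySpec:
    """Configuration of one sensory modality's channel."""

    modality_id: int
    raw_dim: int
    feature_dim: int
    attenuation: float = 1.0
    noise_variance: float | np.ndarray = 0.0  # scalar sigma^2 or full matrix
    norm_interval: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if not 1 <= self.feature_dim <= self.raw_dim:
            raise ValueError("feature_dim must lie in [1, raw_dim]")
        a, b = self.norm_interval
        if not a < b:
            raise ValueError("norm_interval must satisfy a < b")


@dataclass
class FeatureTransform:
    """Fitted feature extractor for one modality.

    Holds the selected DCT coefficient indices (the rows of the selection
    matrix Phi), the affine normalizer (m, c) and the training feature
    range it was fitted on. ``transform`` applies the full chain
    (DCT -> select -> normalize) to raw signals.
    """

    raw_dim: int
    selected_indices: np.ndarray = field(repr=False)
    slope: float = 1.0
    intercept: float = 0.0
    interval: tuple[float, float] = (0.0, 1.0)
    fitted_min: float = 0.0
    fitted_max: float = 1.0

    @property
    def feature_dim(self) -> int:
        return len(self.selected_indices)

    @property
    def selection_matrix(self) -> np.ndarray:
        """The D x d matrix Phi of selected orthonormal DCT basis rows."""
        return dct_rows(self.raw_dim, self.selected_indices)

    def extract(self, signals: np.ndarray) -> np.ndarray:
        """Raw selected DCT coefficients, Phi @ signal (no normalization)."""
        return extract_features(signals, self)

    def transform(self, signals: np.ndarray) -> np.ndarray:
        """Normalized classifier-input features, m * (Phi @ signal) + c."""
        return self.slope * self.extract(signals) + self.intercept


@dataclass(frozen=True)
class PropagatedDensity:
    """Analytic Gaussian density of classifier-input features for a class."""

    class_index: int
    mean: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)


def attenuate(signal: np.ndarray, alpha: float) -> np.ndarray:
    """Scale a stimulus by the attenuation factor alpha in [0, 1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * np.asarray(signal, dtype=float)


def _as_covariance(psi: float | np.ndarray, d: int) -> np.ndarray:
    psi_arr = np.asarray(psi, dtype=float)
    if psi_arr.ndim == 0:
        if psi_arr < 0:
            raise ValueError("noise variance must be nonnegative")
        return float(psi_arr) * np.eye(d)
    if psi_arr.shape != (d, d):
        raise ValueError(f"covariance shape {psi_arr.shape} != ({d}, {d})")
    if not np.allclose(psi_arr, psi_arr.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigmin = np.linalg.eigvalsh(psi_arr).min()
    if eigmin < -1e-10:
        raise ValueError("covariance must be positive semidefinite")
    return psi_arr


def add_noise(
    signal: np.ndarray, psi: float | np.ndarray, rng_seed: int
) -> np.ndarray:
    """Add one seeded draw of Gaussian noise N(0, Psi) to a signal.

    ``psi`` is either a scalar variance (isotropic noise) or a full
    covariance matrix matching the signal dimension.
    """
    x = np.asarray(signal, dtype=float)
    d = x.shape[-1]
    rng = np.random.default_rng(rng_seed)
    psi_arr = np.asarray(psi, dtype=float)
    if psi_arr.ndim == 0:
        if psi_arr < 0:
            raise ValueError("noise variance must be nonnegative")
        if psi_arr == 0:
            return x.copy()
        return x + rng.normal(0.0, np.sqrt(float(psi_arr)), size=x.shape)
    cov = _as_covariance(psi_arr, d)
    noise = rng.multivariate_normal(
        np.zeros(d), cov, size=x.shape[:-1] or None, method="eigh"
    )
    return x + noise


def build_dct_basis(d: int) -> np.ndarray:
    """Full d x d orthonormal DCT-II basis matrix (rows are basis vectors)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return scipy.fft.dct(np.eye(d), type=2, norm="ortho", axis=1).T


def dct_rows(d: int, indices: np.ndarray) -> np.ndarray:
    """Selected rows of the orthonormal DCT-II basis, by closed form."""
    idx = np.asarray(indices, dtype=int)
    n = np.arange(d)
    rows = np.cos(np.pi * idx[:, None] * (2 * n[None, :] + 1) / (2 * d))
    scale = np.where(idx == 0, np.sqrt(1.0 / d), np.sqrt(2.0 / d))
    return scale[:, None] * rows


def _dct(signals: np.ndarray) -> np.ndarray:
    return scipy.fft.dct(np.asarray(signals, dtype=float), type=2, norm="ortho", axis=-1)


def rank_coefficients(
    per_class_transformed: dict[int, np.ndarray] | np.ndarray,
    n_select: int,
    labels: np.ndarray | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """Rank DCT coefficients by class separability and return the top D.

    The score per coefficient is a Fisher-style ratio: variance of the
    class means (between-class) divided by the pooled within-class
    variance plus ``eps``. Input is either a mapping class -> (n_k, d)
    array, or a single (n, d) array with a parallel ``labels`` vector.
    Returned indices are in descending score order, ties broken by the
    lower coefficient index.
    """
    if isinstance(per_class_transformed, dict):
        groups = {
            k: np.atleast_2d(np.asarray(v, dtype=float))
            for k, v in per_class_transformed.items()
        }
    else:
        arr = np.asarray(per_class_transformed, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a flat array")
        lab = np.asarray(labels)
        groups = {int(k): arr[lab == k] for k in np.unique(lab)}
    if not groups:
        raise ValueError("no classes provided")
    d = next(iter(groups.values())).shape[1]
    if not 1 <= n_select <= d:
        raise ValueError(f"n_select must lie in [1, {d}]")
    class_means = np.stack([g.mean(axis=0) for g in groups.values()])
    between = class_means.var(axis=0)
    within = np.zeros(d)
    n_total = 0
    for g in groups.values():
        if g.shape[0] > 1:
            within += (g.shape[0] - 1) * g.var(axis=0, ddof=1)
        n_total += g.shape[0]
    denom = max(n_total - len(groups), 1)
    within /= denom
    score = between / (within + eps)
    # stable sort on (-score, index): descending score, lowest index on ties
    order = np.lexsort((np.arange(d), -score))
    return order[:n_select]


def extract_features(
    signals: np.ndarray, transform: FeatureTransform
) -> np.ndarray:
    """Project signals onto the selected DCT coefficients (Phi @ signal).

    Computed with the fast DCT then index selection, which is exactly
    equivalent to multiplying by the selection matrix Phi.
    """
    x = np.asarray(signals, dtype=float)
    if x.shape[-1] != transform.raw_dim:
        raise ValueError(
            f"signal dimension {x.shape[-1]} != raw_dim {transform.raw_dim}"
        )
    return _dct(x)[..., transform.selected_indices]


def fit_normalizer(
    features: np.ndarray, a: float, b: float
) -> tuple[float, float]:
    """Affine map (m, c) sending the global feature min/max onto [a, b].

    m and c are the slope and intercept of the line through
    (min, a) and (max, b), pooled over every entry of the training
    feature matrix — one normalizer per modality, shared by all classes.
    """
    if not a < b:
        raise ValueError("interval must satisfy a < b")
    feats = np.asarray(features, dtype=float)
    lo, hi = float(feats.min()), float(feats.max())
    if hi == lo:
        raise ValueError("degenerate feature range: max equals min")
    m = (b - a) / (hi - lo)
    c = a - m * lo
    return m, c


def fit_feature_transform(
    signals: np.ndarray,
    labels: np.ndarray,
    feature_dim: int,
    interval: tuple[float, float] = (0.0, 1.0),
) -> FeatureTransform:
    """Fit the full channel transform on a labeled training set.

    Ranks DCT coefficients on the (noisy) training signals, keeps the
    ``feature_dim`` most separable ones, then fits the interval
    normalizer on the selected training features.
    """
    x = np.asarray(signals, dtype=float)
    coeffs = _dct(x)
    idx = rank_coefficients(coeffs, feature_dim, labels=labels)
    raw_feats = coeffs[:, idx]
    m, c = fit_normalizer(raw_feats, *interval)
    return FeatureTransform(
        raw_dim=x.shape[1],
        selected_indices=idx,
        slope=m,
        intercept=c,
        interval=interval,
        fitted_min=float(raw_feats.min()),
        fitted_max=float(raw_feats.max()),
    )


def propagate_density(
    prototype: np.ndarray,
    psi: float | np.ndarray,
    transform: FeatureTransform,
    class_index: int = 0,
) -> PropagatedDensity:
    """Analytic Gaussian density of the channel output for one prototype.

    With unattenuated input (the parameter-estimation convention), noise
    N(0, Psi) and the fitted affine chain, the classifier input is
    Gaussian with mean ``m Phi S + c`` and covariance ``m^2 Phi Psi Phi^T``.
    For isotropic noise the covariance collapses to ``m^2 sigma^2 I``
    because the selected DCT rows are orthonormal.
    """
    s = np.asarray(prototype, dtype=float)
    m, c = transform.slope, transform.intercept
    mean = m * extract_features(s, transform) + c
    psi_arr = np.asarray(psi, dtype=float)
    if psi_arr.ndim == 0:
        if psi_arr < 0:
            raise ValueError("noise variance must be nonnegative")
        cov = (m**2 * float(psi_arr)) * np.eye(transform.feature_dim)
    else:
        phi = transform.selection_matrix
        cov = m**2 * phi @ _as_covariance(psi_arr, s.shape[-1]) @ phi.T
    return PropagatedDensity(class_index=class_index, mean=mean, covariance=cov)
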