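"""Vocabulary fitting and per-subregion encoding.

The generative vocabulary is a diagonal-covariance Gaussian mixture fitted
by EM on reduced patch descriptors.  Each subregion's descriptor set X =
{x_t} is aggregated into a Fisher vector: the gradient of the average
log-likelihood (1/T) log u_lambda(X) with respect to the component means
and variances, whitened by the diagonal closed-form approximation of the
Fisher information matrix.  With gamma_t(k) the posterior of component k,

    g_mu_k    = 1/(T sqrt(w_k))   * sum_t gamma_t(k) (x_t - mu_k) / sigma_k
    g_sigma_k = 1/(T sqrt(2 w_k)) * sum_t gamma_t(k) [(x_t - mu_k)^2 / sigma_k^2 - 1]

(all operations element-wise), giving a 2*d*K vector per subregion.  Only
mean and variance gradients are used; mixture-weight gradients are omitted.
A k-means bag-of-words histogram (hard assignment, K bins) is provided as
the baseline; for a matched signature length BoW needs 2*d times more
visual words than FV.

The concatenated per-subregion encodings are power-normalized
(sign(z)|z|^alpha) and L2-normalized into the image signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .config import PipelineConfig
from .data import TumorCase
from .patches import PatchSet, PcaModel, apply_pca, extract_patches
from .pooling import divide_by_intensity_order
from .roi import augment_tumor_region

__all__ = [
    "GmmModel",
    "FisherVector",
    "BowHistogram",
    "ImageSignature",
    "fit_gmm",
    "fit_bow_vocabulary",
    "posterior",
    "posteriors",
    "encode_fv",
    "encode_bow",
    "normalize_signature",
    "build_signature",
]

#: posterior responsibilities below this are truncated to exact zero
_GAMMA_FLOOR = 1e-12


@dataclass
class GmmModel:
    """Diagonal-covariance GMM: the probabilistic visual vocabulary."""

    weights: np.ndarray  # (K,), positive, sums to 1
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d), positive

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("GMM weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("GMM variances must be positive")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class FisherVector:
    values: np.ndarray  # (2*d*K,)
    subregion: int = 0


@dataclass
class BowHistogram:
    counts: np.ndarray  # (K,), sums to T
    subregion: int = 0


@dataclass
class ImageSignature:
    """Normalized concatenation of the N per-subregion encodings."""

    values: np.ndarray
    case_ref: str = ""


def fit_gmm(features: np.ndarray, K: int, seed: int) -> GmmModel:
    """ML-fit a K-component diagonal GMM by EM (k-means initialization).

    A variance floor of 1e-6 times the mean per-dimension data variance
    guards against collapsing components.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the {X.shape[0]} available descriptors")
    floor = 1e-6 * max(float(X.var(axis=0).mean()), np.finfo(float).tiny)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        init_params="kmeans",
        n_init=1,
        tol=1e-6,
        max_iter=200,
        reg_covar=floor,
        random_state=int(seed),
    )
    gm.fit(X)
    return GmmModel(weights=gm.weights_, means=gm.means_, variances=gm.covariances_)


def fit_bow_vocabulary(features: np.ndarray, K: int, seed: int) -> np.ndarray:
    """k-means visual vocabulary: a (K, d) matrix of centroids."""
    X = np.asarray(features, dtype=float)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the {X.shape[0]} available descriptors")
    km = KMeans(n_clusters=K, n_init=3, random_state=int(seed))
    km.fit(X)
    return km.cluster_centers_


def _log_gaussians(model: GmmModel, X: np.ndarray) -> np.ndarray:
    """log [w_k u_k(x_t)] for each descriptor/component pair, shape (T, K)."""
    diff = X[:, None, :] - model.means[None, :, :]  # (T, K, d)
    maha = (diff * diff / model.variances[None, :, :]).sum(axis=2)
    log_norm = -0.5 * (
        model.d * np.log(2 * np.pi) + np.log(model.variances).sum(axis=1)
    )
    return np.log(model.weights)[None, :] + log_norm[None, :] - 0.5 * maha


def posteriors(model: GmmModel, X: np.ndarray) -> np.ndarray:
    """Soft assignments gamma_t(k), rows summing to 1 (log-domain, safe)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    log_wu = _log_gaussians(model, X)
    gamma = np.exp(log_wu - logsumexp(log_wu, axis=1, keepdims=True))
    gamma[gamma < _GAMMA_FLOOR] = 0.0
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def posterior(model: GmmModel, x: np.ndarray) -> np.ndarray:
    """Soft assignment of a single descriptor to the K components."""
    return posteriors(model, np.asarray(x, dtype=float)[None, :])[0]


def encode_fv(model: GmmModel, patches: PatchSet) -> FisherVector:
    """Fisher vector of a descriptor set under the GMM vocabulary.

    An empty patch set yields the zero vector (with a warning): a gradient
    of nothing carries no evidence.
    """
    K, d = model.K, model.d
    X = patches.descriptors
    if X.shape[0] == 0:
        warnings.warn("empty patch set: returning a zero Fisher vector")
        return FisherVector(values=np.zeros(2 * d * K), subregion=patches.origin)
    if X.shape[1] != d:
        raise ValueError(f"descriptor dim {X.shape[1]} != model dim {d}")
    T = X.shape[0]
    gamma = posteriors(model, X)  # (T, K)
    sigma = np.sqrt(model.variances)  # (K, d)
    diff = (X[:, None, :] - model.means[None, :, :]) / sigma[None, :, :]
    g_mu = (gamma[:, :, None] * diff).sum(axis=0) / (
        T * np.sqrt(model.weights)[:, None]
    )  # (K, d)
    g_sigma = (gamma[:, :, None] * (diff * diff - 1.0)).sum(axis=0) / (
        T * np.sqrt(2.0 * model.weights)[:, None]
    )
    values = np.concatenate([np.concatenate([g_mu[k], g_sigma[k]]) for k in range(K)])
    return FisherVector(values=values, subregion=patches.origin)


def encode_bow(vocabulary: np.ndarray, patches: PatchSet) -> BowHistogram:
    """Hard-assignment histogram over the k-means vocabulary.

    Ties in the nearest-centroid assignment go to the lowest centroid index.
    """
    vocab = np.asarray(vocabulary, dtype=float)
    X = patches.descriptors
    K = vocab.shape[0]
    if X.shape[0] == 0:
        return BowHistogram(counts=np.zeros(K), subregion=patches.origin)
    if X.shape[1] != vocab.shape[1]:
        raise ValueError("descriptor dim does not match vocabulary dim")
    d2 = ((X[:, None, :] - vocab[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)  # argmin returns the lowest index on ties
    counts = np.bincount(assign, minlength=K).astype(float)
    return BowHistogram(counts=counts, subregion=patches.origin)


def normalize_signature(v: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Power-normalize each component (sign(z)|z|^alpha) then L2-normalize.

    The zero vector maps to itself.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    v = np.asarray(v, dtype=float)
    out = np.sign(v) * np.abs(v) ** alpha
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def build_signature(
    case: TumorCase,
    config: PipelineConfig,
    pca: PcaModel,
    model: GmmModel | np.ndarray,
) -> ImageSignature:
    """Full per-image encoding: ROI -> partition -> patches -> PCA -> encode.

    The N per-subregion encodings (FV of length 2*d*K, or BoW of length K)
    are concatenated in intensity-bin order and normalized: power + L2 for
    Fisher vectors, plain L2 for bag-of-words histograms.
    """
    roi = augment_tumor_region(case.tumor_mask, config.R)
    partition = divide_by_intensity_order(case.image, roi, config.N)
    blocks = []
    for i, pixels in enumerate(partition.subregions):
        raw = extract_patches(case.image, pixels, config.W, stride=config.stride)
        raw.origin = i
        reduced = apply_pca(pca, raw)
        if config.encoder == "fv":
            blocks.append(encode_fv(model, reduced).values)
        else:
            blocks.append(encode_bow(model, reduced).counts)
    flat = np.concatenate(blocks)
    if config.encoder == "fv":
        values = normalize_signature(flat, config.alpha)
    else:
        norm = np.linalg.norm(flat)
        values = flat / norm if norm > 0 else flat
    return ImageSignature(values=values, case_ref=case.patient_id)
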