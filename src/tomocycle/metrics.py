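"""Generative-model evaluation metrics.

Embedding-space metrics follow the k-NN-manifold formulation: the real
manifold is the union of balls B(X_i, NND_k(X_i)) around each real embedding
X_i with radius equal to the distance to its k-th nearest neighbour (a point
is not its own neighbour). Precision is the fraction of fake embeddings Y_j
inside the real manifold; recall is the mirror statement with the fake
manifold; density counts, per fake sample, how many real neighbourhoods
contain it (normalized by k·M, so it can exceed 1); coverage is the fraction
of real neighbourhoods containing at least one fake sample. Boundary points
(distance exactly equal to the radius) count as inside.

The inception score is ``exp(E_x KL(p(y|x) || p(y)))`` over a classifier's
class posteriors for generated samples; the Frechet distance compares
Gaussian moment matches of real and generated embeddings,
``||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^(1/2))``. SSIM uses standard
3D windows. Because the two domains are unpaired, the suite-level SSIM pairs
each generated volume with the nearest same-class real exemplar in embedding
space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage.metrics import structural_similarity

from .volume import DomainDataset, Volume

__all__ = [
    "EmbeddingSet",
    "ManifoldIndex",
    "GaussianMoments",
    "knn_radii",
    "precision",
    "recall",
    "density",
    "coverage",
    "inception_score",
    "fid",
    "moments",
    "ssim3d",
    "classification_accuracy",
    "evaluate_suite",
    "REPORT_KEYS",
]

REPORT_KEYS = (
    "ssim", "precision", "recall", "density", "coverage",
    "classification_accuracy", "inception_score", "fid",
)


@dataclass
class EmbeddingSet:
    """N x d matrix of feature vectors with a source tag."""

    vectors: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if not np.isfinite(self.vectors).all():
            raise ValueError("embeddings must be finite")


@dataclass
class ManifoldIndex:
    """k-NN manifold over a set of centres: per-centre radii NND_k."""

    centers: np.ndarray
    radii: np.ndarray
    k: int


@dataclass
class GaussianMoments:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64).ravel()
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=np.float64))
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    return x


def knn_radii(X, k: int) -> ManifoldIndex:
    """Distance to the k-th nearest neighbour for every point (self excluded)."""
    X = _as_matrix(X)
    n = len(X)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < N, got k={k}, N={n}")
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    radii = np.sort(d, axis=1)[:, k - 1]
    if np.any(radii == 0):
        warnings.warn("duplicate points produce zero k-NN radii", stacklevel=2)
    return ManifoldIndex(centers=X, radii=radii, k=k)


def _membership(index: ManifoldIndex, Y: np.ndarray) -> np.ndarray:
    """Boolean (M, N): Y_j inside ball i (boundary counts as inside)."""
    d = cdist(_as_matrix(Y), index.centers)
    return d <= index.radii[None, :]


def precision(X, Y, k: int) -> float:
    """Fraction of fake samples lying on the real k-NN manifold."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty embedding set")
    inside = _membership(knn_radii(X, k), Y)
    return float(inside.any(axis=1).mean())


def recall(X, Y, k: int) -> float:
    """Fraction of real samples lying on the fake k-NN manifold."""
    return precision(Y, X, k)


def density(X, Y, k: int) -> float:
    """Mean number of real neighbourhoods containing each fake sample, / k."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty embedding set")
    inside = _membership(knn_radii(X, k), Y)
    return float(inside.sum() / (k * len(Y)))


def coverage(X, Y, k: int) -> float:
    """Fraction of real neighbourhoods containing at least one fake sample."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty embedding set")
    inside = _membership(knn_radii(X, k), Y)
    return float(inside.any(axis=0).mean())


def inception_score(probs) -> float:
    """exp of the mean KL divergence between per-sample posteriors and the
    marginal; lies in [1, C] for C classes. Zero entries contribute 0·log 0 = 0."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2 or p.size == 0:
        raise ValueError("probs must be a nonempty (N, C) table")
    if np.any(p < -1e-9) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must be probability distributions")
    p = np.clip(p, 0.0, None)
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(p > 0, np.log(p / marginal), 0.0)
    kl = (p * logratio).sum(axis=1)
    return float(np.exp(kl.mean()))


def moments(vectors) -> GaussianMoments:
    """Empirical mean and covariance of an embedding set."""
    v = _as_matrix(vectors)
    return GaussianMoments(mu=v.mean(axis=0), sigma=np.cov(v, rowvar=False).reshape(
        v.shape[1], v.shape[1]))


def _sqrt_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    if vals.min() < -1e-8 * max(1.0, abs(vals.max())):
        warnings.warn("clipping negative covariance eigenvalues", stacklevel=3)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(moments_real: GaussianMoments, moments_fake: GaussianMoments) -> float:
    """Frechet distance between two Gaussians.

    The trace term Tr((S_r S_g)^(1/2)) is evaluated exactly through the
    similarity transform S_r^(1/2) S_g S_r^(1/2), which is symmetric PSD and
    shares the spectrum of S_r S_g; negative eigenvalues from numerical noise
    are clipped to zero with a warning.
    """
    mu_r, s_r = moments_real.mu, moments_real.sigma
    mu_g, s_g = moments_fake.mu, moments_fake.sigma
    if mu_r.shape != mu_g.shape:
        raise ValueError(f"embedding dims differ: {mu_r.shape[0]} vs {mu_g.shape[0]}")
    diff = float(((mu_r - mu_g) ** 2).sum())
    root_r = _sqrt_psd(s_r)
    inner = root_r @ s_g @ root_r
    vals = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    if vals.min() < -1e-8 * max(1.0, abs(vals.max())):
        warnings.warn("clipping negative eigenvalues in FID trace term", stacklevel=2)
    tr_root = np.sqrt(np.clip(vals, 0.0, None)).sum()
    # the distance is nonnegative by construction; rank-deficient empirical
    # covariances can leave a tiny negative residue
    return float(max(0.0, diff + np.trace(s_r) + np.trace(s_g) - 2.0 * tr_root))


def ssim3d(a: np.ndarray, b: np.ndarray, window: int = 7,
           data_range: float | None = None) -> float:
    """Mean local structural similarity over sliding 3D windows."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    return float(structural_similarity(a, b, win_size=window, data_range=data_range))


def classification_accuracy(classifier, generated: DomainDataset) -> float:
    """Fraction of generated volumes classified as their source class.

    ``classifier`` must expose ``predict(list_of_volumes) -> labels``; the
    dataset's labels are the classes of the source density maps.
    """
    if len(generated) == 0:
        raise ValueError("empty generated dataset")
    if generated.labels is None:
        raise ValueError("generated dataset must carry source-class labels")
    predicted = list(classifier.predict(generated.volumes))
    hits = sum(p == t for p, t in zip(predicted, generated.labels))
    return hits / len(generated)


def _paired_ssim(real: DomainDataset, generated: DomainDataset,
                 emb_real: np.ndarray, emb_gen: np.ndarray) -> float:
    """Mean SSIM of each generated volume vs its nearest same-class real one."""
    d = cdist(emb_gen, emb_real)
    if generated.labels is not None and real.labels is not None:
        gl = np.asarray(generated.labels)
        rl = np.asarray(real.labels)
        mask = gl[:, None] != rl[None, :]
        d = np.where(mask, np.inf, d)
    # rows with no same-class partner fall back to the global nearest
    no_partner = ~np.isfinite(d).any(axis=1)
    if no_partner.any():
        d[no_partner] = cdist(emb_gen[no_partner], emb_real)
    nearest = d.argmin(axis=1)
    vals = [
        ssim3d(g.data, real.volumes[j].data)
        for g, j in zip(generated.volumes, nearest)
    ]
    return float(np.mean(vals))


def per_sample_report(real: DomainDataset, generated: DomainDataset,
                      embedder, k: int = 5):
    """Per-generated-sample metric contributions as a DataFrame.

    Columns: nearest same-class real index, SSIM against it, whether the
    sample lies on the real k-NN manifold, predicted class and its
    posterior, and the source label when present.
    """
    import pandas as pd

    emb_real = np.asarray(embedder.features(real.volumes), dtype=np.float64)
    emb_gen = np.asarray(embedder.features(generated.volumes), dtype=np.float64)
    index = knn_radii(emb_real, k)
    inside = _membership(index, emb_gen)
    d = cdist(emb_gen, emb_real)
    if generated.labels is not None and real.labels is not None:
        gl = np.asarray(generated.labels)
        rl = np.asarray(real.labels)
        d = np.where(gl[:, None] != rl[None, :], np.inf, d)
    nearest = d.argmin(axis=1)
    probs = np.asarray(embedder.predict_proba(generated.volumes), dtype=np.float64)
    predicted = list(embedder.predict(generated.volumes))
    rows = []
    for j, g in enumerate(generated.volumes):
        rows.append({
            "sample": j,
            "label": generated.labels[j] if generated.labels else "",
            "nearest_real": int(nearest[j]),
            "ssim_nearest": ssim3d(g.data, real.volumes[nearest[j]].data),
            "in_real_manifold": bool(inside[j].any()),
            "n_real_balls_containing": int(inside[j].sum()),
            "predicted_class": predicted[j],
            "predicted_prob": float(probs[j].max()),
        })
    return pd.DataFrame(rows)


def evaluate_suite(real: DomainDataset, generated: DomainDataset,
                   embedder, k: int = 5) -> dict[str, float]:
    """All eight metrics in one report.

    ``embedder`` must expose ``features(volumes) -> (N, d)`` and
    ``predict_proba(volumes) -> (N, C)``; classification additionally uses
    ``predict``. Returns a dict with exactly the keys in ``REPORT_KEYS``.
    """
    if len(real) == 0 or len(generated) == 0:
        raise ValueError("empty dataset")
    emb_real = np.asarray(embedder.features(real.volumes), dtype=np.float64)
    emb_gen = np.asarray(embedder.features(generated.volumes), dtype=np.float64)
    if emb_real.shape[1] != emb_gen.shape[1]:
        raise ValueError(
            f"embedding dims differ: {emb_real.shape[1]} vs {emb_gen.shape[1]}"
        )
    probs = np.asarray(embedder.predict_proba(generated.volumes), dtype=np.float64)
    report = {
        "ssim": _paired_ssim(real, generated, emb_real, emb_gen),
        "precision": precision(emb_real, emb_gen, k),
        "recall": recall(emb_real, emb_gen, k),
        "density": density(emb_real, emb_gen, k),
        "coverage": coverage(emb_real, emb_gen, k),
        "classification_accuracy": classification_accuracy(embedder, generated)
        if generated.labels is not None else float("nan"),
        "inception_score": inception_score(probs),
        "fid": fid(moments(emb_real), moments(emb_gen)),
    }
    assert tuple(report) == REPORT_KEYS
    return report
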