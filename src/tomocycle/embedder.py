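"""Pluggable volume embedders for the evaluation suite.

The evaluation metrics need two maps: volume -> feature vector and
volume -> class probabilities. Any object with ``features``,
``predict_proba`` and ``predict`` works; two implementations are provided.

:class:`ConvEmbedder` is a small 3D convolutional classifier trained on
labeled real volumes; its penultimate dense activations are the embedding
(dimension configurable). It plays the role that a large pretrained
classifier plays for natural-image metrics.

:class:`CentroidEmbedder` is a deterministic, training-free baseline: it
embeds volumes by average-pooled voxels and scores classes by softmax over
negative distances to class centroids. Useful for fast tests and as a sanity
cross-check.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv3d, InstanceNorm3d, Linear, ReLU, RMSProp, Sequential
from .volume import DomainDataset, Volume

__all__ = ["ConvEmbedder", "CentroidEmbedder"]


def _stack(volumes) -> np.ndarray:
    return np.stack([v.data for v in volumes]).astype(np.float32)[:, None]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvEmbedder:
    """Small 3D conv classifier; penultimate activations are the embedding."""

    def __init__(self, n: int, classes: list[str], feature_dim: int = 64,
                 width: int = 8, seed: int = 0):
        if n % 4 != 0:
            raise ValueError("side length must be divisible by 4")
        self.n = n
        self.classes = list(classes)
        self.feature_dim = feature_dim
        rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
        flat = 2 * width * (n // 4) ** 3
        self.trunk = Sequential(
            Conv3d(1, width, 3, stride=2, pad=1, rng=rng),
            InstanceNorm3d(), ReLU(),
            Conv3d(width, 2 * width, 3, stride=2, pad=1, rng=rng),
            InstanceNorm3d(), ReLU(),
        )
        self.head_feat = Sequential(Linear(flat, feature_dim, rng=rng), ReLU())
        self.head_cls = Linear(feature_dim, len(self.classes), rng=rng)

    def _forward(self, x: np.ndarray):
        h, c1 = self.trunk.forward(x)
        flat = h.reshape(len(x), -1)
        feats, c2 = self.head_feat.forward(flat)
        logits, c3 = self.head_cls.forward(feats)
        return h, flat, feats, logits, (c1, c2, c3)

    def fit(self, dataset: DomainDataset, epochs: int = 30, batch_size: int = 8,
            lr: float = 1e-3, seed: int = 0) -> list[float]:
        """Train with softmax cross-entropy on a labeled dataset."""
        if dataset.labels is None:
            raise ValueError("embedder training needs class labels")
        x = _stack(dataset.volumes)
        label_idx = np.array([self.classes.index(l) for l in dataset.labels])
        rng = np.random.default_rng(seed)
        opts = [RMSProp(self.trunk, lr=lr), RMSProp(self.head_feat, lr=lr),
                RMSProp(self.head_cls, lr=lr)]
        losses = []
        for _ in range(epochs):
            order = rng.permutation(len(x))
            epoch_loss = 0.0
            for start in range(0, len(x) - batch_size + 1, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], label_idx[idx]
                h, flat, feats, logits, (c1, c2, c3) = self._forward(xb)
                p = _softmax(logits.astype(np.float64))
                epoch_loss += -np.log(p[np.arange(len(yb)), yb] + 1e-12).sum()
                g_logits = p.copy()
                g_logits[np.arange(len(yb)), yb] -= 1.0
                g_logits = (g_logits / len(yb)).astype(np.float32)
                for layer in (self.trunk, self.head_feat, self.head_cls):
                    layer.zero_grad()
                g_feats = self.head_cls.backward(g_logits, c3)
                g_flat = self.head_feat.backward(g_feats, c2)
                self.trunk.backward(g_flat.reshape(h.shape), c1)
                for opt in opts:
                    opt.step()
            losses.append(epoch_loss / len(x))
        return losses

    def features(self, volumes) -> np.ndarray:
        _, _, feats, _, _ = self._forward(_stack(volumes))
        return feats.astype(np.float64)

    def predict_proba(self, volumes) -> np.ndarray:
        _, _, _, logits, _ = self._forward(_stack(volumes))
        return _softmax(logits.astype(np.float64))

    def predict(self, volumes) -> list[str]:
        idx = self.predict_proba(volumes).argmax(axis=1)
        return [self.classes[i] for i in idx]


class CentroidEmbedder:
    """Average-pooled voxel embedding with nearest-centroid class posteriors."""

    def __init__(self, pool: int = 4, temperature: float = 1.0):
        self.pool = pool
        self.temperature = temperature
        self.classes: list[str] = []
        self._centroids: np.ndarray | None = None

    def _embed_one(self, v: Volume) -> np.ndarray:
        n = v.side
        p = self.pool
        m = n - (n % p)
        x = v.data[:m, :m, :m].reshape(m // p, p, m // p, p, m // p, p)
        return x.mean(axis=(1, 3, 5)).ravel().astype(np.float64)

    def features(self, volumes) -> np.ndarray:
        return np.stack([self._embed_one(v) for v in volumes])

    def fit(self, dataset: DomainDataset) -> "CentroidEmbedder":
        if dataset.labels is None:
            raise ValueError("centroid fitting needs class labels")
        feats = self.features(dataset.volumes)
        self.classes = sorted(set(dataset.labels))
        labels = np.asarray(dataset.labels)
        self._centroids = np.stack(
            [feats[labels == c].mean(axis=0) for c in self.classes]
        )
        return self

    def predict_proba(self, volumes) -> np.ndarray:
        if self._centroids is None:
            raise ValueError("fit the embedder before predicting")
        feats = self.features(volumes)
        d = np.linalg.norm(feats[:, None, :] - self._centroids[None], axis=2)
        return _softmax(-d / self.temperature)

    def predict(self, volumes) -> list[str]:
        idx = self.predict_proba(volumes).argmax(axis=1)
        return [self.classes[i] for i in idx]
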