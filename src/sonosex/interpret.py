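"""Feature-space diagnostics: activation maps, cluster-number selection,
t-SNE embedding, and silhouette scoring.

These reproduce the analysis used to understand *what* a trained classifier
responds to: intermediate activations are rendered as overlays on the frame;
intermediate feature matrices are clustered with K-means over a range of K,
choosing K by silhouette with the WCSS elbow reported alongside; t-SNE gives
the 2-D scatter. A recurring finding this supports: features can carry
enough signal for high classification accuracy while their 2-D structure
shows heavy class overlap and near-zero silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score as _sk_silhouette

from .cnn import CNNModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# activations


def extract_activations(
    model: CNNModel, frame: np.ndarray, layer_index: int, cmap: str = "viridis", alpha: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel activations of one layer for one frame, plus a rendered overlay.

    The overlay is the channel-mean activation map, min-max normalized,
    color-mapped, upsampled to the frame size, and alpha-blended onto the
    grayscale frame (uint8 RGB, same height/width as the frame).
    """
    if not (0 <= layer_index < len(model.layers)):
        raise IndexError(f"layer_index {layer_index} out of range [0, {len(model.layers)})")
    img = np.asarray(frame)
    x = img.astype(np.float32)[None, None]
    if x.max() > 1.5:
        x = x / 255.0
    _, acts = model.forward(x, collect=True)
    act = acts[layer_index][0]
    if act.ndim == 1:  # dense layer: treat as 1 x n map
        act = act[None, None, :]
    mean_map = act.mean(axis=0)
    lo, hi = float(mean_map.min()), float(mean_map.max())
    norm = (mean_map - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_map)

    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    colored = (colormaps[cmap](norm)[..., :3] * 255).astype(np.uint8)
    up = np.asarray(Image.fromarray(colored).resize((img.shape[1], img.shape[0]), Image.BILINEAR))
    gray_rgb = np.repeat(img[..., None], 3, axis=-1).astype(float)
    overlay = np.clip((1 - alpha) * gray_rgb + alpha * up.astype(float), 0, 255).astype(np.uint8)
    return act, overlay


# ---------------------------------------------------------------------------
# clustering

def extract_feature_matrix(model: CNNModel, frames, layer_index: int | None = None) -> np.ndarray:
    """Intermediate features for a batch of frames (default: the flattened,
    post-dropout output of the convolutional stack)."""
    X = np.asarray(frames, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None]
    if X.max() > 1.5:
        X = X / 255.0
    if layer_index is None:
        # the Flatten layer immediately after the dropout stage
        layer_index = model.dropout_indices[-1] + 1
    feats = []
    for i in range(0, len(X), 64):
        _, acts = model.forward(X[i : i + 64], collect=True)
        a = acts[layer_index]
        feats.append(a.reshape(a.shape[0], -1))
    return np.concatenate(feats)


@dataclass
class ClusterSelection:
    """WCSS and silhouette over the tested K range, with the selected K."""

    k_values: list[int]
    wcss: list[float]
    silhouette: list[float]
    elbow_k: int
    selected_k: int


def select_k(features: np.ndarray, k_range=range(2, 10), seed: int = 0, n_restarts: int = 10) -> ClusterSelection:
    """Choose a cluster count by silhouette, with the WCSS elbow alongside.

    K-means runs with ``n_restarts`` seeded restarts per K (best inertia
    kept). The elbow is formalized as the K of maximum second difference of
    the WCSS curve, anchored at K=1 (whose WCSS is the total sum of squares,
    needing no clustering) so the smallest tested K is eligible. If elbow and
    silhouette disagree, the disagreement is logged and the silhouette argmax
    wins.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or np.isnan(X).any():
        raise ValueError("features must be a 2-D matrix without missing values")
    ks = sorted(int(k) for k in k_range)
    if X.shape[0] <= max(ks):
        raise ValueError(f"need more points ({X.shape[0]}) than clusters ({max(ks)})")
    wcss, sil = [], []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        wcss.append(float(km.inertia_))
        sil.append(float(_sk_silhouette(X, km.labels_)))
    if len(ks) >= 2:
        anchored = wcss
        anchored_ks = ks
        if ks[0] > 1:
            tss = float(((X - X.mean(axis=0)) ** 2).sum())
            anchored = [tss] + wcss
            anchored_ks = [1] + ks
        second_diff = [
            anchored[i - 1] - 2 * anchored[i] + anchored[i + 1]
            for i in range(1, len(anchored_ks) - 1)
        ]
        elbow_k = anchored_ks[1 + int(np.argmax(second_diff))]
    else:
        elbow_k = ks[0]
    selected = ks[int(np.argmax(sil))]
    if elbow_k != selected:
        logger.info("elbow (K=%d) and silhouette (K=%d) disagree; using silhouette", elbow_k, selected)
    return ClusterSelection(ks, wcss, sil, elbow_k, selected)


def tsne_embed(features: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Seeded 2-D t-SNE embedding (PCA initialization)."""
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for n={n} (need n > 3*perplexity)")
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca", random_state=seed).fit_transform(X)
    return np.asarray(emb, dtype=float)


def silhouette_score(features: np.ndarray, labels) -> float:
    """Mean silhouette over samples: (b - a) / max(a, b) per sample, where a
    is the mean intra-cluster distance and b the smallest mean distance to
    another cluster."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if counts.min() < 1:
        raise ValueError("every cluster needs at least one member")
    return float(_sk_silhouette(X, y))
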