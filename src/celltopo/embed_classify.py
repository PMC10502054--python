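"""Dimensionality reduction, hierarchical clustering, and accuracy scoring.

Feature vectors (persistence images/curves or order parameters, one row
per simulation condition) are compressed to a 20-dimensional latent space
by PCA, UMAP, or an autoencoder, then grouped by Ward-linkage
agglomerative clustering cut at the number of ground-truth phases.
Unsupervised accuracy is scored under the optimal one-to-one
cluster-to-phase assignment (Hungarian algorithm). A soft-margin RBF SVM
with stratified cross-validation provides the supervised cross-check.

The autoencoder is a small fully connected network (ReLU hidden layers,
linear latent and output) trained full-batch with Adam on the mean squared
reconstruction error — sufficient for the feature-matrix sizes this
pipeline produces (hundreds of rows, a few hundred columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "EmbeddingConfig",
    "ClusteringResult",
    "Autoencoder",
    "standardize",
    "reduce_dimension",
    "cluster_hierarchical",
    "accuracy_vs_truth",
    "svm_crossval_accuracy",
]


@dataclass
class EmbeddingConfig:
    method: str = "autoencoder"
    latent_dim: int = 20
    ae_hidden_layers: tuple = (256, 64)
    ae_epochs: int = 400
    ae_learning_rate: float = 1e-3
    # "global": center columns, divide by the matrix-wide std — preserves
    # the relative intensity structure of image pixels. "column": classic
    # per-column z-scoring (inflates near-empty pixels; poor for
    # persistence images). False/"none": raw.
    standardize: str | bool = "global"
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.method not in ("pca", "umap", "phate", "autoencoder"):
            raise ValueError(f"unknown embedding method {self.method!r}")
        if self.standardize not in ("global", "column", "none", False, True):
            raise ValueError("standardize must be 'global', 'column' or 'none'")


@dataclass
class ClusteringResult:
    labels: np.ndarray
    n_clusters: int
    linkage: str = "ward"


def standardize(x: np.ndarray, mode: str | bool = "column") -> np.ndarray:
    """Feature scaling before embedding.

    ``"column"``: per-column zero mean / unit variance (constant columns
    map to 0). ``"global"``: per-column centering with one matrix-wide
    scale, preserving relative pixel intensities.
    """
    if mode in (False, "none"):
        return x
    mu = x.mean(axis=0)
    if mode == "global":
        sd = x.std()
        return (x - mu) / (sd if sd > 0 else 1.0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


class Autoencoder:
    """Symmetric dense autoencoder with a linear latent bottleneck."""

    def __init__(self, n_features: int, latent_dim: int = 20,
                 hidden=(256, 64), learning_rate: float = 1e-3,
                 seed: int = 0):
        self.dims = [n_features, *hidden, latent_dim,
                     *reversed(hidden), n_features]
        rng = np.random.default_rng(seed)
        self.W = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
                  for a, b in zip(self.dims[:-1], self.dims[1:])]
        self.b = [np.zeros(b) for b in self.dims[1:]]
        self.lr = learning_rate
        self.latent_layer = len(hidden) + 1  # index into activations
        self._adam = None
        self.loss_history: list[float] = []

    def _forward(self, x):
        acts = [x]
        h = x
        last = len(self.W) - 1
        for li, (w, bb) in enumerate(zip(self.W, self.b)):
            h = h @ w + bb
            # ReLU on hidden layers; latent and output stay linear
            if li != last and li != self.latent_layer - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x)[self.latent_layer]

    def fit(self, x: np.ndarray, epochs: int = 400) -> "Autoencoder":
        n = x.shape[0]
        if self._adam is None:
            self._adam = [(np.zeros_like(w), np.zeros_like(w)) for w in self.W] \
                + [(np.zeros_like(bb), np.zeros_like(bb)) for bb in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        last = len(self.W) - 1
        for _ in range(epochs):
            acts = self._forward(x)
            err = acts[-1] - x
            self.loss_history.append(float(np.mean(err**2)))
            grad = 2.0 * err / (n * x.shape[1])
            gW = [None] * len(self.W)
            gb = [None] * len(self.b)
            for li in range(last, -1, -1):
                a_in = acts[li]
                gW[li] = a_in.T @ grad
                gb[li] = grad.sum(axis=0)
                if li > 0:
                    grad = grad @ self.W[li].T
                    if li - 1 != self.latent_layer - 1:
                        grad = grad * (acts[li] > 0)
            t += 1
            params = self.W + self.b
            grads = gW + gb
            for p, g, (m, v) in zip(params, grads, self._adam):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mh = m / (1 - beta1**t)
                vh = v / (1 - beta2**t)
                p -= self.lr * mh / (np.sqrt(vh) + eps)
        return self


def reduce_dimension(features: np.ndarray,
                     config: EmbeddingConfig | None = None) -> np.ndarray:
    """Embed a feature matrix to ``latent_dim`` columns.

    PCA is deterministic; UMAP and the autoencoder are seeded. Requesting
    PHATE raises: it is dispatched to the external reference
    implementation, which must be installed separately.
    """
    config = config or EmbeddingConfig()
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    if config.latent_dim > x.shape[1]:
        raise ValueError("latent_dim exceeds feature length")
    mode = "column" if config.standardize is True else config.standardize
    x = standardize(x, mode)

    if config.method == "pca":
        k = min(config.latent_dim, x.shape[0], x.shape[1])
        z = PCA(n_components=k, random_state=config.seed).fit_transform(x)
        if k < config.latent_dim:
            z = np.pad(z, ((0, 0), (0, config.latent_dim - k)))
        return z
    if config.method == "umap":
        import umap
        reducer = umap.UMAP(n_components=config.latent_dim,
                            random_state=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(reducer.fit_transform(x), dtype=float)
    if config.method == "phate":
        try:
            import phate
        except ImportError as exc:
            raise ImportError(
                "PHATE embedding requires the external 'phate' package"
            ) from exc
        op = phate.PHATE(n_components=config.latent_dim,
                         random_state=config.seed, verbose=0)
        return np.asarray(op.fit_transform(x), dtype=float)
    # autoencoder
    ae = Autoencoder(x.shape[1], config.latent_dim, config.ae_hidden_layers,
                     config.ae_learning_rate, config.seed)
    ae.fit(x, epochs=config.ae_epochs)
    return ae.encode(x)


def cluster_hierarchical(embedding: np.ndarray, n_clusters: int) -> ClusteringResult:
    """Ward-linkage agglomeration halted at exactly ``n_clusters``."""
    embedding = np.asarray(embedding, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > embedding.shape[0]:
        raise ValueError("n_clusters exceeds the number of samples")
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return ClusteringResult(model.fit_predict(embedding), n_clusters)


def accuracy_vs_truth(predicted, truth) -> float:
    """Fraction of samples matched under the accuracy-maximizing one-to-one
    assignment between predicted clusters and ground-truth phases.

    Invariant to relabeling of either input; unmatched extra clusters (or
    phases) simply contribute no credit.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label arrays must have equal length")
    if predicted.size == 0:
        raise ValueError("empty label arrays")
    p_codes, p_inv = np.unique(predicted, return_inverse=True)
    t_codes, t_inv = np.unique(truth, return_inverse=True)
    cm = np.zeros((p_codes.size, t_codes.size), dtype=int)
    np.add.at(cm, (p_inv, t_inv), 1)
    rows, cols = linear_sum_assignment(cm, maximize=True)
    return float(cm[rows, cols].sum() / predicted.size)


def svm_crossval_accuracy(features: np.ndarray, truth,
                          c_values=(0.1, 1.0, 10.0, 100.0),
                          folds: int = 5, seed: int = 0) -> dict[float, float]:
    """Mean held-out accuracy of an RBF soft-margin SVM per value of C,
    over a seeded stratified k-fold split."""
    x = standardize(np.asarray(features, dtype=float))
    y = np.asarray(truth)
    _, counts = np.unique(y, return_counts=True)
    n_splits = folds
    if counts.min() < folds:
        n_splits = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} samples; using "
            f"{n_splits}-fold splits instead of {folds}")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    out = {}
    for c in c_values:
        scores = cross_val_score(SVC(C=c, kernel="rbf"), x, y, cv=cv)
        out[float(c)] = float(scores.mean())
    return out
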