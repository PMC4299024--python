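"""Vector quantization of window features into a finite primitive alphabet.

An M-centroid codebook is learned with k-means on training feature vectors
only; any feature vector is then mapped to the ID (1..M) of its nearest
centroid, turning a day of accelerometer data into a string of discrete
"primitives" — the observation alphabet of the sequence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .preprocess import FEATURE_NAMES

DEFAULT_N_PRIMITIVES = 300


class PrimitiveQuantizer(BaseEstimator, TransformerMixin):
    """k-means vector quantizer over 12-dimensional window features.

    Parameters
    ----------
    n_primitives : int, default 300
        Alphabet size M (number of k-means centroids).
    n_restarts : int, default 10
        Number of k-means++ restarts; the run with the lowest within-cluster
        sum of squares is kept.
    max_iter : int, default 300
        Lloyd iterations per restart.
    standardize : bool, default False
        Optionally z-score features before clustering (off by default).
    random_state : int or None
        Seed for the k-means initialisation; fixing it makes fitting
        bit-reproducible.

    Attributes
    ----------
    centroids_ : ndarray of shape (M, d)
        Cluster centres in the (possibly standardized) feature space.
    inertia_ : float
        Within-cluster sum of squares of the selected run.
    """

    def __init__(
        self,
        n_primitives: int = DEFAULT_N_PRIMITIVES,
        n_restarts: int = 10,
        max_iter: int = 300,
        standardize: bool = False,
        random_state: int | None = None,
    ):
        self.n_primitives = n_primitives
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.n_primitives < 1:
            raise ValueError("n_primitives must be >= 1")
        if X.shape[0] < self.n_primitives:
            raise ValueError("M exceeds sample count")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
            X = (X - self.mean_) / self.scale_
        km = KMeans(
            n_clusters=self.n_primitives,
            init="k-means++",
            n_init=self.n_restarts,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(X)
        self.centroids_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Primitive IDs in 1..M (nearest centroid; ties -> lowest ID)."""
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centroids_.shape[1]:
            raise ValueError(
                f"expected {self.centroids_.shape[1]} features, got {X.shape[1]}"
            )
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        # cdist + argmin: first minimum wins, giving the lowest-ID tie rule.
        return cdist(X, self.centroids_).argmin(axis=1) + 1

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of each vector to its assigned centroid."""
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        d = cdist(X, self.centroids_)
        return float(d.min(axis=1).mean())


@dataclass
class Codebook:
    """Serializable snapshot of a fitted quantizer: M centroids = primitives."""

    centroids: np.ndarray
    feature_order: tuple[str, ...] = FEATURE_NAMES
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a non-empty 2-D array")

    @property
    def M(self) -> int:
        return self.centroids.shape[0]

    @classmethod
    def from_quantizer(cls, q: PrimitiveQuantizer) -> "Codebook":
        check_is_fitted(q, "centroids_")
        return cls(centroids=q.centroids_.copy(), seed=q.random_state)

    def assign(self, feature_vector: np.ndarray) -> int:
        """ID (1..M) of the nearest centroid; ties -> lowest ID."""
        fv = np.asarray(feature_vector, dtype=float)
        if fv.shape != (self.centroids.shape[1],):
            raise ValueError("feature vector has wrong dimensionality")
        return int(cdist(fv[None, :], self.centroids).argmin()) + 1


@dataclass
class PrimitiveSequence:
    """One run as an ordered string of primitive IDs with per-position labels."""

    run_id: str
    primitives: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.primitives = np.asarray(self.primitives, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.primitives) != len(self.labels):
            raise ValueError("primitives and labels must have equal length")
        if len(self.primitives) == 0:
            raise ValueError("empty input")
        if self.primitives.min(initial=1) < 1:
            raise ValueError("primitive IDs must be >= 1")

    def __len__(self) -> int:
        return len(self.primitives)


def fit_codebook(
    train_features: np.ndarray, M: int = DEFAULT_N_PRIMITIVES, seed: int | None = None
) -> Codebook:
    """Learn an M-primitive codebook by seeded k-means on training features."""
    q = PrimitiveQuantizer(n_primitives=M, random_state=seed).fit(train_features)
    return Codebook.from_quantizer(q)


def quantize_run(
    quantizer: PrimitiveQuantizer | Codebook,
    features: np.ndarray,
    labels: np.ndarray,
    run_id: str = "run",
) -> PrimitiveSequence:
    """Map each window's features to its primitive ID, carrying labels through."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        raise ValueError("empty input")
    if isinstance(quantizer, Codebook):
        ids = cdist(features, quantizer.centroids).argmin(axis=1) + 1
    else:
        ids = quantizer.transform(features)
    return PrimitiveSequence(run_id=run_id, primitives=ids, labels=np.asarray(labels))
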