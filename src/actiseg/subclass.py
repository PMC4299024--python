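"""Intra-class fragmentation: detection, subclassing and mapping back.

One activity label sometimes covers kinematically distinct behaviours (a
"commute" tagged both for bus rides and for walks).  Training a single
emission model on such a fragmented class blurs it.  The remedy implemented
here represents every labeled activity episode as an M-bin histogram of its
primitives, clusters each class's episodes with k-means, scores candidate
splits with a cluster validity index (Silhouette, PBM, or the generalized
Dunn index GDI33), and keeps a split only if it strictly improves a
leave-one-instance-out naive-Bayes cross-validation accuracy on the original
labels — so accepted subclassings never hurt the training-set accuracy.
Predictions made with subclass labels are mapped back to the original class
before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.naive_bayes import MultinomialNB

from .quantize import PrimitiveSequence

SUBCLASS_SEP = "::"


@dataclass
class ActivityInstance:
    """One contiguous labeled episode summarised as a primitive histogram."""

    instance_id: str
    run_index: int
    original_class: str
    start: int  # window position within the run (half-open range)
    end: int
    counts: np.ndarray  # length-M raw primitive counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.length < 1:
            raise ValueError("empty instance")

    @property
    def length(self) -> int:
        return int(self.counts.sum())

    @property
    def histogram(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class SubclassMap:
    """Chosen fragment counts, subclass -> original mapping, assignments."""

    fragment_counts: dict[str, int]
    mapping: dict[str, str]
    instance_labels: np.ndarray = field(default_factory=lambda: np.empty(0, object))

    def map_back(self, predictions: Sequence[str]) -> np.ndarray:
        return apply_and_mapback(self.mapping, predictions)


def histogram(primitives: Sequence[int], M: int) -> np.ndarray:
    """Relative-frequency histogram over the primitive alphabet 1..M."""
    prims = np.asarray(primitives, dtype=int)
    if prims.size == 0:
        raise ValueError("empty input")
    if prims.min() < 1 or prims.max() > M:
        raise ValueError("primitive ID outside 1..M")
    counts = np.bincount(prims - 1, minlength=M)[:M]
    return counts / prims.size


def extract_instances(
    seqs: Sequence[PrimitiveSequence], M: int
) -> list[ActivityInstance]:
    """Maximal same-label runs of each sequence, one instance per episode."""
    instances = []
    for r, seq in enumerate(seqs):
        lab = seq.labels
        boundaries = np.flatnonzero(lab[:-1] != lab[1:]) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(lab)]))
        for s, e in zip(starts, ends):
            counts = np.bincount(seq.primitives[s:e] - 1, minlength=M)[:M]
            instances.append(
                ActivityInstance(
                    instance_id=f"{seq.run_id}:{s}",
                    run_index=r,
                    original_class=str(lab[s]),
                    start=int(s),
                    end=int(e),
                    counts=counts,
                )
            )
    return instances


# ---------------------------------------------------------------------------
# cluster validity indices
# ---------------------------------------------------------------------------

def _check_clustering(points: np.ndarray, assignment: np.ndarray):
    points = np.asarray(points, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ValueError("at least 2 clusters required")
    return points, assignment, labels


def silhouette_index(points, assignment) -> float:
    """Mean silhouette width (Euclidean); singleton clusters score 0."""
    points, assignment, _ = _check_clustering(points, assignment)
    return float(silhouette_score(points, assignment, metric="euclidean"))


def pbm_index(points, assignment) -> float:
    """PBM index ((1/K) * (E1/EK) * DK)^2; larger is better.

    E1 sums distances to the global centroid, EK the within-cluster
    distances to each cluster centroid, DK is the largest centroid-pair
    distance.  Perfectly compact clusterings (EK = 0) return +inf.
    """
    points, assignment, labels = _check_clustering(points, assignment)
    K = len(labels)
    e1 = float(np.linalg.norm(points - points.mean(axis=0), axis=1).sum())
    centroids = np.stack([points[assignment == c].mean(axis=0) for c in labels])
    ek = sum(
        float(np.linalg.norm(points[assignment == c] - centroids[i], axis=1).sum())
        for i, c in enumerate(labels)
    )
    dk = float(pdist(centroids).max())
    if ek == 0:
        return np.inf
    return ((1.0 / K) * (e1 / ek) * dk) ** 2


def gdi33_index(points, assignment) -> float:
    """Generalized Dunn index, variant (3,3); larger is better.

    Separation delta3(Ci, Cj) is the mean pairwise distance between members
    of the two clusters; diameter Delta3(C) is twice the mean distance of
    members to their centroid.  All diameters zero returns +inf.
    """
    points, assignment, labels = _check_clustering(points, assignment)
    members = [points[assignment == c] for c in labels]
    diam = max(
        2.0 * float(np.linalg.norm(m - m.mean(axis=0), axis=1).mean()) for m in members
    )
    sep = min(
        float(cdist(members[i], members[j]).mean())
        for i in range(len(members))
        for j in range(i + 1, len(members))
    )
    if diam == 0:
        return np.inf
    return sep / diam


INDEX_FUNCTIONS: dict[str, Callable] = {
    "silhouette": silhouette_index,
    "pbm": pbm_index,
    "gdi33": gdi33_index,
}


# ---------------------------------------------------------------------------
# subclass search
# ---------------------------------------------------------------------------

def loio_nb_accuracy(
    counts: np.ndarray,
    train_labels: np.ndarray,
    original_labels: np.ndarray,
    mapping: dict[str, str],
) -> float:
    """Leave-one-instance-out multinomial naive-Bayes accuracy.

    The classifier is trained on (possibly subclassed) ``train_labels``,
    each held-out prediction is mapped back to its original class, and the
    accuracy is scored against ``original_labels``.
    """
    n = len(train_labels)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        if len(np.unique(train_labels[mask])) < 2:
            pred = train_labels[mask][0]
        else:
            nb = MultinomialNB(alpha=1.0)
            nb.fit(counts[mask], train_labels[mask])
            pred = nb.predict(counts[i : i + 1])[0]
        if mapping.get(str(pred), str(pred)) == original_labels[i]:
            correct += 1
    return correct / n


def _subclass_name(cls: str, j: int) -> str:
    return f"{cls}{SUBCLASS_SEP}{j}"


def find_subclasses(
    instances: Sequence[ActivityInstance],
    index: str = "silhouette",
    max_k: int = 5,
    seed: int = 0,
) -> SubclassMap:
    """Search per-class subclass counts with a cluster validity index.

    For each class in turn: cluster its instance histograms into
    k = 2..min(max_k, n_i - 1) groups with seeded k-means, take the k
    optimising the chosen index, and keep the candidate split only if it
    strictly improves the current leave-one-instance-out naive-Bayes
    accuracy (measured on original labels after mapping back).  Classes
    with too few instances, or whose best split fails the accuracy gate,
    keep a single subclass.
    """
    if index not in INDEX_FUNCTIONS:
        raise ValueError(f"index must be one of {sorted(INDEX_FUNCTIONS)}")
    index_fn = INDEX_FUNCTIONS[index]
    instances = list(instances)
    counts = np.stack([inst.counts for inst in instances])
    original = np.array([inst.original_class for inst in instances], dtype=object)
    classes = sorted(set(original))

    current = original.copy()
    mapping = {c: c for c in classes}
    fragment_counts = {c: 1 for c in classes}
    current_acc = loio_nb_accuracy(counts, current, original, mapping)

    for cls in classes:
        sel = np.flatnonzero(original == cls)
        n_i = len(sel)
        upper = min(max_k, n_i - 1)
        if upper < 2:
            continue
        hist = counts[sel] / counts[sel].sum(axis=1, keepdims=True)
        best_k, best_labels, best_q = None, None, -np.inf
        for k in range(2, upper + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(hist)
            if len(np.unique(km.labels_)) < 2:
                continue
            q = index_fn(hist, km.labels_)
            if q > best_q:
                best_k, best_labels, best_q = k, km.labels_, q
        if best_k is None:
            continue
        cand = current.copy()
        cand[sel] = [_subclass_name(cls, j + 1) for j in best_labels]
        cand_mapping = dict(mapping)
        cand_mapping.pop(cls, None)
        for j in range(best_k):
            cand_mapping[_subclass_name(cls, j + 1)] = cls
        acc = loio_nb_accuracy(counts, cand, original, cand_mapping)
        if acc > current_acc:
            current, mapping, current_acc = cand, cand_mapping, acc
            fragment_counts[cls] = best_k

    return SubclassMap(
        fragment_counts=fragment_counts, mapping=mapping, instance_labels=current
    )


def fixed_subclasses(
    instances: Sequence[ActivityInstance],
    counts_per_class: dict[str, int],
    seed: int = 0,
) -> SubclassMap:
    """Split each named class into a user-supplied number of subclasses.

    Bypasses both the index search and the accuracy gate (the analogue of
    choosing fragment counts by eye from a dendrogram).  Classes named in
    ``counts_per_class`` but absent from the instances are skipped, since a
    cross-validation fold need not contain every configured class.
    """
    instances = list(instances)
    counts = np.stack([inst.counts for inst in instances])
    original = np.array([inst.original_class for inst in instances], dtype=object)
    classes = sorted(set(original))
    current = original.copy()
    mapping = {c: c for c in classes}
    fragment_counts = {c: 1 for c in classes}
    for cls, k in counts_per_class.items():
        if cls not in classes:
            continue
        sel = np.flatnonzero(original == cls)
        k = int(k)
        if k < 2 or len(sel) < k:
            continue
        hist = counts[sel] / counts[sel].sum(axis=1, keepdims=True)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(hist)
        current[sel] = [_subclass_name(cls, j + 1) for j in km.labels_]
        mapping.pop(cls, None)
        for j in range(k):
            mapping[_subclass_name(cls, j + 1)] = cls
        fragment_counts[cls] = k
    return SubclassMap(
        fragment_counts=fragment_counts, mapping=mapping, instance_labels=current
    )


def apply_and_mapback(mapping: dict[str, str], predictions: Sequence[str]) -> np.ndarray:
    """Replace each predicted subclass label with its original class."""
    out = np.empty(len(predictions), dtype=object)
    for i, p in enumerate(predictions):
        p = str(p)
        if p not in mapping:
            raise KeyError(f"unknown subclass label {p!r}")
        out[i] = mapping[p]
    return out


def relabel_windows(
    seqs: Sequence[PrimitiveSequence],
    instances: Sequence[ActivityInstance],
    submap: SubclassMap,
) -> list[np.ndarray]:
    """Training labels rewritten with each episode's assigned subclass."""
    new_labels = [seq.labels.copy() for seq in seqs]
    for inst, sub in zip(instances, submap.instance_labels):
        new_labels[inst.run_index][inst.start : inst.end] = sub
    return new_labels
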