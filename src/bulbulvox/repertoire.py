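"""Dimensionality reduction and repertoire classification with open-set rejection.

Word vectors (1190-D cleaned mel images) and syllable vectors (8-D) are
projected with PCA for analysis and classification, or embedded with t-SNE
for visualization only.  New detections are classified in the reduced PCA
space by nearest-centroid, KNN (K=3) or an RBF SVM; with rejection enabled,
a test item farther from every class centroid than any training item was
from its own centroid is labeled ``REJECTED`` instead of forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC

from .errors import DegenerateDataError, InvalidConfiguration

__all__ = [
    "ProjectionKind", "ClassifierKind", "ProjectionModel", "RepertoireClassifier",
    "REJECTED", "fit_projection", "project", "fit_classifier", "classify",
    "export_embedding",
]

REJECTED = "REJECTED"


class ProjectionKind(str, Enum):
    PCA = "pca"
    TSNE = "tsne"


class ClassifierKind(str, Enum):
    KNN = "knn"
    NEAREST_CENTROID = "nearest_centroid"
    SVM_RBF = "svm_rbf"


@dataclass
class ProjectionModel:
    kind: ProjectionKind
    n_components: int
    estimator: object                       # fitted sklearn object (PCA only for transform)
    embedding_: np.ndarray                  # training coordinates
    explained_variance_ratio: np.ndarray | None = None  # PCA only


@dataclass
class RepertoireClassifier:
    kind: ClassifierKind
    estimator: object
    classes_: np.ndarray
    centroids_: np.ndarray                  # per-class centroid in the reduced space
    rejection_threshold: float | None = None


def fit_projection(
    vectors: np.ndarray,
    kind: ProjectionKind = ProjectionKind.PCA,
    n_components: int = 2,
    seed: int = 0,
) -> ProjectionModel:
    """Fit PCA (transformable) or t-SNE (fit-once, visualization only)."""
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidConfiguration("need at least two vectors")
    if n_components >= x.shape[1]:
        raise InvalidConfiguration(
            f"n_components={n_components} must be below dimension {x.shape[1]}")
    if np.allclose(x.var(axis=0), 0):
        raise DegenerateDataError("vectors carry no variance")
    if kind == ProjectionKind.PCA:
        est = PCA(n_components=n_components, random_state=seed)
        emb = est.fit_transform(x)
        return ProjectionModel(kind, n_components, est, emb,
                               est.explained_variance_ratio_.copy())
    est = TSNE(n_components=n_components, random_state=seed,
               perplexity=min(30.0, (x.shape[0] - 1) / 3.0), init="pca")
    emb = est.fit_transform(x)
    return ProjectionModel(kind, n_components, est, emb, None)


def project(model: ProjectionModel, vectors: np.ndarray) -> np.ndarray:
    """Map new vectors into the fitted PCA space (linear, centered)."""
    if model.kind != ProjectionKind.PCA:
        raise InvalidConfiguration("only PCA supports out-of-sample projection")
    x = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if x.shape[1] != model.estimator.n_features_in_:
        raise InvalidConfiguration(
            f"dimension mismatch: got {x.shape[1]}, model expects "
            f"{model.estimator.n_features_in_}")
    return model.estimator.transform(x)


def _centroids(embedding: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    cents = np.stack([embedding[labels == c].mean(axis=0) for c in classes])
    return classes, cents


def fit_classifier(
    embedding: np.ndarray,
    labels: np.ndarray | list,
    kind: ClassifierKind = ClassifierKind.NEAREST_CENTROID,
    rejection: bool = False,
    rejection_percentile: float | None = None,
    k: int = 3,
    seed: int = 0,
) -> RepertoireClassifier:
    """Fit a repertoire classifier in the reduced space.

    With ``rejection`` on, the threshold is the maximum (or, if
    ``rejection_percentile`` is given, that percentile) over training samples
    of the Euclidean distance to their own class centroid — anything farther
    from every centroid than that was never seen in training.
    """
    x = np.asarray(embedding, dtype=np.float64)
    y = np.asarray(labels)
    classes, cents = _centroids(x, y)
    if classes.size < 2:
        raise InvalidConfiguration("need at least two classes")
    if kind == ClassifierKind.KNN:
        est = KNeighborsClassifier(n_neighbors=k)
    elif kind == ClassifierKind.NEAREST_CENTROID:
        est = NearestCentroid()
    else:
        est = SVC(kernel="rbf", random_state=seed)
    est.fit(x, y)
    threshold = None
    if rejection:
        own = np.array([cents[np.searchsorted(classes, lab)] for lab in y])
        dists = np.linalg.norm(x - own, axis=1)
        threshold = float(np.max(dists) if rejection_percentile is None
                          else np.percentile(dists, rejection_percentile))
    return RepertoireClassifier(kind, est, classes, cents, threshold)


def classify(clf: RepertoireClassifier, embedded: np.ndarray) -> np.ndarray:
    """Label embedded test vectors; items beyond the rejection threshold from
    every class centroid get ``REJECTED`` before any labeling rule applies."""
    x = np.atleast_2d(np.asarray(embedded, dtype=np.float64))
    labels = clf.estimator.predict(x).astype(object)
    if clf.rejection_threshold is not None:
        d = np.linalg.norm(x[:, None, :] - clf.centroids_[None, :, :], axis=2)
        labels[d.min(axis=1) > clf.rejection_threshold] = REJECTED
    return labels


def export_embedding(path, embedding: np.ndarray, labels=None) -> None:
    """Plot-ready coordinate table (CSV): one row per item, optional label."""
    emb = np.asarray(embedding)
    df = pd.DataFrame(emb, columns=[f"c{i}" for i in range(emb.shape[1])])
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(path, index=False)
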