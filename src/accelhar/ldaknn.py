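"""Per-channel linear-discriminant pipeline with K-nearest-neighbour
classification.

Each of the four channels is treated as a univariate time series: the
raw T-sample window is the input vector of a supervised linear
discriminant projection (at most l - 1 components for l classes), the
per-channel projections are concatenated in fixed channel order, and a
Euclidean KNN classifier votes on the result.  Within-class scatter is
shrinkage-regularised because T can exceed per-class window counts in
small folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors

from .activities import CHANNELS
from .features import FeatureMatrix
from .segment import SegmentTensor


@dataclass
class ChannelProjection:
    """Fitted per-channel discriminant maps (train data only)."""

    models: list[LinearDiscriminantAnalysis]
    n_components: int
    channels: tuple[str, ...] = CHANNELS


def lda_fit(
    seg: SegmentTensor,
    n_components: int | None = None,
    shrinkage="auto",
) -> ChannelProjection:
    """Fit one shrinkage-LDA map per channel on raw T-sample windows."""
    labels = seg.labels.astype(str)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    max_comp = len(classes) - 1
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds class limit {max_comp}"
        )
    models = []
    for c in range(seg.n_channels):
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage=shrinkage, n_components=n_components
        )
        lda.fit(seg.values[:, :, c], labels)
        models.append(lda)
    return ChannelProjection(models=models, n_components=n_components)


def lda_transform(proj: ChannelProjection, seg: SegmentTensor) -> FeatureMatrix:
    """Project every channel and concatenate: K x (m * n_components)."""
    if seg.n_channels != len(proj.models):
        raise ValueError("channel count mismatch with fitted projection")
    n_cols = len(proj.models) * proj.n_components
    if seg.n_segments == 0:
        return FeatureMatrix(
            np.empty((0, n_cols)),
            _component_names(proj),
            seg.labels.copy(),
        )
    blocks = [
        proj.models[c].transform(seg.values[:, :, c])
        for c in range(seg.n_channels)
    ]
    return FeatureMatrix(np.hstack(blocks), _component_names(proj), seg.labels.copy())


def _component_names(proj: ChannelProjection) -> list[str]:
    return [
        f"{ch}_ld{i}"
        for ch in proj.channels[: len(proj.models)]
        for i in range(proj.n_components)
    ]


@dataclass
class KnnModel:
    train_x: np.ndarray
    train_y: np.ndarray
    k: int
    _nn: NearestNeighbors


def knn_train(fm: FeatureMatrix, k: int = 5) -> KnnModel:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(fm):
        raise ValueError(f"k={k} exceeds training size {len(fm)}")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(fm.values)
    return KnnModel(fm.values.copy(), fm.labels.astype(str), k, nn)


def knn_predict(model: KnnModel, fm: FeatureMatrix) -> np.ndarray:
    """Majority label among the k Euclidean-nearest training points.

    Vote ties are broken by the tied class with the smaller mean
    neighbour distance, then by lexicographic label order.
    """
    if len(fm) == 0:
        return np.empty(0, dtype=object)
    dists, idx = model._nn.kneighbors(fm.values)
    out = np.empty(len(fm), dtype=object)
    for i in range(len(fm)):
        neigh_labels = model.train_y[idx[i]]
        neigh_dists = dists[i]
        classes, counts = np.unique(neigh_labels, return_counts=True)
        best = counts.max()
        tied = classes[counts == best]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            mean_d = {
                c: neigh_dists[neigh_labels == c].mean() for c in tied
            }
            out[i] = min(sorted(tied), key=lambda c: mean_d[c])
    return out
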