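"""Handcrafted-feature pipeline: time/frequency features, z-score
normalisation, ReliefF relevance ranking, one-vs-all RBF SVM.

Per channel (Ax, Ay, Az, An) each window yields 13 features — mean,
variance, standard deviation, maximum, minimum, RMS, kurtosis,
skewness, Euclidean (l2) norm, l1 norm, FFT energy, maximum FFT
magnitude and the dominant (non-DC) FFT bin index — plus the lag-0
Pearson cross-correlations of the three raw-axis pairs (Ax,Ay),
(Ax,Az), (Ay,Az): 13 x 4 + 3 = 55 features.

Conventions pinned for reproducibility: population (1/T) denominators;
kurtosis is the non-excess fourth standardised moment; skewness,
kurtosis and cross-correlation of a constant signal are defined as 0;
FFT energy is sum(|X[k]|^2) / T over all bins of the un-windowed
segment (so it equals the time-domain sum of squares by Parseval);
maximum magnitude and the dominant bin exclude DC, so the gravity
offset cannot dominate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .activities import CHANNELS
from .segment import SegmentTensor

_TIME_METRICS = (
    "mean", "var", "std", "max", "min", "rms", "kurtosis", "skewness",
    "l2norm", "l1norm",
)
_FREQ_METRICS = ("fft_energy", "fft_maxmag", "fft_domfreq")
_CORR_PAIRS = ((0, 1, "AxAy"), (0, 2, "AxAz"), (1, 2, "AyAz"))

# variance below this (g^2) is numerically indistinguishable from a
# constant window; shape statistics are then defined as 0
_VAR_EPS = 1e-24


def feature_names(channels=CHANNELS) -> list[str]:
    names = [
        f"{ch}_{metric}"
        for ch in channels
        for metric in _TIME_METRICS + _FREQ_METRICS
    ]
    names += [f"corr_{pair}" for _, _, pair in _CORR_PAIRS]
    return names


@dataclass
class FeatureMatrix:
    """K x F feature table with stable, unique feature names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self):
        return self.values.shape[0]


def _channel_features(x: np.ndarray) -> np.ndarray:
    """13 features of one K x T channel block, vectorised over windows."""
    t_len = x.shape[1]
    mean = x.mean(axis=1)
    var = x.var(axis=1)  # population
    var = np.where(var < _VAR_EPS, 0.0, var)  # constant windows are exactly flat
    std = np.sqrt(var)
    xmax = x.max(axis=1)
    xmin = x.min(axis=1)
    sumsq = np.sum(x * x, axis=1)
    rms = np.sqrt(sumsq / t_len)
    centered = x - mean[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        m3 = np.mean(centered**3, axis=1)
        m4 = np.mean(centered**4, axis=1)
        skew = np.where(std > 0, m3 / np.where(std > 0, std, 1) ** 3, 0.0)
        kurt = np.where(var > 0, m4 / np.where(var > 0, var, 1) ** 2, 0.0)
    l2 = np.sqrt(sumsq)
    l1 = np.sum(np.abs(x), axis=1)
    spec = np.fft.fft(x, axis=1)
    mag = np.abs(spec)
    energy = np.sum(mag**2, axis=1) / t_len
    half = t_len // 2
    nondc = mag[:, 1 : half + 1]
    maxmag = nondc.max(axis=1) if nondc.shape[1] else np.zeros(len(x))
    domfreq = (nondc.argmax(axis=1) + 1.0) if nondc.shape[1] else np.zeros(len(x))
    return np.column_stack(
        [mean, var, std, xmax, xmin, rms, kurt, skew, l2, l1, energy, maxmag, domfreq]
    )


def extract_features(seg: SegmentTensor) -> FeatureMatrix:
    """55 time-frequency features per window (13 per channel + 3
    raw-axis cross-correlations)."""
    if seg.n_segments == 0:
        raise ValueError("cannot extract features from an empty tensor")
    if not np.all(np.isfinite(seg.values)):
        raise ValueError("windows contain non-finite samples")
    if seg.n_channels != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channels (Ax, Ay, Az, An)")
    blocks = [_channel_features(seg.values[:, :, c]) for c in range(seg.n_channels)]
    # cross-correlations of the raw axis pairs
    corrs = []
    for i, j, _ in _CORR_PAIRS:
        xi = seg.values[:, :, i]
        xj = seg.values[:, :, j]
        ci = xi - xi.mean(axis=1, keepdims=True)
        cj = xj - xj.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(ci * ci, axis=1) * np.sum(cj * cj, axis=1))
        num = np.sum(ci * cj, axis=1)
        ok = denom > xi.shape[1] * _VAR_EPS
        corrs.append(np.where(ok, num / np.where(ok, denom, 1), 0.0))
    values = np.column_stack(blocks + [np.column_stack(corrs)])
    return FeatureMatrix(values, feature_names(), seg.labels.copy())


# ---------------------------------------------------------------------------
# z-score normalisation (fit on train only)

@dataclass
class ZScoreParams:
    scaler: StandardScaler


def zscore_fit(train: FeatureMatrix) -> ZScoreParams:
    """Fit per-column mean/std (population) on training features only.
    Zero-variance columns map to 0 on transform."""
    if len(train) == 0:
        raise ValueError("cannot fit normalisation on an empty matrix")
    scaler = StandardScaler().fit(train.values)
    return ZScoreParams(scaler)


def zscore_apply(params: ZScoreParams, fm: FeatureMatrix) -> FeatureMatrix:
    values = params.scaler.transform(fm.values)
    return FeatureMatrix(values, list(fm.feature_names), fm.labels.copy())


# ---------------------------------------------------------------------------
# ReliefF

@dataclass
class FeatureWeights:
    """Per-feature relevance scores and the descending-weight order."""

    weights: np.ndarray
    order: np.ndarray

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]


def relieff_rank(
    fm: FeatureMatrix,
    k_neighbors: int = 10,
    n_samples="all",
    seed: int = 0,
) -> FeatureWeights:
    """Multiclass ReliefF feature relevance.

    For each sampled instance the k nearest same-class neighbours (hits)
    and the k nearest neighbours of every other class (misses) are found
    under Manhattan distance on range-normalised features.  A feature's
    weight decreases by its mean normalised difference to the hits and
    increases by the prior-weighted mean difference to the misses;
    weights are averaged over the sampled instances, so with fully
    separated classes they are bounded by 1 in magnitude.

    With ``n_samples="all"`` every instance is used in index order and
    the result is deterministic; otherwise ``seed`` drives the sample.
    """
    x = fm.values
    y = fm.labels
    n, f = x.shape
    classes, y_idx = np.unique(y.astype(str), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("ReliefF needs at least 2 classes")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")

    rng_range = x.max(axis=0) - x.min(axis=0)
    scale = np.where(rng_range > 0, rng_range, 1.0)
    xn = x / scale  # per-feature range-normalised
    zero_range = rng_range <= 0

    priors = np.bincount(y_idx, minlength=len(classes)) / n

    if n_samples == "all" or n_samples >= n:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sample_idx = rng.choice(n, size=int(n_samples), replace=False)

    weights = np.zeros(f)
    for i in sample_idx:
        diffs = np.abs(xn - xn[i])          # n x f
        diffs[:, zero_range] = 0.0
        dists = diffs.sum(axis=1)
        same = y_idx == y_idx[i]
        hit_pool = np.where(same)[0]
        hit_pool = hit_pool[hit_pool != i]
        if len(hit_pool) == 0:
            continue
        k_h = min(k_neighbors, len(hit_pool))
        hits = hit_pool[np.argsort(dists[hit_pool], kind="stable")[:k_h]]
        weights -= diffs[hits].mean(axis=0)
        p_i = priors[y_idx[i]]
        for c in range(len(classes)):
            if c == y_idx[i]:
                continue
            miss_pool = np.where(y_idx == c)[0]
            if len(miss_pool) == 0:
                continue
            k_m = min(k_neighbors, len(miss_pool))
            misses = miss_pool[np.argsort(dists[miss_pool], kind="stable")[:k_m]]
            weights += (priors[c] / (1.0 - p_i)) * diffs[misses].mean(axis=0)
    weights /= len(sample_idx)
    order = np.argsort(-weights, kind="stable")
    return FeatureWeights(weights=weights, order=order)


# ---------------------------------------------------------------------------
# one-vs-all RBF SVM

@dataclass
class OvaSvm:
    """One binary RBF SVM per class; predicts by decision-function argmax.

    Class weights scale the penalty of each training sample by the
    weight of its (multiclass) label in every binary subproblem."""

    classes: np.ndarray
    estimators: list[SVC]

    def decision_matrix(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack([est.decision_function(x) for est in self.estimators])


def train_svm(
    fm: FeatureMatrix,
    class_weights: dict | None = None,
    gamma: float = 0.001,
    c: float = 1000.0,
) -> OvaSvm:
    """One-vs-all RBF-kernel SVM (gamma and C as manually tuned)."""
    labels = fm.labels.astype(str)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("SVM training needs at least 2 classes")
    if class_weights is None:
        sample_w = np.ones(len(labels))
    else:
        sample_w = np.array([class_weights[str(y)] for y in labels], dtype=float)
    estimators = []
    for cls in classes:
        est = SVC(kernel="rbf", gamma=gamma, C=c)
        est.fit(fm.values, (labels == cls).astype(int), sample_weight=sample_w)
        estimators.append(est)
    return OvaSvm(classes=classes, estimators=estimators)


def predict_svm(model: OvaSvm, fm: FeatureMatrix) -> np.ndarray:
    scores = model.decision_matrix(fm.values)
    return model.classes[scores.argmax(axis=1)].astype(object)
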