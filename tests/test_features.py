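"""Handcrafted features, normalisation, ReliefF and the one-vs-all SVM."""

import numpy as np
import pytest

from accelhar.features import (
    FeatureMatrix,
    extract_features,
    feature_names,
    predict_svm,
    relieff_rank,
    train_svm,
    zscore_apply,
    zscore_fit,
)
from accelhar.segment import SegmentTensor


def _tensor(values, labels):
    k = len(labels)
    return SegmentTensor(values, np.asarray(labels, dtype=object), np.zeros(k), np.zeros(k))


def test_feature_vector_has_55_named_entries(small_tensor):
    fm = extract_features(small_tensor)
    assert fm.n_features == 55
    assert len(feature_names()) == 55
    assert len(set(fm.feature_names)) == 55
    assert np.all(np.isfinite(fm.values))


def test_constant_window_conventions():
    """Zero-variance windows: moments collapse, shape statistics and
    correlations are defined as 0 rather than NaN."""
    c = 0.7
    seg = _tensor(np.full((1, 64, 4), c), ["A5"])
    fm = extract_features(seg)
    get = dict(zip(fm.feature_names, fm.values[0]))
    assert get["Ax_mean"] == pytest.approx(c)
    assert get["Ax_max"] == get["Ax_min"] == pytest.approx(c)
    assert get["Ax_var"] == 0 and get["Ax_std"] == 0
    assert get["Ax_rms"] == pytest.approx(abs(c))
    assert get["Ax_kurtosis"] == 0 and get["Ax_skewness"] == 0
    assert get["corr_AxAy"] == 0 and get["corr_AyAz"] == 0


def test_sinusoid_rms_and_parseval():
    """Full-cycle sinusoid of amplitude A: RMS = A/sqrt(2); FFT energy
    equals the time-domain sum of squares."""
    amp = 1.3
    t = np.arange(64)
    x = amp * np.sin(2 * np.pi * 4 * t / 64)
    vals = np.stack([np.stack([x] * 4, axis=1)])
    fm = extract_features(_tensor(vals, ["A3"]))
    get = dict(zip(fm.feature_names, fm.values[0]))
    assert get["Ax_rms"] == pytest.approx(amp / np.sqrt(2), rel=1e-9)
    assert get["Ax_fft_energy"] == pytest.approx(np.sum(x**2), rel=1e-9)
    assert get["Ax_fft_domfreq"] == 4


def test_fft_energy_parseval_on_every_window(small_tensor):
    fm = extract_features(small_tensor)
    for c, ch in enumerate(("Ax", "Ay", "Az", "An")):
        energy = fm.values[:, fm.feature_names.index(f"{ch}_fft_energy")]
        sumsq = np.sum(small_tensor.values[:, :, c] ** 2, axis=1)
        np.testing.assert_allclose(energy, sumsq, rtol=1e-6)


class TestZScore:
    def test_population_std_worked_example(self):
        fm = FeatureMatrix(np.array([[1.0], [2.0], [3.0]]), ["f"], np.array(["a", "b", "a"]))
        out = zscore_apply(zscore_fit(fm), fm)
        np.testing.assert_allclose(out.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_maps_to_zero(self):
        fm = FeatureMatrix(np.full((5, 2), 3.0), ["f", "g"], np.array(["a"] * 5))
        out = zscore_apply(zscore_fit(fm), fm)
        assert np.all(out.values == 0)

    def test_train_columns_standardised(self, small_tensor):
        fm = extract_features(small_tensor)
        out = zscore_apply(zscore_fit(fm), fm)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
        stds = out.values.std(axis=0)
        nonconst = fm.values.std(axis=0) > 0
        np.testing.assert_allclose(stds[nonconst], 1.0, atol=1e-9)


def _relieff_oracle(x, y, k):
    """Naive all-pairs ReliefF over every instance, loops only."""
    n, f = x.shape
    classes = sorted(set(y))
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0
    priors = {c: (np.asarray(y) == c).mean() for c in classes}
    w = np.zeros(f)
    for i in range(n):
        dists = [np.sum(np.abs(x[j] - x[i]) / span) for j in range(n)]
        order = sorted(range(n), key=lambda j: (dists[j], j))
        hits = [j for j in order if j != i and y[j] == y[i]][:k]
        if not hits:
            continue
        for feat in range(f):
            if np.ptp(x[:, feat]) == 0:
                continue
            w[feat] -= np.mean([abs(x[j, feat] - x[i, feat]) / span[feat] for j in hits])
        for c in classes:
            if c == y[i]:
                continue
            misses = [j for j in order if y[j] == c][:k]
            if not misses:
                continue
            factor = priors[c] / (1 - priors[y[i]])
            for feat in range(f):
                if np.ptp(x[:, feat]) == 0:
                    continue
                w[feat] += factor * np.mean(
                    [abs(x[j, feat] - x[i, feat]) / span[feat] for j in misses]
                )
    return w / n


class TestReliefF:
    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(40, 6))
        y = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 10)
        x[:15, 0] += 4  # informative feature
        fm = FeatureMatrix(x, [f"f{i}" for i in range(6)], y)
        got = relieff_rank(fm, k_neighbors=3).weights
        want = _relieff_oracle(x, list(y), 3)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_constant_feature_has_zero_weight(self, rng):
        x = rng.normal(size=(30, 4))
        x[:, 2] = 5.0
        y = np.array(["a", "b"] * 15)
        fm = FeatureMatrix(x, list("wxyz"), y)
        assert relieff_rank(fm, k_neighbors=2).weights[2] == 0.0

    def test_separating_feature_ranked_first(self, rng):
        x = rng.uniform(size=(50, 5))
        y = np.array(["a"] * 25 + ["b"] * 25)
        x[:25, 3] += 10.0  # perfect separator
        fm = FeatureMatrix(x, [f"f{i}" for i in range(5)], y)
        fw = relieff_rank(fm, k_neighbors=1)
        assert fw.order[0] == 3
        assert set(fw.order) == set(range(5))

    def test_duplicated_column_preserves_original_weights_exhaustive_k(self, rng):
        """With k covering every same/other-class instance, neighbour
        choice is irrelevant and duplicating a column leaves the
        original features' weights (hence their order) unchanged."""
        x = rng.normal(size=(40, 4))
        y = np.array(["a", "b"] * 20)
        x[y == "a", 1] += 2.0
        fm1 = FeatureMatrix(x, list("abcd"), y)
        w1 = relieff_rank(fm1, k_neighbors=20).weights
        fm2 = FeatureMatrix(np.column_stack([x, x[:, 1]]), list("abcd") + ["dup"], y)
        w2 = relieff_rank(fm2, k_neighbors=20).weights
        np.testing.assert_allclose(w1, w2[:4], atol=1e-12)
        assert w2[4] == pytest.approx(w2[1], abs=1e-12)

    def test_single_class_rejected(self):
        fm = FeatureMatrix(np.zeros((5, 2)), ["a", "b"], np.array(["x"] * 5))
        with pytest.raises(ValueError):
            relieff_rank(fm)


class TestOvaSvm:
    def _blobs(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, (30, 5)), rng.normal(3, 0.1, (30, 5))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        return FeatureMatrix(x, [f"f{i}" for i in range(5)], y)

    def test_separated_blobs_memorised(self, rng):
        fm = self._blobs(rng)
        model = train_svm(fm, gamma=0.001, c=1000.0)
        assert (predict_svm(model, fm) == fm.labels).all()

    def test_single_class_rejected(self):
        fm = FeatureMatrix(np.zeros((4, 2)), ["a", "b"], np.array(["x"] * 4))
        with pytest.raises(ValueError):
            train_svm(fm)

    def test_class_weights_accepted(self, rng):
        fm = self._blobs(rng)
        model = train_svm(fm, class_weights={"a": 2.0, "b": 0.5})
        assert set(predict_svm(model, fm)) <= {"a", "b"}
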