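"""Leave-one-subject-out orchestration of the three pipelines.

Each fold trains every pipeline on all subjects but one and predicts
the held-out subject; out-of-fold predictions are pooled over folds and
a single report is computed per pipeline plus the ensemble.  Folds are
mutually independent, so they may be executed by any number of workers:
each fold's randomness is derived from ``SeedSequence((root_seed,
test_subject_id))``, which makes the pooled results bit-identical for
any ``n_workers >= 1``.

A fold whose training windows cover fewer than two classes cannot be
fitted; it is skipped with a logged warning and its test subject is
absent from the pooled predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from . import cnn as cnn_mod
from . import features as fe
from . import ldaknn
from .activities import ACTIVITY_CLASSES
from .config import RunConfig
from .fusion import ClassificationReport, PredictionSet, class_weights, fuse_predictions
from .segment import FoldPlan, make_fold_plan, segment_recordings

logger = logging.getLogger(__name__)


def fold_seed(root_seed: int, test_subject: int) -> int:
    """Deterministic per-fold seed, independent of execution order."""
    ss = np.random.SeedSequence((int(root_seed), int(test_subject)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class LosoResult:
    predictions: PredictionSet
    reports: dict[str, ClassificationReport]
    fold_plan: FoldPlan
    skipped_subjects: list[int]
    feature_weights: dict[int, np.ndarray]  # per test subject, ReliefF scores


def _segment_kwargs(config: RunConfig) -> dict:
    return dict(
        window_seconds=config.window_seconds,
        overlap=config.overlap,
        fs=config.fs,
    )


def run_fold(train_recordings, test_recordings, config: RunConfig, seed: int) -> dict:
    """Fit all three pipelines on the training subjects and predict the
    held-out subject.  Pure function of its arguments."""
    seg_kwargs = _segment_kwargs(config)
    train = segment_recordings(train_recordings, **seg_kwargs)
    test = segment_recordings(test_recordings, **seg_kwargs)

    train_classes = np.unique(train.labels.astype(str))
    if len(train_classes) < 2:
        return {"skipped": True, "n_classes": len(train_classes)}
    weights = class_weights(train.labels)

    # pipeline 1: handcrafted features -> z-score -> ReliefF -> OvA RBF SVM
    fm_train = fe.extract_features(train)
    zs = fe.zscore_fit(fm_train)
    fm_train_z = fe.zscore_apply(zs, fm_train)
    ranking = fe.relieff_rank(
        fm_train_z, k_neighbors=config.relieff_k,
        n_samples=config.relieff_n_samples, seed=seed,
    )
    keep = ranking.top(config.top_n_features or fm_train_z.n_features)
    keep = np.sort(keep)  # stable column order after selection
    fm_train_sel = fe.FeatureMatrix(
        fm_train_z.values[:, keep],
        [fm_train_z.feature_names[i] for i in keep],
        fm_train_z.labels,
    )
    svm = fe.train_svm(fm_train_sel, class_weights=weights,
                       gamma=config.svm_gamma, c=config.svm_c)

    # pipeline 2: per-channel shrinkage LDA -> concatenation -> KNN
    n_comp = config.lda_components
    max_comp = len(train_classes) - 1
    n_comp = max_comp if n_comp is None else min(n_comp, max_comp)
    proj = ldaknn.lda_fit(train, n_components=n_comp, shrinkage=config.lda_shrinkage)
    knn = ldaknn.knn_train(ldaknn.lda_transform(proj, train), k=config.knn_k)

    # pipeline 3: per-channel CNN
    classes = [c for c in ACTIVITY_CLASSES if c in set(train_classes)]
    cnn_cfg = cnn_mod.CnnConfig(
        **{**config.cnn.__dict__, "n_classes": len(classes), "seed": seed}
    )
    model = cnn_mod.build_model(cnn_cfg, train.window_length, train.n_channels, classes)
    model = cnn_mod.train_cnn(model, train, class_weights=weights)

    if test.n_segments == 0:
        empty = np.empty(0, dtype=object)
        return {
            "skipped": False, "true": empty, "fe": empty, "lda": empty,
            "cnn": empty, "subjects": np.empty(0, dtype=int),
            "relieff_weights": ranking.weights,
        }

    fm_test = fe.zscore_apply(zs, fe.extract_features(test))
    fm_test_sel = fe.FeatureMatrix(
        fm_test.values[:, keep],
        [fm_test.feature_names[i] for i in keep],
        fm_test.labels,
    )
    pred_fe = fe.predict_svm(svm, fm_test_sel)
    pred_lda = ldaknn.knn_predict(knn, ldaknn.lda_transform(proj, test))
    pred_cnn = cnn_mod.predict_cnn(model, test)
    return {
        "skipped": False,
        "true": test.labels.copy(),
        "fe": pred_fe,
        "lda": pred_lda,
        "cnn": pred_cnn,
        "subjects": test.subject_ids.copy(),
        "relieff_weights": ranking.weights,
    }


def run_loso(recordings, config: RunConfig | None = None, n_workers: int = 1) -> LosoResult:
    """Full leave-one-subject-out evaluation of the ensemble.

    Returns pooled out-of-fold predictions and one report per pipeline
    (``fe``, ``lda``, ``cnn``) plus the majority-vote ``ensemble``.
    """
    config = config or RunConfig()
    by_subject: dict[int, list] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    plan = make_fold_plan(by_subject.keys())

    tasks = [
        (
            [r for s in sorted(train_subjects) for r in by_subject[s]],
            by_subject[test_subject],
            config,
            fold_seed(config.seed, test_subject),
        )
        for train_subjects, test_subject in plan
    ]
    results = Parallel(n_jobs=n_workers)(
        delayed(run_fold)(*task) for task in tasks
    )

    skipped, pooled, weights = [], [], {}
    for (train_subjects, test_subject), res in zip(plan, results):
        if res.get("skipped"):
            logger.warning(
                "fold with test subject %s skipped: training set has %d class(es)",
                test_subject, res.get("n_classes", 0),
            )
            skipped.append(test_subject)
            continue
        weights[test_subject] = res["relieff_weights"]
        pooled.append(res)
    if not pooled or all(len(r["true"]) == 0 for r in pooled):
        raise ValueError("no usable folds: every fold was skipped or empty")

    def cat(key):
        return np.concatenate([r[key] for r in pooled])

    true = cat("true")
    pred_fe, pred_lda, pred_cnn = cat("fe"), cat("lda"), cat("cnn")
    fused = fuse_predictions(pred_fe, pred_lda, pred_cnn)
    predictions = PredictionSet(
        true=true, fe=pred_fe, lda=pred_lda, cnn=pred_cnn, fused=fused,
        subject_ids=cat("subjects"),
    )
    reports = {
        name: ClassificationReport.from_predictions(true, pred)
        for name, pred in (
            ("fe", pred_fe), ("lda", pred_lda), ("cnn", pred_cnn), ("ensemble", fused),
        )
    }
    return LosoResult(predictions, reports, plan, skipped, weights)
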