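"""Per-region linear SVMs, decision fusion baselines, and kernel combination.

Every classifier in the pipeline is a linear support vector machine with cost
C = 1; per-region features are the raw normalized voxel intensities of the
region in a fixed raster (axis-major) order.  Region SVM outputs are HARD
labels: the downstream Bayesian network is discrete, so margins are collapsed
to decisions at the hyperplane.  A test point landing exactly on the decision
boundary is assigned the APS (negative) class — an arbitrary but fixed and
configurable convention.

The comparison systems (`baseline_classify`) cover the standard alternatives:
whole-brain voxels-as-features, striatum-only voxels, concatenated selected
regions, per-region majority voting, a multiple-kernel SVM with one linear
kernel per region, and the Bayesian-network fusion itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from ._common import LABEL_PD, LABEL_APS
from .phantom import AtlasVolume
from .preprocess import Volume

logger = logging.getLogger(__name__)

MODES = ("all_voxels", "striatum", "concat_regions", "majority", "mkl", "bayes_net")


@dataclass
class RegionAccuracyTable:
    """Leave-one-out training-set accuracy per region, each in [0, 1]."""

    accuracies: dict[int, float]

    def __post_init__(self) -> None:
        for r, a in self.accuracies.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"region {r}: accuracy {a} outside [0, 1]")


def extract_features(vol: Volume, atlas: AtlasVolume, region_id: int) -> np.ndarray:
    """A region's voxel intensities in deterministic raster (C, axis-major) order."""
    mask = atlas.region_mask(region_id)  # raises on unknown id
    return vol.data[mask]  # boolean indexing follows C order


# ---------------------------------------------------------------------------
# linear SVM plumbing (C=1, hard decisions, tie -> APS)
# ---------------------------------------------------------------------------

class _MajorityClassifier:
    """Degenerate stand-in when a training fold contains a single class."""

    def __init__(self, label: int):
        self.label = int(label)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        val = 1.0 if self.label == LABEL_PD else -1.0
        return np.full(np.asarray(X).shape[0], val)


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0, gram: bool = False):
    """Fit a linear-kernel SVC; single-class folds degrade to majority (logged)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        logger.warning("degenerate single-class training fold; predicting %s", classes[0])
        return _MajorityClassifier(classes[0])
    clf = SVC(C=C, kernel="precomputed" if gram else "linear")
    clf.fit(X, y)
    return clf


def hard_predict(clf, X: np.ndarray) -> np.ndarray:
    """Hard labels from the signed margin; exactly-zero margin maps to APS."""
    df = np.asarray(clf.decision_function(X))
    return np.where(df > 0, LABEL_PD, LABEL_APS)


def linear_gram(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Linear-kernel Gram matrix a @ b.T (b defaults to a)."""
    b = a if b is None else b
    return np.asarray(a, dtype=np.float64) @ np.asarray(b, dtype=np.float64).T


def loo_predictions(
    X: np.ndarray | None,
    y: np.ndarray,
    C: float = 1.0,
    gram: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out hard predictions for every subject.

    ``gram`` may supply a precomputed linear Gram matrix over all subjects to
    avoid refitting kernels per fold (exactly equivalent to the raw-feature
    path for the linear kernel).
    """
    y = np.asarray(y)
    n = y.size
    if gram is None:
        gram = linear_gram(np.asarray(X, dtype=np.float64))
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        clf = fit_linear_svm(gram[np.ix_(tr, tr)], y[tr], C=C, gram=True)
        preds[i] = hard_predict(clf, gram[np.ix_([i], tr)])[0]
    return preds


def loo_region_accuracy(
    features: np.ndarray, labels: np.ndarray, C: float = 1.0,
    gram: np.ndarray | None = None,
) -> float:
    """Fraction of subjects a linear SVM (C=1) predicts correctly under LOO."""
    labels = np.asarray(labels)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class")
    preds = loo_predictions(features, labels, C=C, gram=gram)
    return float(np.mean(preds == labels))


def region_decisions(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    C: float = 1.0,
) -> np.ndarray:
    """Hard PD/APS decision for each test subject from one region's SVM."""
    clf = fit_linear_svm(np.asarray(train_features, float), train_labels, C=C)
    return hard_predict(clf, np.asarray(test_features, float))


def majority_vote(decisions, accuracies=None) -> int:
    """Label with the most votes; ties follow the most accurate region's vote.

    ``accuracies`` is a sequence aligned with ``decisions``; when absent, a
    tied vote falls back to APS (the same convention as the SVM boundary).
    """
    decisions = np.asarray(decisions, dtype=int)
    if decisions.size == 0:
        raise ValueError("majority_vote needs at least one decision")
    n_pd = int(np.sum(decisions == LABEL_PD))
    n_aps = decisions.size - n_pd
    if n_pd != n_aps:
        return LABEL_PD if n_pd > n_aps else LABEL_APS
    if accuracies is None:
        return LABEL_APS
    best = int(np.argmax(np.asarray(accuracies, dtype=float)))
    return int(decisions[best])


def mkl_gram(
    feature_blocks: list[np.ndarray],
    weights=None,
    test_blocks: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Convex combination of per-region linear Gram matrices.

    ``feature_blocks[p]`` holds the region-p features of the (training)
    subjects; ``test_blocks`` optionally supplies a second subject set to
    produce the rectangular test-train kernel.  Weights default to uniform;
    they must be non-negative and sum to 1.  The square combination is
    symmetric PSD, being a non-negative sum of PSD matrices.
    """
    P = len(feature_blocks)
    if P < 1:
        raise ValueError("need at least one kernel block")
    if weights is None:
        weights = np.full(P, 1.0 / P)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (P,):
        raise ValueError(f"expected {P} weights, got shape {weights.shape}")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rows = feature_blocks if test_blocks is None else test_blocks
    K = sum(
        w * linear_gram(np.asarray(ra, float), np.asarray(ca, float))
        for w, ra, ca in zip(weights, rows, feature_blocks)
    )
    return K


def accuracy_weights(accuracies) -> np.ndarray:
    """Accuracy-proportional kernel weights (optional MKL mode)."""
    a = np.asarray(accuracies, dtype=float)
    if np.any(a < 0) or a.sum() <= 0:
        raise ValueError("accuracies must be non-negative with positive sum")
    return a / a.sum()


# ---------------------------------------------------------------------------
# the six comparison systems on one cross-validation fold
# ---------------------------------------------------------------------------

@dataclass
class CohortFold:
    """Feature bundle for one outer fold: training set plus held-out subjects.

    Feature dicts map region id -> (n_subjects, region_voxels) arrays with
    identical raster ordering across subjects; ``selected_regions`` are the
    fold's ROI-selection output, ``striatal_regions`` the atlas tag.
    """

    train_features: dict[int, np.ndarray]
    test_features: dict[int, np.ndarray]
    train_labels: np.ndarray
    selected_regions: list[int]
    striatal_regions: tuple[int, ...] = ()
    region_accuracies: dict[int, float] = field(default_factory=dict)

    def concat(self, region_ids, test: bool = False) -> np.ndarray:
        src = self.test_features if test else self.train_features
        return np.concatenate([src[r] for r in region_ids], axis=1)


def baseline_classify(
    mode: str,
    fold: CohortFold,
    C: float = 1.0,
    bn_model=None,
    mkl_weights=None,
) -> np.ndarray:
    """Predict the fold's held-out subjects with one of the six systems.

    Modes: ``all_voxels`` (every atlas region's voxels), ``striatum``
    (striatal-tagged regions only), ``concat_regions`` (selected regions as a
    single feature vector), ``majority`` (per-region SVM votes),
    ``mkl`` (combined linear kernels, one per selected region) and
    ``bayes_net`` (region decisions fused by a fitted network passed as
    ``bn_model=(structure, cpts)``).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    y = fold.train_labels

    if mode in ("all_voxels", "striatum", "concat_regions"):
        if mode == "all_voxels":
            regions = sorted(fold.train_features)
        elif mode == "striatum":
            regions = [r for r in sorted(fold.train_features)
                       if r in fold.striatal_regions]
            if not regions:
                raise ValueError("no striatal regions available in this fold")
        else:
            regions = fold.selected_regions
        clf = fit_linear_svm(fold.concat(regions), y, C=C)
        return hard_predict(clf, fold.concat(regions, test=True))

    if mode == "mkl":
        blocks = [fold.train_features[r] for r in fold.selected_regions]
        K_train = mkl_gram(blocks, weights=mkl_weights)
        clf = fit_linear_svm(K_train, y, C=C, gram=True)
        K_test = mkl_gram(
            blocks,
            weights=mkl_weights,
            test_blocks=[fold.test_features[r] for r in fold.selected_regions],
        )
        return hard_predict(clf, K_test)

    # decision-fusion modes
    decisions = np.column_stack(
        [
            region_decisions(fold.train_features[r], y, fold.test_features[r], C=C)
            for r in fold.selected_regions
        ]
    )
    acc = [fold.region_accuracies.get(r) for r in fold.selected_regions]
    acc = None if any(a is None for a in acc) else np.asarray(acc, float)

    if mode == "majority":
        return np.array([majority_vote(row, acc) for row in decisions])

    from .bayesnet import classify  # deferred: bayesnet.classify imports this module

    if bn_model is None:
        raise ValueError("bayes_net mode requires bn_model=(structure, cpts)")
    structure, cpts = bn_model
    return np.array(
        [classify(structure, cpts, row, region_accuracies=acc) for row in decisions]
    )
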