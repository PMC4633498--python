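"""Nested leave-one-out evaluation, confusion metrics, and method comparison.

The outer leave-one-out loop holds out one subject at a time; everything that
can learn — region selection from the smoothed t-map, the inner leave-one-out
that assigns each region its accuracy, the per-region SVMs, and the Bayesian
network structure and parameters — is re-fit on the remaining subjects only,
so no information from the held-out subject leaks into its own prediction.
Intensity normalization is per-image and therefore leak-free by construction.

Region selection inside each outer fold is the default (leak-free) protocol;
``selection_scope="global"`` reproduces the simpler whole-cohort selection
behind a config switch.

Metrics follow the standard diagnostic definitions with PD as the positive
class: accuracy, sensitivity, specificity (percent), and the positive /
negative likelihood ratios sens/(1-spec) and (1-sens)/spec computed on
proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._common import LABEL_PD, LABEL_APS
from .phantom import SyntheticCohort
from .preprocess import normalize_intensity, gaussian_smooth
from .roi import voxel_two_sample_t, threshold_map, RegionRanking, select_regions
from .classifiers import (
    MODES,
    CohortFold,
    accuracy_weights,
    baseline_classify,
    linear_gram,
    loo_predictions,
)
from .bayesnet import DiscreteDataset, MHTrace, fit_cpts_map, mh_structure_search

logger = logging.getLogger(__name__)


@dataclass
class EvalConfig:
    """Pipeline settings; defaults follow the study protocol this emulates."""

    n_select_regions: int = 4
    p_threshold: float = 0.001
    smoothing_fwhm_mm: float = 8.0
    top_fraction: float = 0.001
    svm_c: float = 1.0
    mh_iterations: int = 1000
    mh_burn_in: int = 200
    dirichlet_alpha: float = 1.0
    selection_scope: str = "fold"  # "fold" (leak-free) or "global"
    classify_smoothed: bool = False  # t-map always uses smoothed data
    two_tailed: bool = False
    mkl_weighting: str = "uniform"  # or "accuracy"
    methods: tuple[str, ...] = MODES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_scope not in ("fold", "global"):
            raise ValueError(f"unknown selection_scope {self.selection_scope!r}")
        if self.mkl_weighting not in ("uniform", "accuracy"):
            raise ValueError(f"unknown mkl_weighting {self.mkl_weighting!r}")
        unknown = set(self.methods) - set(MODES)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


@dataclass
class FoldResult:
    """Outcome of one outer fold (one held-out subject)."""

    subject_id: str
    true_label: int
    predictions: dict[str, int]
    selected_regions: list[int]
    region_accuracies: dict[int, float]
    bn_edges: list[tuple[int, int]]
    mh_trace: MHTrace | None = field(default=None, repr=False)


@dataclass
class ConfusionMetrics:
    """Diagnostic summary of one method (percentages; LRs on proportions)."""

    accuracy: float
    sensitivity: float
    specificity: float
    positive_likelihood: float
    negative_likelihood: float
    n: int = 0


def confusion_metrics(predictions, truths, positive_label: int = LABEL_PD
                      ) -> ConfusionMetrics:
    """Accuracy / sensitivity / specificity in percent plus likelihood ratios.

    A likelihood ratio with zero denominator is reported as infinity.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    pos = truths == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    correct = predictions == truths
    sens = float(correct[pos].mean()) if n_pos else float("nan")
    spec = float(correct[~pos].mean()) if n_neg else float("nan")
    acc = float(correct.mean())
    lr_pos = sens / (1.0 - spec) if (1.0 - spec) > 0 else float("inf")
    lr_neg = (1.0 - sens) / spec if spec > 0 else float("inf")
    return ConfusionMetrics(
        accuracy=100.0 * acc,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        positive_likelihood=lr_pos,
        negative_likelihood=lr_neg,
        n=predictions.size,
    )


# ---------------------------------------------------------------------------
# nested leave-one-out driver
# ---------------------------------------------------------------------------

class _PreparedCohort:
    """Per-image preprocessing shared across folds (all of it leak-free).

    Normalization is per image; smoothing is per image; per-region Gram
    matrices only cache inner products, and any fold uses exclusively the
    training-row/column submatrices for fitting.
    """

    def __init__(self, cohort: SyntheticCohort, config: EvalConfig):
        self.cohort = cohort
        self.config = config
        atlas = cohort.atlas
        self.labels = np.asarray(cohort.labels, dtype=int)
        self.region_ids = atlas.region_ids
        flat_atlas = atlas.labels.ravel()
        self.brain_idx = np.flatnonzero(flat_atlas > 0)
        brain_labels = flat_atlas[self.brain_idx]
        self.region_cols = {
            r: np.flatnonzero(brain_labels == r) for r in self.region_ids
        }

        n = cohort.n_subjects
        nb = self.brain_idx.size
        feats = np.empty((n, nb))
        smoothed = np.empty((n, nb))
        self.norm_params = []
        for i, vol in enumerate(cohort.volumes):
            norm, params = normalize_intensity(vol, config.top_fraction)
            self.norm_params.append(params)
            sm = gaussian_smooth(norm, config.smoothing_fwhm_mm)
            smoothed[i] = sm.data.ravel()[self.brain_idx]
            src = sm if config.classify_smoothed else norm
            feats[i] = src.data.ravel()[self.brain_idx]
        self.features = feats
        self.smoothed = smoothed
        # per-region linear Gram over all subjects (train submatrices reused per fold)
        self.grams = {
            r: linear_gram(feats[:, cols]) for r, cols in self.region_cols.items()
        }
        self.global_selection: list[int] | None = None
        if config.selection_scope == "global":
            self.global_selection = self._select(np.arange(n))

    def _select(self, train_idx: np.ndarray) -> list[int]:
        """Run the t-map -> threshold -> region-ranking chain on one subject set."""
        cfg = self.config
        y = self.labels[train_idx]
        sm = self.smoothed[train_idx]
        tmap = voxel_two_sample_t(
            sm[y == LABEL_PD], sm[y == LABEL_APS], two_tailed=cfg.two_tailed
        )
        mask = threshold_map(tmap, cfg.p_threshold)
        ranking = RegionRanking(
            fractions={
                r: float(mask[cols].mean()) for r, cols in self.region_cols.items()
            },
            counts={r: cols.size for r, cols in self.region_cols.items()},
        )
        return select_regions(ranking, cfg.n_select_regions)

    def run_fold(self, test_idx: int) -> FoldResult:
        cfg = self.config
        n = self.labels.size
        train = np.setdiff1d(np.arange(n), [test_idx])
        y_train = self.labels[train]

        selected = (
            self.global_selection
            if self.global_selection is not None
            else self._select(train)
        )

        # inner LOO: per-region accuracies + the decision table the BN trains on
        decisions = np.empty((train.size, len(selected)), dtype=np.uint8)
        accuracies: dict[int, float] = {}
        for j, r in enumerate(selected):
            K = self.grams[r][np.ix_(train, train)]
            preds = loo_predictions(None, y_train, C=cfg.svm_c, gram=K)
            decisions[:, j] = preds
            accuracies[r] = float(np.mean(preds == y_train))

        dataset = DiscreteDataset(np.column_stack([decisions, y_train]))
        mh_seed = (cfg.seed * 1_000_003 + test_idx * 7_919 + 1) % 2**31
        structure, trace = mh_structure_search(
            dataset, n_iter=cfg.mh_iterations, burn_in=cfg.mh_burn_in, seed=mh_seed
        )
        cpts = fit_cpts_map(structure, dataset, alpha=cfg.dirichlet_alpha)

        fold = CohortFold(
            train_features={
                r: self.features[np.ix_(train, cols)]
                for r, cols in self.region_cols.items()
            },
            test_features={
                r: self.features[np.ix_([test_idx], cols)]
                for r, cols in self.region_cols.items()
            },
            train_labels=y_train,
            selected_regions=selected,
            striatal_regions=self.cohort.atlas.striatal_regions,
            region_accuracies=accuracies,
        )
        mkl_w = (
            accuracy_weights([accuracies[r] for r in selected])
            if cfg.mkl_weighting == "accuracy"
            else None
        )
        predictions: dict[str, int] = {}
        for mode in cfg.methods:
            preds = baseline_classify(
                mode,
                fold,
                C=cfg.svm_c,
                bn_model=(structure, cpts),
                mkl_weights=mkl_w if mode == "mkl" else None,
            )
            predictions[mode] = int(preds[0])

        return FoldResult(
            subject_id=self.cohort.volumes[test_idx].subject_id,
            true_label=int(self.labels[test_idx]),
            predictions=predictions,
            selected_regions=list(selected),
            region_accuracies=accuracies,
            bn_edges=sorted(structure.edges),
            mh_trace=trace,
        )


def run_fold(cohort: SyntheticCohort, config: EvalConfig, test_idx: int) -> FoldResult:
    """Prepare the cohort and evaluate a single outer fold (mainly for tests)."""
    return _PreparedCohort(cohort, config).run_fold(test_idx)


def nested_loo(cohort: SyntheticCohort, config: EvalConfig | None = None
               ) -> list[FoldResult]:
    """Two-level (nested) leave-one-out evaluation of all configured methods."""
    config = config or EvalConfig()
    labels = np.asarray(cohort.labels)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class")
    prepared = _PreparedCohort(cohort, config)
    results = []
    for i in range(cohort.n_subjects):
        results.append(prepared.run_fold(i))
        logger.info(
            "fold %d/%d subject=%s regions=%s",
            i + 1, cohort.n_subjects,
            results[-1].subject_id, results[-1].selected_regions,
        )
    return results


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

METHOD_TITLES = {
    "all_voxels": "All the voxels in the brain",
    "striatum": "Only striatum",
    "concat_regions": "Selected regions as a whole",
    "majority": "Multiple SVM (majority voting)",
    "mkl": "Multiple kernel SVM",
    "bayes_net": "Proposed method (Bayesian network)",
}


def compare_methods(fold_results: list[FoldResult]) -> pd.DataFrame:
    """One metrics row per method (Table-style layout, 2-decimal rounding)."""
    if not fold_results:
        raise ValueError("no fold results")
    methods = list(fold_results[0].predictions)
    truths = np.array([f.true_label for f in fold_results])
    rows = {}
    for m in methods:
        try:
            preds = np.array([f.predictions[m] for f in fold_results])
        except KeyError as exc:
            raise ValueError(f"method {m!r} missing from a fold result") from exc
        cm = confusion_metrics(preds, truths)
        rows[m] = {
            "accuracy": round(cm.accuracy, 2),
            "sensitivity": round(cm.sensitivity, 2),
            "specificity": round(cm.specificity, 2),
            "positive_likelihood": round(cm.positive_likelihood, 2),
            "negative_likelihood": round(cm.negative_likelihood, 2),
        }
    order = [m for m in MODES if m in rows] + [m for m in rows if m not in MODES]
    return pd.DataFrame.from_dict(rows, orient="index").loc[order]


def fold_frame(fold_results: list[FoldResult]) -> pd.DataFrame:
    """Long-format per-fold record for the run report CSV."""
    rows = []
    for f in fold_results:
        row = {
            "subject_id": f.subject_id,
            "true_label": f.true_label,
            "selected_regions": ";".join(map(str, f.selected_regions)),
            "mh_acceptance_ratio": (
                f.mh_trace.acceptance_ratio if f.mh_trace else float("nan")
            ),
        }
        row.update({f"pred_{m}": p for m, p in f.predictions.items()})
        row.update({f"acc_region_{r}": a for r, a in f.region_accuracies.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    fold_results: list[FoldResult],
    config: EvalConfig,
    out_dir: str | Path,
    plot_trace: bool = True,
) -> pd.DataFrame:
    """Write comparison table, per-fold CSV, config header and the MH trace plot."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = compare_methods(fold_results)
    table.to_csv(out_dir / "comparison.csv")
    (out_dir / "comparison.json").write_text(table.to_json(orient="index", indent=2))
    fold_frame(fold_results).to_csv(out_dir / "folds.csv", index=False)
    (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    if plot_trace and fold_results and fold_results[0].mh_trace is not None:
        try:
            _plot_mh_trace(fold_results[0].mh_trace, out_dir / "mh_trace.png")
        except ImportError:  # plotting backend is optional
            logger.info("matplotlib unavailable; skipping the MH trace plot")
    return table


def _plot_mh_trace(trace: MHTrace, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(trace.cumulative_acceptance())
    ax.set_xlabel("iteration")
    ax.set_ylabel("cumulative acceptance ratio")
    ax.set_title("MH structure-search acceptance")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
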