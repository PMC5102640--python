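"""Exhaustive wrapper feature-subset selection.

Every non-empty subset of the 11 feature names is scored by repeated
random-subsampling classification (stratified 70/30 split, default 1000
repeats) with a Decision Tree; LDA and a polynomial-kernel SVM are provided
for the classifier comparison.  One run-seed sequence is shared across all
subsets (common random numbers) so subset comparisons are paired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from nirsmark.hemo_features import FEATURE_NAMES

__all__ = [
    "ConfusionCounts",
    "EvaluationMetrics",
    "SubsetScore",
    "RocCurve",
    "enumerate_subsets",
    "expand_subset_columns",
    "random_subsample_split",
    "confusion_metrics",
    "train_classifier",
    "evaluate_subset",
    "wrapper_search",
    "averaged_roc",
    "task_load_comparison",
]

POSITIVE_LABEL = "tbi"  # positive class; "healthy" is the negative class
CLASSIFIERS = ("decision_tree", "lda", "svm_poly")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvaluationMetrics:
    """Mean +/- SD of accuracy/sensitivity/specificity over subsampling runs."""

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float = 0.0
    sensitivity_sd: float = 0.0
    specificity_sd: float = 0.0
    n_runs: int = 1
    n_failed: int = 0


@dataclass
class SubsetScore:
    subset: tuple[str, ...]
    metrics: EvaluationMetrics

    @property
    def size(self) -> int:
        return len(self.subset)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def enumerate_subsets(feature_names=FEATURE_NAMES) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically.

    The spectral feature counts as one atomic name here, preserving the
    ``2^11 - 1 = 2047`` subset arithmetic.
    """
    names = tuple(feature_names)
    p = len(names)
    if not 1 <= p <= 20:
        raise ValueError(f"refusing exhaustive enumeration for p={p} (allowed 1..20)")
    subsets: list[tuple[str, ...]] = []
    for size in range(1, p + 1):
        subsets.extend(sorted(itertools.combinations(sorted(names), size)))
    return subsets


def feature_names_from_columns(columns) -> tuple[str, ...]:
    """Infer atomic feature names from table columns (HDFT_k -> HDFT)."""
    names: list[str] = []
    for c in columns:
        base = c.split("_")[0] if c.startswith("HDFT_") else c
        if base not in names:
            names.append(base)
    return tuple(names)


def expand_subset_columns(
    subset: tuple[str, ...], columns: list[str]
) -> list[str]:
    """Map feature names to table columns, expanding HDFT to HDFT_1..k."""
    out: list[str] = []
    for name in subset:
        if name in columns:
            out.append(name)
        else:
            expanded = sorted(c for c in columns if c.startswith(f"{name}_"))
            if not expanded:
                raise KeyError(f"feature {name!r} not found in the table")
            out.extend(expanded)
    return out


def random_subsample_split(
    labels: np.ndarray, train_frac: float = 0.70, rng=None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test partition of subject indices.

    Per class, ``round(train_frac * n)`` subjects go to training (capped so
    at least one member of each class remains in the test set).
    """
    labels = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    train, test = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as exact ratios."""
    total = counts.tp + counts.tn + counts.fp + counts.fn
    if total == 0 or counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("confusion counts leave a metric denominator empty")
    accuracy = (counts.tp + counts.tn) / total
    sensitivity = counts.tp / (counts.tp + counts.fn)
    specificity = counts.tn / (counts.tn + counts.fp)
    return accuracy, sensitivity, specificity


def train_classifier(spec: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit a classifier and return ``(model, score_fn)``.

    ``score_fn`` maps a feature matrix to a continuous positive-class score
    for ROC construction: positive-class leaf fraction for the tree, the
    discriminant value for LDA, and the decision margin for the SVM.
    """
    if spec == "decision_tree":
        model = DecisionTreeClassifier(criterion="gini", random_state=seed)
        model.fit(X, y)
        pos_col = list(model.classes_).index(POSITIVE_LABEL)
        return model, lambda Z: model.predict_proba(Z)[:, pos_col]
    if spec == "lda":
        # small covariance ridge guards against singular pooled covariance
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
        model.fit(X, y)
        sign = 1.0 if model.classes_[1] == POSITIVE_LABEL else -1.0
        return model, lambda Z: sign * model.decision_function(Z)
    if spec == "svm_poly":
        model = SVC(kernel="poly", degree=3, C=1.0)
        model.fit(X, y)
        sign = 1.0 if model.classes_[1] == POSITIVE_LABEL else -1.0
        return model, lambda Z: sign * model.decision_function(Z)
    raise ValueError(f"unknown classifier {spec!r}; choose from {CLASSIFIERS}")


def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    """Deterministic per-run seed sequence shared across subsets."""
    return np.random.SeedSequence(seed).generate_state(n_runs)


_split_cache: dict = {}


def _cached_splits(y: np.ndarray, seeds: np.ndarray, train_frac: float):
    """Per-run splits depend only on (labels, seeds, fraction); memoize so
    the 2047-subset search does not redraw identical partitions."""
    key = (y.tobytes(), seeds.tobytes(), train_frac)
    if key not in _split_cache:
        if len(_split_cache) > 8:
            _split_cache.clear()
        _split_cache[key] = [
            random_subsample_split(y, train_frac, rng=np.random.default_rng(s))
            for s in seeds
        ]
    return _split_cache[key]


def repeated_subsampling(
    X: np.ndarray,
    y: np.ndarray,
    classifier_spec: str = "decision_tree",
    n_runs: int = 1000,
    seed: int = 0,
    *,
    train_frac: float = 0.70,
    collect_scores: bool = False,
    max_failure_frac: float = 0.01,
    fit_predict=None,
) -> tuple[EvaluationMetrics, list[tuple[np.ndarray, np.ndarray]]]:
    """Core repeated random-subsampling evaluation engine.

    Each run draws a fresh stratified 70/30 split, trains on the training
    side, predicts the test side, and records accuracy, sensitivity and
    specificity; means and SDs are taken over runs.  A failing run is
    excluded and counted; more than ``max_failure_frac`` failures aborts.

    ``fit_predict(X_tr, y_tr, X_te, run_seed) -> (predictions, scores)``
    may override the default classifier path (used for missing-data modes).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y)
    seeds = _run_seeds(seed, n_runs)
    splits = _cached_splits(y, seeds, train_frac)
    accs, sens, specs = [], [], []
    score_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    n_failed = 0
    for run_seed, (train_idx, test_idx) in zip(seeds, splits):
        try:
            if fit_predict is not None:
                pred, scores = fit_predict(
                    X[train_idx], y[train_idx], X[test_idx], int(run_seed)
                )
            elif classifier_spec == "decision_tree" and not collect_scores:
                model = DecisionTreeClassifier(
                    criterion="gini", random_state=int(run_seed)
                )
                model.fit(X[train_idx], y[train_idx])
                pred = model.predict(X[test_idx])
                scores = None
            else:
                model, score_fn = train_classifier(
                    classifier_spec, X[train_idx], y[train_idx], seed=int(run_seed)
                )
                pred = model.predict(X[test_idx])
                scores = score_fn(X[test_idx]) if collect_scores else None
        except Exception:
            n_failed += 1
            continue
        y_te = y[test_idx]
        pos, neg = y_te == POSITIVE_LABEL, y_te != POSITIVE_LABEL
        counts = ConfusionCounts(
            tp=int(np.sum(pred[pos] == POSITIVE_LABEL)),
            fn=int(np.sum(pred[pos] != POSITIVE_LABEL)),
            tn=int(np.sum(pred[neg] != POSITIVE_LABEL)),
            fp=int(np.sum(pred[neg] == POSITIVE_LABEL)),
        )
        a, s, p = confusion_metrics(counts)
        accs.append(a)
        sens.append(s)
        specs.append(p)
        if collect_scores:
            score_pairs.append((np.asarray(scores, float), pos.astype(int)))
    if n_failed > max_failure_frac * n_runs:
        raise RuntimeError(f"{n_failed}/{n_runs} classification runs failed")
    metrics = EvaluationMetrics(
        accuracy=float(np.mean(accs)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(specs)),
        accuracy_sd=float(np.std(accs)),
        sensitivity_sd=float(np.std(sens)),
        specificity_sd=float(np.std(specs)),
        n_runs=len(accs),
        n_failed=n_failed,
    )
    return metrics, score_pairs


def evaluate_subset(
    features: pd.DataFrame,
    labels: np.ndarray,
    subset: tuple[str, ...],
    classifier_spec: str = "decision_tree",
    n_runs: int = 1000,
    seed: int = 0,
    *,
    collect_scores: bool = False,
):
    """Score one feature subset by repeated random-subsampling classification.

    ``features`` must be a complete (no-missing) table whose columns include
    the scalar features and the expanded spectral columns.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    cols = expand_subset_columns(tuple(subset), list(features.columns))
    X = features[cols].to_numpy(dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("feature table contains missing values")
    metrics, pairs = repeated_subsampling(
        X, labels, classifier_spec, n_runs, seed, collect_scores=collect_scores
    )
    score = SubsetScore(subset=tuple(subset), metrics=metrics)
    return (score, pairs) if collect_scores else score


def wrapper_search(
    features: pd.DataFrame,
    labels: np.ndarray,
    classifier_spec: str = "decision_tree",
    n_runs: int = 1000,
    seed: int = 0,
    feature_names=FEATURE_NAMES,
) -> dict:
    """Evaluate every non-empty feature subset and rank them.

    Returns a dict with all ``scores``, the per-``size`` optima (ties broken
    toward the lexicographically smaller subset), the ``best`` overall
    subset, and a tabular ``report``.  All subsets share the same run-seed
    sequence, so their metric differences are paired comparisons.
    """
    subsets = enumerate_subsets(feature_names)
    scores = [
        evaluate_subset(features, labels, s, classifier_spec, n_runs, seed)
        for s in subsets
    ]
    by_size: dict[int, SubsetScore] = {}
    for sc in scores:
        cur = by_size.get(sc.size)
        if (
            cur is None
            or sc.metrics.accuracy > cur.metrics.accuracy
            or (sc.metrics.accuracy == cur.metrics.accuracy and sc.subset < cur.subset)
        ):
            by_size[sc.size] = sc
    best = min(scores, key=lambda sc: (-sc.metrics.accuracy, sc.size, sc.subset))
    report = pd.DataFrame(
        [
            {
                "subset": "+".join(sc.subset),
                "size": sc.size,
                "accuracy": sc.metrics.accuracy,
                "accuracy_sd": sc.metrics.accuracy_sd,
                "sensitivity": sc.metrics.sensitivity,
                "sensitivity_sd": sc.metrics.sensitivity_sd,
                "specificity": sc.metrics.specificity,
                "specificity_sd": sc.metrics.specificity_sd,
            }
            for sc in scores
        ]
    )
    return {"scores": scores, "by_size": by_size, "best": best, "report": report}


def _staircase_on_grid(
    fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Sample an empirical ROC staircase onto an FPR grid.

    Duplicated FPR values are vertical jumps; between distinct FPRs the
    curve sits on its plateau.  Grid points landing exactly on a jump take
    the midpoint (upper value at the left edge, lower at the right edge), so
    grid trapezoid integration reproduces the exact empirical AUC whenever
    the jump locations lie on the grid.
    """
    uniq = np.unique(fpr)
    first = np.searchsorted(fpr, uniq, side="left")
    last = np.searchsorted(fpr, uniq, side="right") - 1
    t_lo, t_hi = tpr[first], tpr[last]
    j = np.searchsorted(uniq, grid, side="left")
    j_cl = np.minimum(j, uniq.size - 1)
    exact = uniq[j_cl] == grid
    out = np.empty_like(grid)
    plateau = np.maximum(j, 1) - 1  # between jumps: level after the previous one
    out[~exact] = t_hi[plateau[~exact]]
    mid = (t_lo[j_cl] + t_hi[j_cl]) / 2.0
    out[exact] = mid[exact]
    if exact[0] and j_cl[0] == 0:
        out[0] = t_hi[0]
    if exact[-1] and j_cl[-1] == uniq.size - 1:
        out[-1] = t_lo[-1]
    return out


def averaged_roc(
    score_pairs: list[tuple[np.ndarray, np.ndarray]],
    n_grid: int = 101,
) -> RocCurve:
    """Vertically averaged ROC over runs on a fixed FPR grid, AUC by trapezoid.

    Each run's empirical ROC (exhaustive threshold sweep over its scores) is
    interpolated onto the grid; a run with constant scores contributes the
    chance diagonal.
    """
    if not score_pairs:
        raise ValueError("need at least one run with scores")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for scores, is_pos in score_pairs:
        scores = np.asarray(scores, float)
        is_pos = np.asarray(is_pos, int)
        if is_pos.min() == is_pos.max():
            continue  # single-class test set cannot contribute
        if np.ptp(scores) == 0:
            tprs.append(grid.copy())
            continue
        order = np.argsort(-scores, kind="stable")
        sp = is_pos[order]
        tp = np.concatenate([[0], np.cumsum(sp)])
        fp = np.concatenate([[0], np.cumsum(1 - sp)])
        tpr = tp / tp[-1]
        fpr = fp / fp[-1]
        tprs.append(_staircase_on_grid(fpr, tpr, grid))
    if not tprs:
        raise ValueError("no run had both classes in its test set")
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return RocCurve(fpr=grid, tpr=mean_tpr, auc=auc)


def task_load_comparison(
    subjects,
    subset: tuple[str, ...],
    conditions: tuple[str, ...] = ("Font", "LowComplexity", "HighComplexity"),
    classifier_spec: str = "decision_tree",
    n_runs: int = 1000,
    seed: int = 0,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Re-run QC -> features -> subset evaluation per task condition.

    ``subjects`` are ``(subject_id, group, HemoSignals, EventSchedule)``
    tuples.  A condition in which fewer than two subjects per class survive
    QC is reported as not evaluable (NaN metrics).
    """
    from nirsmark import hemo_features as hf
    from nirsmark.pipeline import condition_features

    rows = []
    for cond in conditions:
        feats, _report = condition_features(subjects, cond, **pipeline_kwargs)
        table = hf.temporal_table(feats)
        row = {"condition": cond, "n_subjects": len(table)}
        evaluable = (
            not table.empty
            and table["group"].nunique() == 2
            and table["group"].value_counts().min() >= 2
        )
        if evaluable:
            sc = evaluate_subset(
                table.drop(columns=["subject", "group"]),
                table["group"].to_numpy(),
                subset,
                classifier_spec,
                n_runs,
                seed,
            )
            row.update(
                accuracy=sc.metrics.accuracy,
                accuracy_sd=sc.metrics.accuracy_sd,
                sensitivity=sc.metrics.sensitivity,
                sensitivity_sd=sc.metrics.sensitivity_sd,
                specificity=sc.metrics.specificity,
                specificity_sd=sc.metrics.specificity_sd,
            )
        else:
            row.update(
                accuracy=np.nan, accuracy_sd=np.nan, sensitivity=np.nan,
                sensitivity_sd=np.nan, specificity=np.nan, specificity_sd=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)
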