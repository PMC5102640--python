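"""Per-channel (spatio-temporal) classification and population activity maps.

A subject's spatio-temporal representation of one feature is its vector of
up to 16 per-channel values; channels rejected by QC appear as missing
entries.  Decision trees handle the missingness natively (learned default
split direction); LDA/SVM fall back to train-mean imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nirsmark.hemo_features import SCALAR_FEATURES
from nirsmark.synth_cohort import N_CHANNELS
from nirsmark.wrapper_select import (
    EvaluationMetrics,
    repeated_subsampling,
    train_classifier,
)

__all__ = [
    "SpatioTemporalMatrix",
    "ActivityMap",
    "build_matrix",
    "classify_spatiotemporal",
    "activity_map",
    "hemisphere_contrast",
    "default_layout",
]


@dataclass
class SpatioTemporalMatrix:
    """Subjects x channel-columns matrix of one feature with NaN missingness."""

    feature: str
    values: np.ndarray  # (n_subjects, n_columns), NaN = missing channel
    labels: np.ndarray  # group per subject
    subjects: list[str]
    columns: list[str]  # e.g. ch01 .. ch16 (x n_coeff for vector features)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass
class ActivityMap:
    """Missing-aware per-channel population means of one feature."""

    feature: str
    population: str
    channel_mean: np.ndarray  # (16,), NaN where no subject contributed
    channel_n: np.ndarray  # (16,) contributing-subject counts


def build_matrix(
    long_table: pd.DataFrame, feature: str, n_channels: int = N_CHANNELS
) -> SpatioTemporalMatrix:
    """Pivot the long spatio-temporal table into one feature's matrix.

    ``long_table`` columns: subject, group, channel (1-based), feature,
    value (NaN for dropped channels).  Vector-valued features select every
    ``<feature>_k`` column, giving ``n_channels * k`` matrix columns.
    """
    names = sorted(long_table["feature"].unique())
    if feature in names:
        selected = [feature]
    else:
        selected = sorted(n for n in names if n.startswith(f"{feature}_"))
        if not selected:
            raise KeyError(f"feature {feature!r} not in the table")
    sub = long_table[long_table["feature"].isin(selected)]
    wide = sub.pivot_table(
        index="subject", columns=["feature", "channel"], values="value",
        dropna=False,
    )
    # enforce the full channel grid even if a channel is missing everywhere
    cols = [
        (f, ch) for f in selected for ch in range(1, n_channels + 1)
    ]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    groups = sub.drop_duplicates("subject").set_index("subject")["group"]
    wide = wide.loc[sorted(wide.index)]
    return SpatioTemporalMatrix(
        feature=feature,
        values=wide.to_numpy(dtype=float),
        labels=groups.loc[wide.index].to_numpy(),
        subjects=list(wide.index),
        columns=[f"{f}_ch{ch:02d}" for f, ch in cols],
    )


def _impute_fit_predict(classifier_spec: str):
    def fit_predict(X_tr, y_tr, X_te, run_seed):
        cnt = np.sum(~np.isnan(X_tr), axis=0)
        means = np.nansum(X_tr, axis=0) / np.maximum(cnt, 1)  # 0 if all missing
        X_tr = np.where(np.isnan(X_tr), means, X_tr)
        X_te = np.where(np.isnan(X_te), means, X_te)
        model, score_fn = train_classifier(classifier_spec, X_tr, y_tr, run_seed)
        return model.predict(X_te), score_fn(X_te)

    return fit_predict


def classify_spatiotemporal(
    matrix: SpatioTemporalMatrix,
    classifier_spec: str = "decision_tree",
    n_runs: int = 1000,
    seed: int = 0,
    *,
    max_missing_frac: float = 0.90,
) -> EvaluationMetrics | None:
    """Repeated-subsampling classification on one feature's channel matrix.

    Decision trees consume the NaN entries directly (missing samples follow
    a learned default direction at each split); the LDA/SVM comparison modes
    impute train-set channel means first.  Returns ``None`` (not evaluable)
    when more than ``max_missing_frac`` of all entries are missing.
    """
    if matrix.missing_fraction > max_missing_frac:
        return None
    fit_predict = (
        None if classifier_spec == "decision_tree"
        else _impute_fit_predict(classifier_spec)
    )
    metrics, _ = repeated_subsampling(
        matrix.values,
        matrix.labels,
        classifier_spec,
        n_runs,
        seed,
        fit_predict=fit_predict,
    )
    return metrics


def spatiotemporal_report(
    long_table: pd.DataFrame,
    features: tuple[str, ...] = SCALAR_FEATURES,
    classifier_spec: str = "decision_tree",
    n_runs: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature spatio-temporal classification metrics table."""
    rows = []
    for name in features:
        matrix = build_matrix(long_table, name)
        m = classify_spatiotemporal(matrix, classifier_spec, n_runs, seed)
        row = {"feature": name, "evaluable": m is not None}
        if m is not None:
            row.update(
                accuracy=m.accuracy, accuracy_sd=m.accuracy_sd,
                sensitivity=m.sensitivity, sensitivity_sd=m.sensitivity_sd,
                specificity=m.specificity, specificity_sd=m.specificity_sd,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def activity_map(
    matrix: SpatioTemporalMatrix, population: str, n_channels: int = N_CHANNELS
) -> ActivityMap:
    """Missing-aware per-channel mean of one feature over a population."""
    mask = matrix.labels == population
    if not mask.any():
        raise ValueError(f"no subjects in population {population!r}")
    vals = matrix.values[mask]
    k = vals.shape[1] // n_channels  # vector features: average their bins
    per_ch = vals.reshape(vals.shape[0], k, n_channels).mean(axis=1)
    n = np.sum(~np.isnan(per_ch), axis=0)
    mean = np.where(n > 0, np.nansum(per_ch, axis=0) / np.maximum(n, 1), np.nan)
    return ActivityMap(
        feature=matrix.feature,
        population=population,
        channel_mean=mean,
        channel_n=n.astype(int),
    )


def default_layout(n_channels: int = N_CHANNELS) -> dict[int, str]:
    """Stand-in channel->hemisphere assignment: 1-8 left, 9-16 right."""
    half = n_channels // 2
    return {
        ch: ("left" if ch <= half else "right") for ch in range(1, n_channels + 1)
    }


def hemisphere_contrast(
    amap: ActivityMap, layout: dict[int, str] | None = None
) -> dict[str, float]:
    """Mean map value per hemisphere and the left-minus-right difference."""
    layout = layout or default_layout()
    sides: dict[str, list[float]] = {}
    for ch in range(1, amap.channel_mean.size + 1):
        if ch not in layout:
            raise KeyError(f"layout does not assign channel {ch}")
        v = amap.channel_mean[ch - 1]
        if np.isfinite(v):
            sides.setdefault(layout[ch], []).append(float(v))
    out = {side: float(np.mean(v)) for side, v in sides.items()}
    out["left_minus_right"] = out.get("left", np.nan) - out.get("right", np.nan)
    return out
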