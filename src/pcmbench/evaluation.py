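"""Per-protein metrics, baseline adjustment, and predicted-ratio tables.

Metrics are computed per protein x fold x strategy on the test-set
predictions: balanced accuracy, macro-averaged F1, Matthews correlation
coefficient (MCC) and AUROC, plus plain accuracy (used for epoch selection
and reported alongside the headline four).  AUROC uses raw scores; the
others use predictions binarized at 0.5 (a score of exactly 0.5 counts as
active, matching the baseline's [0.5, 1] active interval).

Undefined values are represented as NaN and excluded downstream with a
per-metric exclusion count: balanced accuracy and AUROC are undefined when
the test labels are single-class, MCC whenever any contingency marginal is
zero.  A per-class F1 with a zero denominator scores 0, so macro-F1 stays
defined on degenerate proteins.

The *adjusted* metric is the model's value minus its paired imbalance-aware
baseline's value: positive means the model beats imbalance-matched chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pcmbench.strategies import StrategyName, StrategyRun

METRICS = ("balanced_accuracy", "macro_f1", "mcc", "auroc")
ALL_METRICS = METRICS + ("accuracy",)


def binarize_scores(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Active (1) iff score >= threshold."""
    return (np.asarray(scores) >= threshold).astype(int)


def _check_lengths(labels, predictions) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {predictions.shape} predictions"
        )
    return labels, predictions


def _confusion(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return tp, tn, fp, fn


def accuracy(labels, predictions) -> float:
    labels, predictions = _check_lengths(labels, predictions)
    if len(labels) == 0:
        return np.nan
    return float(np.mean(labels == predictions))


def balanced_accuracy(labels, predictions) -> float:
    """Mean of sensitivity and specificity; NaN if either class is absent."""
    labels, predictions = _check_lengths(labels, predictions)
    tp, tn, fp, fn = _confusion(labels, predictions)
    if tp + fn == 0 or tn + fp == 0:
        return np.nan
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def macro_f1(labels, predictions) -> float:
    """Unweighted mean of the two per-class F1 values (zero-denominator F1 = 0)."""
    labels, predictions = _check_lengths(labels, predictions)
    if len(labels) == 0:
        return np.nan
    tp, tn, fp, fn = _confusion(labels, predictions)
    f1_active = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    f1_inactive = 2 * tn / (2 * tn + fn + fp) if (2 * tn + fn + fp) > 0 else 0.0
    return 0.5 * (f1_active + f1_inactive)


def mcc(labels, predictions) -> float:
    """Matthews correlation coefficient; NaN when any marginal is zero."""
    labels, predictions = _check_lengths(labels, predictions)
    tp, tn, fp, fn = _confusion(labels, predictions)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return np.nan
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def auroc(labels, scores) -> float:
    """P(random active outranks random inactive), ties half; NaN single-class."""
    labels, scores = _check_lengths(labels, np.asarray(scores, dtype=float))
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    # Mann-Whitney U via midranks handles ties exactly
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


_METRIC_FUNCS = {
    "balanced_accuracy": balanced_accuracy,
    "macro_f1": macro_f1,
    "mcc": mcc,
    "accuracy": accuracy,
}


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """All five metrics for one protein's test predictions."""
    labels = np.asarray(labels)
    predictions = binarize_scores(scores, threshold)
    out = {name: fn(labels, predictions) for name, fn in _METRIC_FUNCS.items()}
    out["auroc"] = auroc(labels, scores)
    return out


def adjust_metric(metric_model: float, metric_baseline: float) -> float:
    """Baseline-adjusted metric: model minus paired baseline; NaN propagates."""
    return metric_model - metric_baseline


@dataclass
class ExtremeCases:
    """Per-strategy tabulation of all-active / all-inactive predictions."""

    n_observations: int
    pct_all_active: float
    pct_all_inactive: float


def characterize_predictions(
    runs: list[StrategyRun],
    predictions: dict[int, np.ndarray],
    baseline_scores: dict[int, np.ndarray] | None = None,
    sequences: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ExtremeCases]:
    """Build the protein x fold observation table for one strategy.

    ``predictions[fold_index]`` holds one score per test record, in record
    order; ``baseline_scores`` likewise for the random baseline.  For each
    protein with test records the table carries the training/test/predicted
    active ratios (r_training, r_test, r_pred), the interaction count in
    the test set (n_int), the sequence length (n_seq), the test count
    (n_test) and every raw/baseline/adjusted metric.  Proteins with zero
    test records in a fold are simply absent.  Also tabulates the
    percentage of protein x fold cases predicted all-active / all-inactive.
    """
    rows = []
    n_all_active = n_all_inactive = 0
    for run in runs:
        scores = np.asarray(predictions[run.fold_index], dtype=float)
        if len(scores) != len(run.test):
            raise ValueError(
                f"fold {run.fold_index}: {len(scores)} scores for "
                f"{len(run.test)} test records"
            )
        base = None
        if baseline_scores is not None:
            base = np.asarray(baseline_scores[run.fold_index], dtype=float)
            if len(base) != len(run.test):
                raise ValueError("baseline scores misaligned with test records")
        train_by_protein: dict[str, list[int]] = {}
        for rec in run.train:
            train_by_protein.setdefault(rec.protein_id, []).append(rec.label)
        test_index: dict[str, list[int]] = {}
        for i, rec in enumerate(run.test):
            test_index.setdefault(rec.protein_id, []).append(i)
        global_train_ratio = (
            float(np.mean([r.label for r in run.train])) if run.train else 0.5
        )
        for pid in sorted(test_index):
            idx = np.array(test_index[pid])
            labels = np.array([run.test[i].label for i in idx])
            s = scores[idx]
            pred = binarize_scores(s)
            r_pred = float(pred.mean())
            if r_pred == 1.0:
                n_all_active += 1
            elif r_pred == 0.0:
                n_all_inactive += 1
            train_labels = train_by_protein.get(pid)
            r_training = (
                float(np.mean(train_labels))
                if train_labels
                else global_train_ratio  # fallback for proteins absent from train
            )
            row = {
                "protein_id": pid,
                "strategy": run.strategy.value,
                "k_fold": run.fold_index,
                "r_training": r_training,
                "r_test": float(labels.mean()),
                "r_pred": r_pred,
                "n_int": len(idx),
                "n_test": len(idx),
                "n_seq": len(sequences[pid]) if sequences else np.nan,
            }
            for name, value in compute_metrics(labels, s).items():
                row[name] = value
            if base is not None:
                base_metrics = compute_metrics(labels, base[idx])
                for name, value in base_metrics.items():
                    row[f"baseline_{name}"] = value
                    row[f"adjusted_{name}"] = adjust_metric(row[name], value)
            rows.append(row)
    table = pd.DataFrame(rows)
    n_obs = len(table)
    extremes = ExtremeCases(
        n_observations=n_obs,
        pct_all_active=100.0 * n_all_active / n_obs if n_obs else np.nan,
        pct_all_inactive=100.0 * n_all_inactive / n_obs if n_obs else np.nan,
    )
    return table, extremes


def exclusion_counts(table: pd.DataFrame) -> dict[str, int]:
    """How many observations each metric loses to undefined values."""
    return {m: int(table[m].isna().sum()) for m in ALL_METRICS if m in table}


def wilcoxon_paired(values_a, values_b) -> float:
    """Two-sided paired signed-rank p-value; incomplete pairs are dropped."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError(f"need >= 2 complete pairs, got {len(a)}")
    if np.all(a == b):
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="zsplit", alternative="two-sided").pvalue)
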