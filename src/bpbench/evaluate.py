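"""Evaluation metrics for BP estimation: ME, SD, MAE and MASE.

MASE (mean absolute scaled error) scales a model's MAE by the MAE of the
naive predictor — the constant training-set mean — so 100% means "no better
than predicting the mean" regardless of the dataset's BP range.  Metrics
are always computed on predictions pooled across folds, never by averaging
per-fold metrics; the naive denominator uses each fold's own training mean
so that it never sees test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (CoverageError, DataError, PairingError,
                     UndefinedMetricError)

__all__ = [
    "PredictionSet", "EvaluationReport",
    "mean_error", "sd_of_differences", "mean_absolute_error",
    "naive_predictor", "mase", "pooled_metrics",
    "labels_from_predicted_abp", "bootstrap_compare",
]


@dataclass
class PredictionSet:
    """Paired predictions and references for one target (SBP or DBP).

    ``frame`` columns: segment_key, subject_id, fold, ref, pred and
    (optionally) naive — the fold-wise naive prediction.
    """

    frame: pd.DataFrame
    target: str = "SBP"

    def __post_init__(self):
        required = {"ref", "pred"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"PredictionSet missing columns {missing}")
        if len(self.frame) < 1:
            raise DataError("empty prediction set")
        vals = self.frame[["ref", "pred"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataError("non-finite predictions or references")

    @property
    def diff(self) -> np.ndarray:
        """Diff_i = predicted - reference, mmHg."""
        return (self.frame["pred"] - self.frame["ref"]).to_numpy(dtype=float)


def _as_diff(preds) -> np.ndarray:
    if isinstance(preds, PredictionSet):
        return preds.diff
    return np.asarray(preds, dtype=float)


def mean_error(preds) -> float:
    """ME: arithmetic mean of the differences."""
    d = _as_diff(preds)
    if d.size < 1:
        raise DataError("ME undefined on empty input")
    return float(d.mean())


def sd_of_differences(preds) -> float:
    """SD of the differences with the n-1 denominator."""
    d = _as_diff(preds)
    if d.size < 2:
        raise DataError("SD undefined for n < 2")
    return float(d.std(ddof=1))


def mean_absolute_error(preds) -> float:
    """MAE: mean of absolute differences."""
    d = _as_diff(preds)
    if d.size < 1:
        raise DataError("MAE undefined on empty input")
    return float(np.abs(d).mean())


def naive_predictor(train_labels):
    """Constant predictor at the training-set mean label.

    Returns a callable mapping any number of test segments to that constant;
    the constant itself is exposed as ``.constant``.
    """
    labels = np.asarray(train_labels, dtype=float)
    if labels.size == 0:
        raise DataError("naive predictor needs a non-empty training set")
    const = float(labels.mean())

    def predict(n_or_array):
        n = (n_or_array if isinstance(n_or_array, (int, np.integer))
             else len(n_or_array))
        return np.full(n, const)

    predict.constant = const
    return predict


def mase(preds, naive_preds, refs=None) -> float:
    """MASE in percent: 100 * MAE(model) / MAE(naive), same reference set.

    ``preds``/``naive_preds`` may be difference arrays, (pred, ref) handled
    via PredictionSet, or raw prediction arrays with ``refs`` supplied.
    """
    if refs is not None:
        d_model = np.asarray(preds, dtype=float) - np.asarray(refs, float)
        d_naive = np.asarray(naive_preds, dtype=float) - np.asarray(refs, float)
    else:
        d_model = _as_diff(preds)
        d_naive = _as_diff(naive_preds)
    mae_naive = float(np.abs(d_naive).mean())
    if mae_naive == 0:
        raise UndefinedMetricError(
            "MASE undefined: naive MAE is zero (constant labels)")
    return 100.0 * float(np.abs(d_model).mean()) / mae_naive


@dataclass
class EvaluationReport:
    """Per-target ME/SD/MAE/MASE plus optional bootstrap annotations."""

    metrics: pd.DataFrame      # index: target; columns ME, SD, MAE, MASE, ...
    pooled: dict               # target -> pooled PredictionSet
    bootstrap: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.metrics.to_csv(path)

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"metrics": self.metrics.to_dict(orient="index"),
                       "bootstrap": self.bootstrap}, fh, indent=1,
                      default=float)


def pooled_metrics(fold_sets: dict | list) -> EvaluationReport:
    """Concatenate per-fold predictions, then compute the metrics once.

    ``fold_sets`` maps target name -> list of per-fold PredictionSets (or
    is a list for a single target).  Every segment must be predicted
    exactly once across folds; the naive column must be present for MASE
    (each fold's training-mean prediction, pooled the same way).
    """
    if isinstance(fold_sets, list):
        fold_sets = {"SBP": fold_sets}
    rows = {}
    pooled_sets = {}
    for target, sets in fold_sets.items():
        frames = [ps.frame if isinstance(ps, PredictionSet) else ps
                  for ps in sets]
        pooled = pd.concat(frames, ignore_index=True)
        if "segment_key" in pooled.columns:
            dup = pooled["segment_key"].duplicated()
            if dup.any():
                raise CoverageError(
                    f"{target}: segments predicted more than once: "
                    f"{pooled.loc[dup, 'segment_key'].tolist()[:5]}")
        ps = PredictionSet(pooled, target=target)
        row = {"n": len(pooled), "ME": mean_error(ps),
               "SD": sd_of_differences(ps), "MAE": mean_absolute_error(ps)}
        if "naive" in pooled.columns:
            naive_diff = (pooled["naive"] - pooled["ref"]).to_numpy(float)
            row["MAE_naive"] = float(np.abs(naive_diff).mean())
            row["MASE"] = mase(ps.diff, naive_diff)
        rows[target] = row
        pooled_sets[target] = ps
    return EvaluationReport(metrics=pd.DataFrame(rows).T, pooled=pooled_sets)


def labels_from_predicted_abp(predicted_abp: np.ndarray, fs: float):
    """Extract (SBP, DBP) labels from a predicted ABP waveform.

    Reuses the same cycle detector and label extractor as the reference
    pipeline; returns ``None`` when no cycles are detectable (the caller
    counts such segments as missing predictions).
    """
    from . import preprocess
    try:
        cycles = preprocess.detect_cycles(
            np.asarray(predicted_abp, dtype=float), fs, hr_bounds=(1.0, 1e9))
    except (preprocess.CycleDetectionError, DataError):
        return None
    return preprocess.extract_bp_labels(
        np.asarray(predicted_abp, dtype=float), cycles)


def bootstrap_compare(preds_a: PredictionSet, preds_b: PredictionSet,
                      n_boot: int = 2000,
                      alphas=(0.05, 0.01, 0.001),
                      n_comparisons: int = 1, seed: int = 0) -> dict:
    """Paired bootstrap of the MASE difference with Bonferroni correction.

    Resamples segment indices with replacement (paired across models),
    recomputes MASE_A - MASE_B per replicate, and reports the percentile
    interval at level 1 - alpha/n_comparisons for each alpha.  The
    significance mark is the smallest alpha whose corrected interval
    excludes 0 ('***' for 0.001, '**' for 0.01, '*' for 0.05, 'ns'
    otherwise).  Individual-model MASE intervals are included.
    """
    fa, fb = preds_a.frame, preds_b.frame
    if len(fa) != len(fb):
        raise PairingError("prediction sets differ in length")
    if "segment_key" in fa.columns and "segment_key" in fb.columns:
        if not (fa["segment_key"].to_numpy()
                == fb["segment_key"].to_numpy()).all():
            raise PairingError("prediction sets cover different segments")
    for name, f in (("A", fa), ("B", fb)):
        if "naive" not in f.columns:
            raise DataError(f"model {name} lacks naive predictions for MASE")

    rng = np.random.default_rng(seed)
    n = len(fa)
    da = np.abs((fa["pred"] - fa["ref"]).to_numpy(float))
    db = np.abs((fb["pred"] - fb["ref"]).to_numpy(float))
    na = np.abs((fa["naive"] - fa["ref"]).to_numpy(float))
    nb = np.abs((fb["naive"] - fb["ref"]).to_numpy(float))

    idx = rng.integers(0, n, size=(n_boot, n))
    mase_a = 100.0 * da[idx].mean(axis=1) / na[idx].mean(axis=1)
    mase_b = 100.0 * db[idx].mean(axis=1) / nb[idx].mean(axis=1)
    delta = mase_a - mase_b

    out = {"mase_a": 100.0 * da.mean() / na.mean(),
           "mase_b": 100.0 * db.mean() / nb.mean(),
           "intervals": {}, "mark": "ns",
           "ci_a": {}, "ci_b": {}}
    for alpha in sorted(alphas, reverse=True):   # 0.05 first, 0.001 last
        corrected = alpha / max(n_comparisons, 1)
        lo, hi = np.percentile(delta, [100 * corrected / 2,
                                       100 * (1 - corrected / 2)])
        out["intervals"][alpha] = (float(lo), float(hi))
        out["ci_a"][alpha] = tuple(
            float(v) for v in np.percentile(
                mase_a, [100 * corrected / 2, 100 * (1 - corrected / 2)]))
        out["ci_b"][alpha] = tuple(
            float(v) for v in np.percentile(
                mase_b, [100 * corrected / 2, 100 * (1 - corrected / 2)]))
        if lo > 0 or hi < 0:
            out["mark"] = {0.05: "*", 0.01: "**", 0.001: "***"}.get(
                alpha, f"p<{alpha}")
    return out
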