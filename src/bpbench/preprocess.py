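"""Signal cleaning pipeline: alignment, segmentation, ABP plausibility
filters, cycle identification, distortion elimination, baseline-wander
removal and skewness-based quality refinement, with a per-step audit.

The pipeline mirrors standard practice for paired PPG/ABP preparation:

0. align PPG to ABP by maximum cross-correlation (shift capped at 1 s) and
   cut non-overlapping fixed-length segments;
1. drop segments whose ABP is implausible — samples outside 30–220 mmHg,
   median pulse pressure not above 10 mmHg, heart rate outside 35–140 BPM,
   or no identifiable cardiac cycles — and extract SBP/DBP labels from the
   survivors (median of systolic peaks; median of pooled onsets/offsets);
2. drop segments whose PPG has no valley–peak–valley cycles or an implied
   heart rate outside 35–140 BPM;
3. drop segments with distorted PPG (high standard deviation of
   peak-to-peak / valley-to-valley intervals or of their amplitudes);
4. remove baseline wander by subtracting a natural cubic spline through the
   PPG valleys, then re-check cycles and distortion;
5. drop segments for which handcrafted feature extraction fails;
6. drop segments whose PPG skewness is below zero.

Every removal is recorded with its step and criterion so the audit table's
kept/deleted arithmetic is exactly conserved.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import correlate, correlation_lags, find_peaks, resample_poly
from scipy.stats import skew as _skew

from .errors import (AlignmentError, BPBenchError, ConfigurationError,
                     DataError, FeatureFailure, LabelingError)

__all__ = [
    "Segment", "CycleSet", "AuditTable", "PipelineConfig",
    "CycleDetectionError",
    "align_signals", "segment_record", "detect_cycles",
    "filter_abp_extreme", "extract_bp_labels", "distortion_statistics",
    "filter_distortion", "remove_baseline_wander", "sqi_skewness",
    "run_pipeline", "run_pipeline_on_segments", "decimate_record",
]


class CycleDetectionError(BPBenchError):
    """No usable cardiac cycles; ``reason`` is one of
    {no_extrema, p2p_bpm, v2v_bpm}."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(f"cycle detection failed: {reason}")


@dataclass
class CycleSet:
    """Per-cycle (onset, peak, offset) sample indices for one segment."""

    onsets: np.ndarray
    peaks: np.ndarray
    offsets: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def valleys(self) -> np.ndarray:
        """Distinct valley indices (onsets plus the final offset)."""
        return np.append(self.onsets, self.offsets[-1])

    @property
    def heart_rate(self) -> float:
        """60 * fs / median peak-to-peak interval, BPM."""
        if len(self.peaks) < 2:
            return 60.0 * self.fs / float(
                np.median(np.diff(self.valleys)))
        return 60.0 * self.fs / float(np.median(np.diff(self.peaks)))


@dataclass
class Segment:
    subject_id: str
    record_id: str
    segment_index: int
    fs: float
    ppg: np.ndarray
    abp: np.ndarray | None = None
    sbp_label: float | None = None
    dbp_label: float | None = None
    status: str = "kept"
    removal_step: int | None = None
    removal_reason: str | None = None
    meta: dict = field(default_factory=dict)

    def mark_removed(self, step: int, reason: str) -> None:
        self.status = "removed"
        self.removal_step = step
        self.removal_reason = reason

    def copy(self) -> "Segment":
        return Segment(
            subject_id=self.subject_id, record_id=self.record_id,
            segment_index=self.segment_index, fs=self.fs,
            ppg=self.ppg.copy(),
            abp=None if self.abp is None else self.abp.copy(),
            sbp_label=self.sbp_label, dbp_label=self.dbp_label,
            status=self.status, removal_step=self.removal_step,
            removal_reason=self.removal_reason,
            meta=copy.deepcopy(self.meta))


class AuditTable:
    """Per-step removal bookkeeping with exact conservation."""

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, step: int, criterion: str, deleted: int,
            kept_segments: int, kept_subjects: int, kept_records: int):
        self.rows.append(dict(step=step, criterion=criterion,
                              deleted=deleted, kept_segments=kept_segments,
                              kept_subjects=kept_subjects,
                              kept_records=kept_records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable bounds and thresholds of the cleaning pipeline.

    ``distortion_thresholds`` is a mapping of the four distortion statistics
    to absolute thresholds (seconds for intervals; PPG amplitude units for
    amplitudes; defaults assume unit-amplitude PPG).  Set it to ``None`` to
    derive thresholds as the ``distortion_percentile``-th cumulative
    percentile of each statistic over the candidate population, floored by
    small discretization allowances (see docs/methods.md).
    """

    segment_length: float = 5.0
    max_shift: float = 1.0
    abp_bounds: tuple = (30.0, 220.0)
    pp_min: float = 10.0
    hr_bounds: tuple = (35.0, 140.0)
    prominence_frac: float = 0.6
    distortion_thresholds: dict | None = field(default_factory=lambda: {
        "sd_p2p": 0.15, "sd_v2v": 0.15,
        "sd_peak_amp": 0.12, "sd_valley_amp": 0.12})
    distortion_percentile: float = 97.5
    fail_on_undefined_distortion: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "abp_bounds" in raw:
            raw["abp_bounds"] = tuple(raw["abp_bounds"])
        if "hr_bounds" in raw:
            raw["hr_bounds"] = tuple(raw["hr_bounds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        data = asdict(self)
        data["abp_bounds"] = list(self.abp_bounds)
        data["hr_bounds"] = list(self.hr_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# alignment and segmentation
# ---------------------------------------------------------------------------

def align_signals(ppg: np.ndarray, abp: np.ndarray, fs: float,
                  max_shift: float = 1.0):
    """Align PPG to ABP by the maximum cross-correlation magnitude.

    The shift is the lag (in samples, capped at ``max_shift`` seconds) that
    maximizes |cross-correlation| of the mean-removed signals.  A positive
    shift means the PPG lags the ABP and is advanced; both signals are
    truncated to their overlap.  Returns ``(shift, ppg_aligned, abp_aligned)``.
    """
    ppg = np.asarray(ppg, dtype=float)
    abp = np.asarray(abp, dtype=float)
    max_lag = int(round(max_shift * fs))
    if len(ppg) <= 2 * max_lag or len(abp) <= 2 * max_lag:
        raise DataError("signals shorter than twice the alignment window")
    p0 = ppg - ppg.mean()
    a0 = abp - abp.mean()
    if np.allclose(p0, 0) or np.allclose(a0, 0):
        raise AlignmentError("alignment undefined for constant input")
    corr = correlate(p0, a0, mode="full")
    lags = correlation_lags(len(p0), len(a0), mode="full")
    window = (lags >= -max_lag) & (lags <= max_lag)
    shift = int(lags[window][np.argmax(np.abs(corr[window]))])
    if shift >= 0:
        ppg_al, abp_al = ppg[shift:], abp[:len(abp) - shift]
    else:
        ppg_al, abp_al = ppg[:len(ppg) + shift], abp[-shift:]
    n = min(len(ppg_al), len(abp_al))
    return shift, ppg_al[:n], abp_al[:n]


def segment_record(record, segment_length: float = 5.0) -> list[Segment]:
    """Cut a record into consecutive, non-overlapping fixed-length segments.

    The trailing remainder shorter than one segment is discarded; a record
    shorter than one segment yields an empty list.
    """
    n_seg_samples = int(round(record.fs * segment_length))
    n = len(record.ppg) // n_seg_samples
    out = []
    for k in range(n):
        sl = slice(k * n_seg_samples, (k + 1) * n_seg_samples)
        out.append(Segment(
            subject_id=record.subject_id, record_id=record.record_id,
            segment_index=k, fs=record.fs, ppg=record.ppg[sl].copy(),
            abp=None if record.abp is None else record.abp[sl].copy(),
            meta=copy.deepcopy(record.meta)))
    return out


# ---------------------------------------------------------------------------
# cycle detection and ABP filters
# ---------------------------------------------------------------------------

def detect_cycles(signal: np.ndarray, fs: float,
                  hr_bounds: tuple = (35.0, 140.0),
                  prominence_frac: float = 0.6) -> CycleSet:
    """Identify valley–peak–valley cardiac cycles.

    Peaks/valleys are local extrema with prominence at least
    ``prominence_frac`` of the interquartile amplitude range and spacing at
    least one period at 220 BPM (so supra-threshold tachycardia remains
    measurable; dicrotic bumps are rejected by prominence, not spacing).
    A cycle is a valley pair with exactly one peak in between.  Raises
    :class:`CycleDetectionError` with reason ``no_extrema`` (no cycle
    exists), ``p2p_bpm`` or ``v2v_bpm`` (median-interval heart rate outside
    ``hr_bounds``).
    """
    x = np.asarray(signal, dtype=float)
    if np.isnan(x).any():
        raise DataError("NaN samples in signal")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise CycleDetectionError("no_extrema")
    prom = prominence_frac * iqr
    dist = max(1, int(round(fs * 60.0 / 220.0)))
    peaks, _ = find_peaks(x, prominence=prom, distance=dist)
    valleys, _ = find_peaks(-x, prominence=prom, distance=dist)
    if len(peaks) == 0 or len(valleys) < 2:
        raise CycleDetectionError("no_extrema")

    onsets, cyc_peaks, offsets = [], [], []
    for v0, v1 in zip(valleys[:-1], valleys[1:]):
        inside = peaks[(peaks > v0) & (peaks < v1)]
        if len(inside) == 1:
            onsets.append(v0)
            cyc_peaks.append(inside[0])
            offsets.append(v1)
    if not cyc_peaks:
        raise CycleDetectionError("no_extrema")

    lo, hi = hr_bounds
    if len(peaks) >= 2:
        hr_p2p = 60.0 * fs / float(np.median(np.diff(peaks)))
        if not (lo <= hr_p2p <= hi):
            raise CycleDetectionError("p2p_bpm")
    hr_v2v = 60.0 * fs / float(np.median(np.diff(valleys)))
    if not (lo <= hr_v2v <= hi):
        raise CycleDetectionError("v2v_bpm")

    return CycleSet(onsets=np.asarray(onsets), peaks=np.asarray(cyc_peaks),
                    offsets=np.asarray(offsets), fs=fs)


def filter_abp_extreme(segment: Segment, abp_bounds=(30.0, 220.0),
                       pp_min: float = 10.0,
                       hr_bounds=(35.0, 140.0)) -> list[str]:
    """ABP plausibility check; returns the list of violated criteria
    (empty list = pass).

    Reasons: ``amplitude`` (samples outside ``abp_bounds`` mmHg),
    ``pulse_pressure`` (median per-cycle pulse pressure not above
    ``pp_min``), ``heart_rate`` (cycle rate outside ``hr_bounds``),
    ``no_cycles`` (no identifiable cycles).  All violated reasons are
    reported, since one segment can meet several removal criteria.
    """
    if segment.abp is None:
        raise DataError("filter_abp_extreme requires ABP")
    abp = segment.abp
    reasons = []
    if abp.max() > abp_bounds[1] or abp.min() < abp_bounds[0]:
        reasons.append("amplitude")
    try:
        cycles = detect_cycles(abp, segment.fs, hr_bounds=(1.0, 1e9))
    except (CycleDetectionError, DataError):
        reasons.append("no_cycles")
        return reasons
    pp = [abp[p] - 0.5 * (abp[o] + abp[f])
          for o, p, f in zip(cycles.onsets, cycles.peaks, cycles.offsets)]
    if float(np.median(pp)) <= pp_min:
        reasons.append("pulse_pressure")
    if not (hr_bounds[0] <= cycles.heart_rate <= hr_bounds[1]):
        reasons.append("heart_rate")
    segment.meta["abp_cycles"] = cycles
    return reasons


def extract_bp_labels(abp: np.ndarray, cycles: CycleSet) -> tuple[float, float]:
    """SBP/DBP labels from an ABP segment.

    SBP is the median ABP value at the cycle peaks; DBP the median over the
    pooled multiset of onset and offset values (even counts average the two
    central values, plain median semantics).
    """
    if len(cycles) < 1:
        raise LabelingError("no cycles for label extraction")
    sbp = float(np.median(abp[cycles.peaks]))
    pooled = np.concatenate([abp[cycles.onsets], abp[cycles.offsets]])
    dbp = float(np.median(pooled))
    return sbp, dbp


# ---------------------------------------------------------------------------
# distortion statistics and filtering
# ---------------------------------------------------------------------------

_DISTORTION_KEYS = ("sd_p2p", "sd_v2v", "sd_peak_amp", "sd_valley_amp")


def distortion_statistics(segment: Segment, cycles: CycleSet) -> dict:
    """Sample SDs (n-1 denominator) of peak-to-peak / valley-to-valley
    intervals (seconds) and of peak / valley amplitudes.

    With fewer than two intervals the statistics are undefined and returned
    as NaN (flagged downstream).
    """
    ppg = segment.ppg
    peaks, valleys = cycles.peaks, cycles.valleys

    def sd(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan")

    return {
        "sd_p2p": sd(np.diff(peaks) / segment.fs),
        "sd_v2v": sd(np.diff(valleys) / segment.fs),
        "sd_peak_amp": sd(ppg[peaks]),
        "sd_valley_amp": sd(ppg[valleys]),
    }


def filter_distortion(stats: pd.DataFrame, thresholds: dict | None = None,
                      percentile: float = 97.5,
                      floors: dict | None = None):
    """Pass/fail per segment from the four distortion statistics.

    With explicit ``thresholds`` a segment fails if any statistic strictly
    exceeds its threshold.  Otherwise thresholds are derived as the
    ``percentile``-th percentile of each statistic over the candidate
    population, floored by ``floors`` (discretization allowances), and
    recorded for the audit.  Returns ``(pass_mask, thresholds_used)``.
    """
    if thresholds is None:
        if len(stats) == 0:
            raise ConfigurationError(
                "percentile thresholds need a non-empty population")
        thresholds = {}
        for key in _DISTORTION_KEYS:
            col = stats[key].to_numpy(dtype=float)
            col = col[~np.isnan(col)]
            thr = float(np.percentile(col, percentile)) if len(col) else np.inf
            if floors and key in floors:
                thr = max(thr, floors[key])
            thresholds[key] = thr
    mask = np.ones(len(stats), dtype=bool)
    for key in _DISTORTION_KEYS:
        col = stats[key].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mask &= ~(col > thresholds[key])
    return mask, dict(thresholds)


# ---------------------------------------------------------------------------
# baseline wander and SQI
# ---------------------------------------------------------------------------

def remove_baseline_wander(segment: Segment, cycles: CycleSet) -> Segment:
    """Subtract a natural cubic spline through the PPG valleys.

    The spline interpolates the (valley index, valley value) knots; beyond
    the terminal knots the baseline is extended by the constant knot values.
    Corrected valleys sit at ~0.  With fewer than two valleys the segment is
    returned unchanged with a flag in ``meta``.
    """
    out = segment.copy()
    valleys = cycles.valleys
    if len(valleys) < 2:
        out.meta["bw_skipped"] = True
        return out
    knots_x = valleys.astype(float)
    knots_y = segment.ppg[valleys]
    spline = CubicSpline(knots_x, knots_y, bc_type="natural")
    idx = np.arange(len(segment.ppg), dtype=float)
    baseline = spline(np.clip(idx, knots_x[0], knots_x[-1]))
    out.ppg = segment.ppg - baseline
    out.meta["bw_corrected"] = True
    return out


def sqi_skewness(segment) -> float:
    """Fisher–Pearson sample skewness (m3 / m2^1.5) of the PPG segment.

    Returns NaN for zero-variance input (treated as a degenerate removal by
    the pipeline).  Segments are removed iff skewness is strictly below 0.
    """
    x = np.asarray(getattr(segment, "ppg", segment), dtype=float)
    if x.size < 3 or np.var(x) == 0:
        return float("nan")
    return float(_skew(x))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    kept: list
    audit: AuditTable
    segments: list
    alignment_shifts: dict = field(default_factory=dict)


def _counts(segments):
    kept = [s for s in segments if s.status == "kept"]
    return (len(kept),
            len({s.subject_id for s in kept}),
            len({s.record_id for s in kept}))


def run_pipeline(records, config: PipelineConfig | None = None) -> PipelineResult:
    """Run alignment + segmentation and the full filter cascade.

    Applies the steps in audit order; any stage error marks the segment
    removed with its reason and the pipeline continues.  Re-running the
    pipeline on its own kept segments removes nothing (idempotence).
    """
    config = config or PipelineConfig()
    segments: list[Segment] = []
    shifts: dict[str, int] = {}
    for rec in records:
        rec_use = rec
        if rec.abp is not None:
            try:
                shift, ppg_al, abp_al = align_signals(
                    rec.ppg, rec.abp, rec.fs, max_shift=config.max_shift)
                shifts[rec.record_id] = shift
                rec_use = replace_record_arrays(rec, ppg_al, abp_al)
            except (AlignmentError, DataError):
                shifts[rec.record_id] = 0
        segments.extend(segment_record(rec_use, config.segment_length))
    result = run_pipeline_on_segments(segments, config)
    result.alignment_shifts = shifts
    return result


def replace_record_arrays(record, ppg, abp):
    out = record.copy()
    out.ppg = np.asarray(ppg)
    out.abp = None if abp is None else np.asarray(abp)
    return out


def run_pipeline_on_segments(segments, config: PipelineConfig | None = None
                             ) -> PipelineResult:
    """Filter cascade only (steps 1-6), for pre-cut segments."""
    config = config or PipelineConfig()
    segments = [s.copy() for s in segments]
    audit = AuditTable()
    audit.add(0, "segmented", 0, *_counts(segments))

    # --- step 1: ABP plausibility + labels -------------------------------
    deleted_by = {k: 0 for k in ("amplitude", "pulse_pressure",
                                 "heart_rate", "no_cycles")}
    for seg in segments:
        if seg.abp is None:
            if seg.meta.get("sbp") is not None:
                seg.sbp_label = float(seg.meta["sbp"])
                seg.dbp_label = float(seg.meta["dbp"])
            continue
        reasons = filter_abp_extreme(seg, config.abp_bounds, config.pp_min,
                                     config.hr_bounds)
        if reasons:
            for r in reasons:
                deleted_by[r] += 1
            seg.mark_removed(1, "+".join(reasons))
        else:
            cycles = seg.meta.pop("abp_cycles")
            seg.sbp_label, seg.dbp_label = extract_bp_labels(seg.abp, cycles)
    for crit, n in deleted_by.items():
        audit.add(1, f"abp_{crit}", n, *_counts(segments))

    # --- step 2: PPG cycle identification + BPM limits -------------------
    deleted_by = {k: 0 for k in ("no_extrema", "p2p_bpm", "v2v_bpm")}
    for seg in segments:
        if seg.status != "kept":
            continue
        try:
            cycles = detect_cycles(seg.ppg, seg.fs, config.hr_bounds,
                                   config.prominence_frac)
            seg.meta["cycles"] = cycles
        except CycleDetectionError as err:
            deleted_by[err.reason] += 1
            seg.mark_removed(2, err.reason)
        except DataError:
            deleted_by["no_extrema"] += 1
            seg.mark_removed(2, "nan_samples")
    for crit, n in deleted_by.items():
        audit.add(2, f"ppg_{crit}", n, *_counts(segments))

    # --- step 3: PPG distortion ------------------------------------------
    candidates = [s for s in segments if s.status == "kept"]
    n_del = _distortion_pass(candidates, config, step=3, audit=audit,
                             criterion="ppg_distortion")

    # --- step 4: baseline-wander removal + re-check ----------------------
    deleted_cycles = 0
    for seg in segments:
        if seg.status != "kept":
            continue
        seg_corr = remove_baseline_wander(seg, seg.meta["cycles"])
        seg.ppg = seg_corr.ppg
        seg.meta.update({k: v for k, v in seg_corr.meta.items()
                         if k.startswith("bw_")})
        try:
            seg.meta["cycles"] = detect_cycles(
                seg.ppg, seg.fs, config.hr_bounds, config.prominence_frac)
        except (CycleDetectionError, DataError) as err:
            deleted_cycles += 1
            seg.mark_removed(4, "post_bw_"
                             + getattr(err, "reason", "nan_samples"))
    audit.add(4, "post_bw_cycles", deleted_cycles, *_counts(segments))
    candidates = [s for s in segments if s.status == "kept"]
    _distortion_pass(candidates, config, step=4, audit=audit,
                     criterion="post_bw_distortion")

    # --- step 5: feature-generation failures ------------------------------
    from .features import extract_features  # deferred import (layering)
    n_feat = 0
    for seg in segments:
        if seg.status != "kept":
            continue
        try:
            seg.meta["features"] = extract_features(seg, seg.meta["cycles"])
        except (FeatureFailure, BPBenchError) as err:
            n_feat += 1
            seg.mark_removed(5, "feature_failure:"
                             + getattr(err, "missing", "unknown"))
    audit.add(5, "feature_failure", n_feat, *_counts(segments))

    # --- step 6: skewness SQI ---------------------------------------------
    n_skew = 0
    for seg in segments:
        if seg.status != "kept":
            continue
        sk = sqi_skewness(seg)
        if np.isnan(sk):
            n_skew += 1
            seg.mark_removed(6, "degenerate")
        elif sk < 0:
            n_skew += 1
            seg.mark_removed(6, "sqi_skewness")
        else:
            seg.meta["sqi_skewness"] = sk
    audit.add(6, "sqi_skewness", n_skew, *_counts(segments))

    kept = [s for s in segments if s.status == "kept"]
    return PipelineResult(kept=kept, audit=audit, segments=segments)


def _distortion_pass(candidates, config, step, audit, criterion) -> int:
    if not candidates:
        audit.add(step, criterion, 0, 0, 0, 0)
        return 0
    stats = pd.DataFrame([
        distortion_statistics(s, s.meta["cycles"]) for s in candidates])
    fs = candidates[0].fs
    amp_scale = float(np.median([np.ptp(s.ppg) for s in candidates]))
    floors = {"sd_p2p": 2.0 / fs, "sd_v2v": 2.0 / fs,
              "sd_peak_amp": 0.02 * amp_scale,
              "sd_valley_amp": 0.02 * amp_scale}
    mask, used = filter_distortion(stats, config.distortion_thresholds,
                                   config.distortion_percentile, floors)
    undefined = stats.isna().any(axis=1).to_numpy()
    if config.fail_on_undefined_distortion:
        mask &= ~undefined
    n_del = 0
    for seg, ok in zip(candidates, mask):
        if not ok:
            n_del += 1
            seg.mark_removed(step, criterion)
    audit.add(step, criterion, n_del, *_counts(candidates))
    audit.rows[-1]["thresholds"] = used
    return n_del


def segments_table(segments) -> pd.DataFrame:
    """One row per segment: ids, labels, status and removal bookkeeping."""
    return pd.DataFrame([{
        "subject_id": s.subject_id, "record_id": s.record_id,
        "segment_index": s.segment_index, "sbp": s.sbp_label,
        "dbp": s.dbp_label, "status": s.status,
        "removal_step": s.removal_step, "removal_reason": s.removal_reason,
        "artifact": s.meta.get("artifact"),
    } for s in segments])


def decimate_record(record, factor: int):
    """Plain polyphase decimation of a record by an integer factor."""
    out = record.copy()
    out.ppg = resample_poly(record.ppg, 1, factor)
    if record.abp is not None:
        out.abp = resample_poly(record.abp, 1, factor)
    out.fs = record.fs / factor
    return out
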