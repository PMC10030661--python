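"""Handcrafted PPG feature catalog: landmarks, times, areas, widths,
frequency, histogram, slope-deviation, quality and index features.

The catalog follows the conventional fiducial-point taxonomy of PPG
morphology analysis: the systolic peak ``s`` on the PPG itself, points
``w, y, z`` on the first derivative (VPG) — maximum upslope, maximum
downslope and the diastolic rise — and points ``a, b, c, d, e`` on the
second derivative (APG), where ``e`` marks the dicrotic notch.  All features
are computed per cardiac cycle and aggregated across a segment's cycles by
the median (robust to one residual odd cycle); frequency features are
computed once per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .errors import FeatureFailure

__all__ = [
    "PointsOfInterest",
    "FEATURE_NAMES",
    "derivatives",
    "locate_points",
    "time_amplitude_area_features",
    "width_features",
    "frequency_features",
    "histogram_features",
    "sdc_features",
    "sqi_index_features",
    "extract_features",
    "features_table",
]

_POINTS = ("o", "w", "s", "y", "z", "a", "b", "c", "d", "e", "f")
_TIME_ORDER = ("o", "w", "s", "e", "z", "f")
_ELEVATIONS = (0.25, 0.50, 0.75)


def derivatives(ppg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """First (VPG) and second (APG) time derivatives in per-second units.

    Central differences in the interior, one-sided at the ends (``np.gradient``
    semantics), scaled by ``fs`` and ``fs**2`` respectively.
    """
    ppg = np.asarray(ppg, dtype=float)
    if ppg.size < 5:
        raise FeatureFailure("vpg", "need at least 5 samples")
    vpg = np.gradient(ppg) * fs
    apg = np.gradient(vpg / fs) * fs * fs
    return vpg, apg


def _search_derivatives(ppg: np.ndarray, fs: float,
                        period_s: float | None = None):
    """Savitzky-Golay polynomial derivatives used only to *locate* extrema.

    A cubic window of ~14% of the cardiac period (capped at 50-120 ms)
    suppresses sample-level noise that raw difference derivatives amplify
    quadratically, while preserving landmark geometry at physiological time
    scales.  Reported amplitudes always come from the plain
    central-difference derivatives.
    """
    win_s = 0.11 if period_s is None else float(
        np.clip(0.14 * period_s, 0.05, 0.12))
    win = int(round(win_s * fs))
    if win % 2 == 0:
        win += 1
    win = max(win, 5)
    if len(ppg) <= win:
        vpg, apg = derivatives(ppg, fs)
        return vpg, apg
    v_s = savgol_filter(ppg, win, 3, deriv=1, delta=1.0 / fs)
    a_s = savgol_filter(ppg, win, 3, deriv=2, delta=1.0 / fs)
    return v_s, a_s


def _locate_in_cycle(ppg, v_s, a_s, o: int, s: int, f: int,
                     fs: float) -> dict:
    """Locate all landmark indices within one cycle (onset o, peak s, end f).

    ``v_s``/``a_s`` are the smoothed search derivatives.  Raises
    :class:`FeatureFailure` naming the first missing point.
    """
    if not (o < s < f):
        raise FeatureFailure("s", "cycle boundaries not ordered")

    pts = {"o": o, "s": s, "f": f}
    if s - o < 3 or f - s < 3:
        raise FeatureFailure("w", "cycle too short")
    pts["w"] = o + int(np.argmax(v_s[o:s]))
    pts["y"] = s + int(np.argmin(v_s[s:f]))
    zc, _ = find_peaks(v_s[pts["y"]:f])
    if len(zc) == 0:
        raise FeatureFailure("z", "no diastolic rise in VPG")
    pts["z"] = pts["y"] + int(zc[np.argmax(v_s[pts["y"] + zc])])

    pts["a"] = o + int(np.argmax(a_s[o:s]))
    pts["b"] = pts["a"] + int(np.argmin(a_s[pts["a"]:f]))
    pc, _ = find_peaks(a_s[pts["b"]:f])
    if len(pc) == 0:
        raise FeatureFailure("c", "no APG maximum after b")
    pts["c"] = pts["b"] + int(pc[0])
    td, _ = find_peaks(-a_s[pts["c"]:f])
    if len(td) == 0:
        raise FeatureFailure("d", "no APG minimum after c")
    pts["d"] = pts["c"] + int(td[0])

    # e precedes the dicrotic wave: find the most negative APG local minimum
    # in late diastole (the dicrotic wave) and take the last APG local
    # maximum of positive curvature before it (the notch itself; sign
    # filtering rejects micro-wiggles on the dicrotic dip).
    margin = max(2, int(round(0.08 * (f - o))))
    stop = f - margin
    if stop <= pts["d"] + 2:
        raise FeatureFailure("e", "no room for dicrotic complex")
    tm, _ = find_peaks(-a_s[pts["d"]:stop])
    if len(tm) == 0:
        raise FeatureFailure("e", "no dicrotic APG minimum")
    dic = pts["d"] + int(tm[np.argmin(a_s[pts["d"] + tm])])
    pe, _ = find_peaks(a_s[pts["d"]:dic + 1])
    pe = pe[a_s[pts["d"] + pe] > 0]
    if len(pe) == 0:
        raise FeatureFailure("e", "no APG maximum before dicrotic wave")
    pts["e"] = pts["d"] + int(pe[-1])
    if not (s < pts["e"] < f):
        raise FeatureFailure("e", "notch landmark outside diastole")
    return pts


@dataclass
class PointsOfInterest:
    """Per-cycle landmark indices plus the signal arrays they refer to."""

    cycles: list  # list of dicts point-name -> sample index
    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    fs: float

    def amplitude(self, signal: str, point: str, cycle: int) -> float:
        arr = getattr(self, signal)
        return float(arr[self.cycles[cycle][point]])


def locate_points(segment, cycles, vpg: np.ndarray,
                  apg: np.ndarray) -> PointsOfInterest:
    """Locate VPG/APG points of interest for every cycle of a segment.

    ``segment`` may be a `preprocess.Segment` or a plain array; ``cycles``
    is a `preprocess.CycleSet`.  A missing landmark in any cycle raises
    :class:`FeatureFailure` carrying the missing point's name — the pipeline
    routes such segments to the feature-generation removal step.
    """
    ppg = np.asarray(getattr(segment, "ppg", segment), dtype=float)
    fs = getattr(segment, "fs", None) or getattr(cycles, "fs")
    period = (float(np.median(np.diff(cycles.peaks))) / fs
              if len(cycles.peaks) >= 2 else None)
    v_s, a_s = _search_derivatives(ppg, fs, period)
    located = []
    for o, s, f in zip(cycles.onsets, cycles.peaks, cycles.offsets):
        located.append(
            _locate_in_cycle(ppg, v_s, a_s, int(o), int(s), int(f), fs))
    return PointsOfInterest(cycles=located, ppg=ppg, vpg=vpg, apg=apg, fs=fs)


# ---------------------------------------------------------------------------
# per-cycle feature groups
# ---------------------------------------------------------------------------

def time_amplitude_area_features(poi: PointsOfInterest, ppg: np.ndarray,
                                 fs: float) -> list[dict]:
    """Elapsed times, landmark amplitudes and phase areas, per cycle.

    Times cover all ordered pairs among (o, w, s, e, z, f).  Areas integrate
    the cycle-min-referenced PPG by the trapezoid rule over the phases
    [o,w], [w,s], [s,e], [e,f]; systole is A1+A2 and diastole A3+A4, so the
    systolic and diastolic areas sum exactly to the area over [o,f].
    """
    rows = []
    for pts in poi.cycles:
        row = {}
        for i, p in enumerate(_TIME_ORDER):
            for q in _TIME_ORDER[i + 1:]:
                row[f"T_{p}_{q}"] = (pts[q] - pts[p]) / fs
        for p in _POINTS:
            row[f"ppg_{p}"] = float(ppg[pts[p]])
            row[f"vpg_{p}"] = float(poi.vpg[pts[p]])
            row[f"apg_{p}"] = float(poi.apg[pts[p]])
        o, w, s, e, f_ = pts["o"], pts["w"], pts["s"], pts["e"], pts["f"]
        base = float(np.min(ppg[o:f_ + 1]))
        y = ppg - base

        def area(i0, i1):
            return float(np.trapezoid(y[i0:i1 + 1], dx=1.0 / fs))

        row["A1"], row["A2"] = area(o, w), area(w, s)
        row["A3"], row["A4"] = area(s, e), area(e, f_)
        row["A_sys"] = row["A1"] + row["A2"]
        row["A_dia"] = row["A3"] + row["A4"]
        rows.append(row)
    return rows


def width_features(ppg: np.ndarray, pts: dict, fs: float,
                   elevations=_ELEVATIONS) -> dict:
    """Systolic/diastolic widths at fractional elevations of the peak.

    At elevation ``p`` the level is ``onset + p * (peak - onset)``;
    SW is the time from the rising crossing to the peak and DW from the peak
    to the falling crossing, with crossings linearly interpolated between
    samples.  Sum and ratio at each elevation are included.
    """
    o, s, f = pts["o"], pts["s"], pts["f"]
    amp = ppg[s] - ppg[o]
    if amp <= 0:
        raise FeatureFailure("width", "non-positive peak amplitude")
    row = {}
    for p in elevations:
        level = ppg[o] + p * amp
        rise = ppg[o:s + 1]
        below = np.flatnonzero(rise < level)
        if len(below) == 0 or below[-1] == s - o:
            raise FeatureFailure("width", f"no rising crossing at {p}")
        i = below[-1]
        frac = (level - rise[i]) / (rise[i + 1] - rise[i])
        t_rise = (o + i + frac) / fs
        fall = ppg[s:f + 1]
        under = np.flatnonzero(fall < level)
        if len(under) == 0:
            raise FeatureFailure("width", f"no falling crossing at {p}")
        j = under[0]
        frac = (fall[j - 1] - level) / (fall[j - 1] - fall[j])
        t_fall = (s + j - 1 + frac) / fs
        tag = f"{int(p * 100)}"
        sw = s / fs - t_rise
        dw = t_fall - s / fs
        row[f"SW_{tag}"] = sw
        row[f"DW_{tag}"] = dw
        row[f"SW_DW_{tag}"] = sw + dw
        row[f"DW_over_SW_{tag}"] = dw / sw if sw > 0 else np.nan
    return row


def frequency_features(ppg: np.ndarray, fs: float,
                       band=(0.5, 8.0), near_hz: float = 0.5) -> dict:
    """Dominant-frequency features of the mean-removed segment spectrum.

    ``f_dom`` is the frequency of maximum magnitude within ``band`` (Hz),
    ``mag_dom`` that magnitude and ``mag_near`` the mean magnitude within
    ±``near_hz`` of it, excluding the peak bin itself.
    """
    x = np.asarray(ppg, dtype=float)
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise FeatureFailure("f_dom", "no spectral bins in band")
    k = np.flatnonzero(in_band)[int(np.argmax(mag[in_band]))]
    near = (np.abs(freqs - freqs[k]) <= near_hz)
    near[k] = False
    return {"f_dom": float(freqs[k]), "mag_dom": float(mag[k]),
            "mag_near": float(mag[near].mean()) if near.any() else 0.0}


def histogram_features(samples: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width histogram densities over [min, max], summing to 1.

    A constant phase degenerates to density 1 in the first bin.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise FeatureFailure("histogram", "empty phase")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        dens = np.zeros(n_bins)
        dens[0] = 1.0
        return dens
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts / counts.sum()


def _phase_histograms(poi: PointsOfInterest, pts: dict) -> dict:
    row = {}
    o, s, f = pts["o"], pts["s"], pts["f"]
    for name, arr in (("ppg", poi.ppg), ("vpg", poi.vpg), ("apg", poi.apg)):
        sysd = histogram_features(arr[o:s + 1], 5)
        diad = histogram_features(arr[s:f + 1], 10)
        for i, v in enumerate(sysd, start=1):
            row[f"{name}_sys_hist_{i}"] = float(v)
        for i, v in enumerate(diad, start=1):
            row[f"{name}_dia_hist_{i}"] = float(v)
    return row


def sdc_features(ppg: np.ndarray, pts: dict) -> dict:
    """Slope-deviation-curve features.

    Each phase (systolic upstroke o→s, diastolic fall s→f) is compared to
    its mean slope curve — the straight chord between the phase endpoints;
    the feature is the mean absolute deviation from the chord, normalized by
    the pulse amplitude (peak − onset), hence amplitude-scale invariant.
    """
    o, s, f = pts["o"], pts["s"], pts["f"]
    amp = ppg[s] - ppg[o]
    if amp == 0:
        raise FeatureFailure("SDC", "zero pulse amplitude")

    def sdc(i0, i1):
        seg = ppg[i0:i1 + 1]
        chord = np.linspace(seg[0], seg[-1], len(seg))
        return float(np.mean(np.abs(seg - chord)) / abs(amp))

    return {"SDC_sys": sdc(o, s), "SDC_dia": sdc(s, f)}


def sqi_index_features(ppg: np.ndarray, pts: dict, poi: PointsOfInterest,
                       fs: float) -> dict:
    """Cycle quality (skewness, excess kurtosis) and APG index features.

    AI (aging index) = (b - c - d - e) / a on APG amplitudes, with
    I_bd = b/d and I_bcda = (b - c - d)/a following the conventional APG
    literature.  I_sdoo is the diastolic-to-systolic duration ratio
    (t_f - t_s)/(t_s - t_o); see :func:`i_sdoo`.
    """
    o, s, f = pts["o"], pts["s"], pts["f"]
    cyc = ppg[o:f + 1]
    a, b, c, d, e = (float(poi.apg[pts[k]]) for k in "abcde")
    if a == 0:
        raise FeatureFailure("AI", "apg_a is zero")
    return {
        "skewness": float(_skew(cyc)),
        "kurtosis": float(_kurtosis(cyc)),  # Fisher (excess)
        "AI": (b - c - d - e) / a,
        "I_bd": b / d if d != 0 else np.nan,
        "I_bcda": (b - c - d) / a,
        "I_sdoo": i_sdoo(pts, fs),
    }


def i_sdoo(pts: dict, fs: float) -> float:
    """Diastolic-to-systolic duration ratio (t_f - t_s) / (t_s - t_o).

    The source literature for this index does not fix a formula; this
    package adopts the duration-ratio convention (the systolic peak against
    the two cycle onsets).  Isolated here so the convention can be swapped.
    """
    return (pts["f"] - pts["s"]) / (pts["s"] - pts["o"])


# ---------------------------------------------------------------------------
# schema and segment-level extraction
# ---------------------------------------------------------------------------

def _build_feature_names() -> list[str]:
    names = []
    for i, p in enumerate(_TIME_ORDER):
        for q in _TIME_ORDER[i + 1:]:
            names.append(f"T_{p}_{q}")
    for p in _POINTS:
        names += [f"ppg_{p}", f"vpg_{p}", f"apg_{p}"]
    names += ["A1", "A2", "A3", "A4", "A_sys", "A_dia"]
    for p in _ELEVATIONS:
        tag = f"{int(p * 100)}"
        names += [f"SW_{tag}", f"DW_{tag}", f"SW_DW_{tag}",
                  f"DW_over_SW_{tag}"]
    names += ["f_dom", "mag_dom", "mag_near"]
    for sig in ("ppg", "vpg", "apg"):
        names += [f"{sig}_sys_hist_{i}" for i in range(1, 6)]
        names += [f"{sig}_dia_hist_{i}" for i in range(1, 11)]
    names += ["SDC_sys", "SDC_dia", "skewness", "kurtosis",
              "AI", "I_bd", "I_bcda", "I_sdoo"]
    return names


FEATURE_NAMES: tuple = tuple(_build_feature_names())


def extract_features(segment, cycles=None) -> pd.Series:
    """Full feature vector for one cleaned segment (fixed schema).

    Per-cycle features are aggregated across the segment's cycles by the
    median; frequency features are computed once on the whole segment.  Any
    sub-extractor failure raises :class:`FeatureFailure`, which the pipeline
    translates into a feature-generation removal.
    """
    from . import preprocess  # deferred to avoid an import cycle

    ppg = np.asarray(segment.ppg, dtype=float)
    fs = segment.fs
    if cycles is None:
        cycles = preprocess.detect_cycles(ppg, fs)
    vpg, apg = derivatives(ppg, fs)
    poi = locate_points(ppg if not hasattr(segment, "ppg") else segment,
                        cycles, vpg, apg)

    per_cycle = time_amplitude_area_features(poi, ppg, fs)
    for row, pts in zip(per_cycle, poi.cycles):
        row.update(width_features(ppg, pts, fs))
        row.update(_phase_histograms(poi, pts))
        row.update(sdc_features(ppg, pts))
        row.update(sqi_index_features(ppg, pts, poi, fs))
    agg = pd.DataFrame(per_cycle).median(axis=0)
    agg = pd.concat([agg, pd.Series(frequency_features(ppg, fs))])
    return agg.reindex(FEATURE_NAMES)


def features_table(segments) -> pd.DataFrame:
    """Feature rows for kept segments: ids + labels + the feature schema.

    Segments whose extraction fails are skipped (the pipeline removes them
    before this point in normal operation).
    """
    rows = []
    for seg in segments:
        try:
            feats = extract_features(seg)
        except FeatureFailure:
            continue
        meta = {"subject_id": seg.subject_id, "record_id": seg.record_id,
                "segment_index": seg.segment_index,
                "sbp": seg.sbp_label, "dbp": seg.dbp_label}
        rows.append({**meta, **feats.to_dict()})
    return pd.DataFrame(rows)
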