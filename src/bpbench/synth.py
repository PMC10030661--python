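"""Synthetic paired PPG/ABP cohorts for exercising the benchmark end to end.

Real cuffless-BP studies train on paired photoplethysmogram (PPG) and
arterial blood pressure (ABP) waveforms.  This module generates such pairs
with controllable morphology so that every downstream stage — quality
filtering, label extraction, landmark-based feature extraction, splitting and
evaluation — can be tested without multi-GB waveform downloads.

The waveform family is a smooth periodic pulse built per cardiac cycle from
Gaussian lobes:

* an asymmetric systolic lobe (fast rise, slower fall),
* a small "ripple" on the downslope (part of the dicrotic complex; it gives
  the second derivative its conventional c and d wiggle),
* a dicrotic lobe whose position is calibrated so that the second-derivative
  notch landmark *e* falls exactly ``notch_delay`` seconds after the systolic
  peak.

The shape is analytic, hence smooth between samples, and exhibits the
standard first-derivative (w, y, z) and second-derivative (a, b, c, d, e)
points of interest.  ABP is the shape rescaled to ``[dbp, sbp]`` mmHg; PPG is
the same shape, unit-amplitude in ``[0, 1]`` before noise, delayed by
``ppg_delay`` (pulse-arrival lag), with optional additive baseline wander and
white noise.  No claim of hemodynamic realism is made; the family is designed
to carry the landmarks and statistical structure the pipeline consumes.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace, asdict
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import SpecificationError

__all__ = [
    "PulseSpec",
    "BPDistribution",
    "CohortSpec",
    "SignalRecord",
    "Cohort",
    "ARTIFACT_KINDS",
    "PRESETS",
    "generate_pulse_train",
    "generate_cohort",
    "inject_artifact",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_hdf5",
    "read_cohort_hdf5",
]

# Morphology regime within which the dicrotic calibration is exact; outside
# it the generator clamps (see docs/methods.md).
_ND_FRAC_MIN, _ND_FRAC_MAX = 0.18, 0.33
_DEPTH_MAX = 0.60


@dataclass(frozen=True)
class PulseSpec:
    """Parameters of one pulse train.

    Parameters
    ----------
    heart_rate : float
        Beats per minute; must be positive.
    sbp, dbp : float
        Systolic / diastolic pressure targets in mmHg; ``sbp > dbp``.
    notch_delay : float
        Seconds from the systolic peak to the dicrotic-notch landmark (the
        second-derivative *e* point).  Clamped to 0.18–0.33 of the cardiac
        period during synthesis.
    notch_depth : float
        Dicrotic-lobe amplitude as a fraction of pulse amplitude, in [0, 1).
        Zero removes the dicrotic complex entirely.
    ppg_delay : float
        Seconds the PPG lags the ABP (pulse arrival time difference).
    noise_sd : float
        Standard deviation of additive white noise on the PPG (PPG units).
    bw_amplitude, bw_frequency : float
        Amplitude (PPG units) and frequency (Hz) of sinusoidal baseline
        wander added to the PPG.
    """

    heart_rate: float = 60.0
    sbp: float = 120.0
    dbp: float = 80.0
    notch_delay: float = 0.28
    notch_depth: float = 0.35
    ppg_delay: float = 0.20
    noise_sd: float = 0.0
    bw_amplitude: float = 0.0
    bw_frequency: float = 0.25

    def __post_init__(self) -> None:
        if not self.heart_rate > 0:
            raise SpecificationError("heart_rate > 0 violated "
                                     f"(got {self.heart_rate})")
        if not self.sbp > self.dbp:
            raise SpecificationError("sbp > dbp violated "
                                     f"(got sbp={self.sbp}, dbp={self.dbp})")
        if not (0 <= self.notch_depth < 1):
            raise SpecificationError("0 <= notch_depth < 1 violated "
                                     f"(got {self.notch_depth})")
        if not self.notch_delay > 0:
            raise SpecificationError("notch_delay > 0 violated "
                                     f"(got {self.notch_delay})")

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class BPDistribution:
    """Shifted log-normal family parameterized by (mean, sd, skew).

    ``skew == 0`` degenerates to a normal distribution; a negative skew
    mirrors the log-normal.  Three interpretable parameters suffice to mimic
    the right-skewed SBP/DBP distributions seen in clinical cohorts.
    """

    mean: float
    sd: float
    skew: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd <= 0:
            return np.full(n, self.mean)
        if self.skew == 0.0:
            return rng.normal(self.mean, self.sd, size=n)
        gamma = abs(self.skew)
        # solve (w + 2) * sqrt(w - 1) = gamma with w = exp(sigma^2)
        roots = np.roots([1.0, 3.0, 0.0, -(4.0 + gamma ** 2)])
        w = float(max(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 1))
        sigma = math.sqrt(math.log(w))
        emu = self.sd / math.sqrt(w * (w - 1.0))
        y = emu * np.exp(sigma * rng.standard_normal(n))
        centered = y - emu * math.sqrt(w)
        return self.mean + math.copysign(1.0, self.skew) * centered


ARTIFACT_KINDS = ("flatline", "amplitude_spike", "extreme_bp", "low_pp",
                  "tachy", "brady", "bw_drift")

# bw_drift is corrected (not removed) by the pipeline, so it is excluded from
# the default injected set used for filter-recall experiments.
_REMOVABLE_KINDS = ("flatline", "amplitude_spike", "extreme_bp", "low_pp",
                    "tachy", "brady")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic multi-subject cohort.

    One :class:`SignalRecord` is generated per (subject, segment): each
    record is one segment-length pulse train carrying that segment's latent
    labels.  Subjects draw a latent (SBP, DBP) level from the configured
    distributions; segments within a subject jitter around it by
    ``within_subject_sd``, which makes samples of one subject correlated —
    the property the leakage experiments rely on.
    """

    n_subjects: int = 50
    segments_per_subject: int = 5
    sampling_rate: float = 125.0
    segment_length: float = 5.0
    sbp_distribution: BPDistribution = field(
        default_factory=lambda: BPDistribution(134.36, 21.78, 0.5))
    dbp_distribution: BPDistribution = field(
        default_factory=lambda: BPDistribution(65.37, 10.51, 0.5))
    within_subject_sd: float = 4.0
    artifact_fraction: float = 0.0
    artifact_kinds: tuple = _REMOVABLE_KINDS
    seed: int = 0
    heart_rate_mean: float = 74.0
    heart_rate_sd: float = 7.0
    noise_sd: float = 0.003
    bw_amplitude: float = 0.04
    bw_frequency: float = 0.25
    ppg_delay_mean: float = 0.20
    ppg_delay_sd: float = 0.04
    # records are generated this much longer than one segment so that
    # cross-correlation alignment can consume samples without losing the
    # segment entirely
    alignment_pad: float = 1.0
    # Optional: make subject SBP an affine function of heart rate
    # (slope mmHg/BPM, intercept mmHg, noise sd mmHg) — used by the
    # learnability and leakage experiments.
    sbp_affine_hr: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecificationError("n_subjects >= 1 violated")
        if self.segments_per_subject < 1:
            raise SpecificationError("segments_per_subject >= 1 violated")
        if not (0.0 <= self.artifact_fraction <= 1.0):
            raise SpecificationError("artifact_fraction in [0, 1] violated "
                                     f"(got {self.artifact_fraction})")
        for k in self.artifact_kinds:
            if k not in ARTIFACT_KINDS:
                raise SpecificationError(f"unknown artifact kind {k!r}")


@dataclass
class SignalRecord:
    """One subject/record's raw paired PPG (+optional ABP) time series."""

    subject_id: str
    record_id: str
    fs: float
    ppg: np.ndarray
    abp: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.ppg) / self.fs

    def copy(self) -> "SignalRecord":
        return SignalRecord(
            subject_id=self.subject_id,
            record_id=self.record_id,
            fs=self.fs,
            ppg=self.ppg.copy(),
            abp=None if self.abp is None else self.abp.copy(),
            meta=copy.deepcopy(self.meta),
        )


class Cohort(Sequence):
    """A list of :class:`SignalRecord` plus cohort-level metadata."""

    def __init__(self, records: list, meta: dict | None = None):
        self.records = records
        self.meta = meta or {}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[SignalRecord]:
        return iter(self.records)


# ---------------------------------------------------------------------------
# waveform template
# ---------------------------------------------------------------------------

def _shape_params(T: float, notch_delay: float, notch_depth: float):
    nd = float(np.clip(notch_delay, _ND_FRAC_MIN * T, _ND_FRAC_MAX * T))
    depth = float(min(notch_depth, _DEPTH_MAX))
    mu_s = 0.28 * T
    sl, sr = 0.09 * T, 0.16 * T
    s_r = 0.12 * nd
    a_r = min(2.6 * depth, 0.62) * (s_r / sl) ** 2
    mu_r = mu_s + 0.35 * nd
    s_d = 0.30 * nd
    return nd, depth, mu_s, sl, sr, mu_r, s_r, a_r, s_d


def _cycle_shape(t: np.ndarray, T: float, notch_delay: float,
                 notch_depth: float, d_shift: float) -> np.ndarray:
    """Periodic pulse shape (arbitrary units) at times ``t``."""
    nd, depth, mu_s, sl, sr, mu_r, s_r, a_r, s_d = _shape_params(
        T, notch_delay, notch_depth)
    mu_d = mu_s + nd + d_shift

    def wrapped(mu):
        return (t - mu + T / 2.0) % T - T / 2.0

    d = wrapped(mu_s)
    sig = np.where(d < 0, sl, sr)
    out = np.exp(-0.5 * (d / sig) ** 2)
    if depth > 0:
        out = out + a_r * np.exp(-0.5 * (wrapped(mu_r) / s_r) ** 2)
        out = out + depth * np.exp(-0.5 * (wrapped(mu_d) / s_d) ** 2)
    return out


@lru_cache(maxsize=4096)
def _calibrate(T: float, notch_delay: float, notch_depth: float):
    """Find the dicrotic-lobe shift placing landmark *e* at ``notch_delay``
    after the systolic peak; returns (d_shift, tau_onset, y_min, y_max).

    Calibration runs the same landmark chain the feature extractor uses, on
    a dense noiseless grid, so generator ground truth and analysis agree by
    construction.  If the chain fails (e.g. very shallow notch) an analytic
    fallback placement is used.
    """
    from .features import _locate_in_cycle, _search_derivatives  # deferred

    nd, depth, *_ = _shape_params(T, notch_delay, notch_depth)
    npc = 2048
    dt = T / npc
    tau = np.arange(2 * npc) * dt

    def landmarks(d_shift):
        y = _cycle_shape(tau, T, notch_delay, notch_depth, d_shift)
        o = int(np.argmin(y[:npc]))
        f = o + npc
        s = o + int(np.argmax(y[o:f]))
        v_s, a_s = _search_derivatives(y, 1.0 / dt, period_s=T)
        return _locate_in_cycle(y, v_s, a_s, o, s, f, 1.0 / dt), s

    d_shift = 0.57 * nd
    if depth > 0:
        for _ in range(15):
            try:
                pts, s = landmarks(d_shift)
            except Exception:
                d_shift = 0.57 * nd
                break
            err = nd - (pts["e"] - s) * dt
            if abs(err) < 2e-4:
                break
            d_shift = float(np.clip(d_shift + 0.8 * err, 0.2 * nd, 1.0 * nd))
    y = _cycle_shape(tau, T, notch_delay, notch_depth, d_shift)
    o = int(np.argmin(y[:npc]))
    tau_onset = tau[o]
    seg = y[o:o + npc]
    return d_shift, tau_onset, float(seg.min()), float(seg.max())


def _pulse_shape_unit(t: np.ndarray, spec: PulseSpec) -> np.ndarray:
    """Unit-amplitude pulse shape in [0, 1].

    The record starts just after a systolic peak so that the first full
    onset valley is an interior extremum detectors can find.
    """
    T = spec.period
    d_shift, tau_onset, ymin, ymax = _calibrate(
        round(T, 6), round(spec.notch_delay, 6), round(spec.notch_depth, 4))
    start = 0.28 * T + 0.02 * T  # systolic-lobe center + small margin
    y = _cycle_shape(t + start, T, spec.notch_delay, spec.notch_depth,
                     d_shift)
    return (y - ymin) / (ymax - ymin)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_pulse_train(spec: PulseSpec, duration: float, fs: float,
                         seed: int = 0, subject_id: str = "S0",
                         record_id: str = "S0-000") -> SignalRecord:
    """Generate one paired ABP/PPG record of ``duration`` seconds at ``fs`` Hz.

    The noiseless ABP has valleys at ``spec.dbp`` and peaks at ``spec.sbp``
    (up to sample-grid discretization); the PPG shares the cycle structure,
    is unit-amplitude in [0, 1] before noise, and lags the ABP by
    ``spec.ppg_delay``.  Deterministic for a fixed ``(spec, seed)``.
    """
    if fs < 25:
        raise SpecificationError(f"fs >= 25 Hz violated (got {fs})")
    if duration < spec.period:
        raise SpecificationError(
            f"duration >= one cardiac period violated "
            f"(duration={duration}, period={spec.period:.3f})")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    shape_abp = _pulse_shape_unit(t, spec)
    shape_ppg = _pulse_shape_unit(t - spec.ppg_delay, spec)

    abp = spec.dbp + (spec.sbp - spec.dbp) * shape_abp
    ppg = shape_ppg.copy()
    rng = np.random.default_rng(seed)
    if spec.bw_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ppg += spec.bw_amplitude * np.sin(
            2 * np.pi * spec.bw_frequency * t + phase)
    if spec.noise_sd > 0:
        ppg += spec.noise_sd * rng.standard_normal(n)

    meta = {"spec": spec, "seed": int(seed), "sbp": spec.sbp, "dbp": spec.dbp,
            "heart_rate": spec.heart_rate, "artifact": None}
    return SignalRecord(subject_id=subject_id, record_id=record_id, fs=fs,
                        ppg=ppg, abp=abp, meta=meta)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort of single-segment records per the cohort spec.

    Subject-level (SBP, DBP, heart rate, morphology) parameters are drawn
    once per subject; per-segment labels jitter by ``within_subject_sd``
    (DBP at half that scale).  Draws with pulse pressure below 15 mmHg are
    rejected and resampled; the rejection rate is reported in the cohort
    metadata.  ``artifact_fraction`` of segments receive a randomly chosen
    injected artifact and carry a ground-truth tag in ``record.meta``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_draw = 0
    n_reject = 0

    def draw_pair(sbp_level=None):
        nonlocal n_draw, n_reject
        for _ in range(1000):
            n_draw += 1
            sbp = (spec.sbp_distribution.sample(rng, 1)[0]
                   if sbp_level is None else sbp_level)
            dbp = spec.dbp_distribution.sample(rng, 1)[0]
            if sbp - dbp >= 15.0:
                return float(sbp), float(dbp)
            n_reject += 1
        raise SpecificationError(
            "could not draw sbp > dbp after 1000 rejections; "
            "check sbp_distribution / dbp_distribution")

    records: list[SignalRecord] = []
    seed_seq = np.random.SeedSequence(spec.seed).spawn(
        spec.n_subjects * spec.segments_per_subject + 1)
    seed_i = 0
    for i in range(spec.n_subjects):
        subject = f"sub{i:04d}"
        hr_i = float(np.clip(rng.normal(spec.heart_rate_mean,
                                        spec.heart_rate_sd), 45.0, 110.0))
        if spec.sbp_affine_hr is not None:
            slope, intercept, lab_noise = spec.sbp_affine_hr
            sbp_i = slope * hr_i + intercept + rng.normal(0.0, lab_noise)
            sbp_i, dbp_i = draw_pair(sbp_level=sbp_i)
        else:
            sbp_i, dbp_i = draw_pair()
        T_i = 60.0 / hr_i
        nd_i = float(rng.uniform(0.24, 0.30)) * T_i
        depth_i = float(rng.uniform(0.25, 0.45))
        delay_i = float(np.clip(rng.normal(spec.ppg_delay_mean,
                                           spec.ppg_delay_sd), 0.05, 0.45))
        for j in range(spec.segments_per_subject):
            if spec.within_subject_sd > 0:
                for _ in range(1000):
                    sbp_ij = sbp_i + rng.normal(0, spec.within_subject_sd)
                    dbp_ij = dbp_i + rng.normal(0, 0.5 * spec.within_subject_sd)
                    if sbp_ij - dbp_ij >= 15.0:
                        break
            else:
                sbp_ij, dbp_ij = sbp_i, dbp_i
            pulse = PulseSpec(
                heart_rate=hr_i, sbp=float(sbp_ij), dbp=float(dbp_ij),
                notch_delay=nd_i, notch_depth=depth_i, ppg_delay=delay_i,
                noise_sd=spec.noise_sd, bw_amplitude=spec.bw_amplitude,
                bw_frequency=spec.bw_frequency)
            rec_seed = int(seed_seq[seed_i].generate_state(1)[0] % (2 ** 31))
            seed_i += 1
            rec = generate_pulse_train(
                pulse, spec.segment_length + spec.alignment_pad,
                spec.sampling_rate,
                seed=rec_seed, subject_id=subject,
                record_id=f"{subject}-{j:03d}")
            records.append(rec)

    # artifact injection with ground-truth tags
    n_seg = len(records)
    if spec.artifact_fraction > 0:
        mask = rng.random(n_seg) < spec.artifact_fraction
        for idx in np.flatnonzero(mask):
            kind = spec.artifact_kinds[
                int(rng.integers(len(spec.artifact_kinds)))]
            inj_seed = int(seed_seq[-1].generate_state(1)[0] % (2 ** 31)) + int(idx)
            records[idx] = inject_artifact(records[idx], kind, seed=inj_seed)

    meta = {
        "spec": spec,
        "seed": int(spec.seed),
        "rejection_rate": (n_reject / n_draw) if n_draw else 0.0,
        "n_records": n_seg,
        "n_artifact": int(sum(r.meta.get("artifact") is not None
                              for r in records)),
    }
    return Cohort(records, meta)


def inject_artifact(record: SignalRecord, kind: str,
                    seed: int = 0) -> SignalRecord:
    """Return a copy of ``record`` violating exactly the targeted filter.

    Kinds mirror the pipeline's removal criteria: ``flatline`` (no cardiac
    cycles), ``amplitude_spike`` (PPG peak-amplitude distortion),
    ``extreme_bp`` (ABP above 220 mmHg), ``low_pp`` (pulse pressure below
    10 mmHg), ``tachy``/``brady`` (heart rate outside 35–140 BPM), and
    ``bw_drift`` (0.2 Hz baseline wander; cycle structure preserved, the
    pipeline corrects rather than removes it).  The input record is left
    untouched.
    """
    if kind not in ARTIFACT_KINDS:
        raise SpecificationError(
            f"unknown artifact kind {kind!r}; one of {ARTIFACT_KINDS}")
    rng = np.random.default_rng(seed)
    out = record.copy()
    spec: PulseSpec | None = out.meta.get("spec")

    if kind == "flatline":
        out.ppg[:] = float(np.median(out.ppg))
        if out.abp is not None:
            out.abp[:] = float(np.median(out.abp))
    elif kind == "amplitude_spike":
        # inflate two pulse peaks so the peak-amplitude SD explodes
        from scipy.signal import find_peaks
        dist = max(1, int(round(out.fs * 60.0 / 140.0)))
        peaks, _ = find_peaks(out.ppg, distance=dist,
                              prominence=0.25 * np.ptp(out.ppg))
        # keep spikes inside the window that survives alignment truncation
        # and trailing-remainder discard during segmentation
        lo = int(0.6 * out.fs)
        hi = len(out.ppg) - int(1.1 * out.fs)
        interior = peaks[(peaks >= lo) & (peaks <= hi)]
        if len(interior):
            peaks = interior
        if len(peaks) == 0:
            peaks = np.array([len(out.ppg) // 2])
        chosen = peaks[rng.choice(len(peaks), size=min(2, len(peaks)),
                                  replace=False)]
        width = max(2, int(0.04 * out.fs))
        amp = 1.5 * np.ptp(out.ppg)
        for p in chosen:
            lo, hi = max(0, p - width), min(len(out.ppg), p + width + 1)
            bump = amp * (1 - np.abs(np.arange(lo, hi) - p) / width)
            out.ppg[lo:hi] += np.clip(bump, 0, None)
    elif kind == "extreme_bp":
        if out.abp is None:
            raise SpecificationError("extreme_bp artifact requires ABP")
        out.abp += (230.0 - out.abp.max())
    elif kind == "low_pp":
        if out.abp is None:
            raise SpecificationError("low_pp artifact requires ABP")
        mean = out.abp.mean()
        pp = out.abp.max() - out.abp.min()
        out.abp = mean + (out.abp - mean) * (8.0 / pp)
    elif kind in ("tachy", "brady"):
        hr = 160.0 if kind == "tachy" else 28.0
        base = spec if spec is not None else PulseSpec()
        new_spec = replace(base, heart_rate=hr,
                           notch_delay=0.28 * 60.0 / hr)
        regen = generate_pulse_train(
            new_spec, duration=len(out.ppg) / out.fs, fs=out.fs,
            seed=int(rng.integers(2 ** 31)), subject_id=out.subject_id,
            record_id=out.record_id)
        out.ppg = regen.ppg
        out.abp = regen.abp
        out.meta["spec"] = new_spec
    elif kind == "bw_drift":
        t = np.arange(len(out.ppg)) / out.fs
        out.ppg += 0.3 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))

    out.meta["artifact"] = kind
    return out


# ---------------------------------------------------------------------------
# presets emulating the published dataset statistics
# ---------------------------------------------------------------------------

PRESETS: dict[str, CohortSpec] = {
    # ICU subset: many subjects, ~9 segments each, wide skewed SBP
    "sensors": CohortSpec(
        n_subjects=100, segments_per_subject=9,
        sbp_distribution=BPDistribution(134.36, 21.78, 0.5),
        dbp_distribution=BPDistribution(65.37, 10.51, 0.5)),
    # large continuous-recording set, narrow SBP spread, no subject ids
    "uci": CohortSpec(
        n_subjects=60, segments_per_subject=38,
        sbp_distribution=BPDistribution(131.57, 11.16, 0.5),
        dbp_distribution=BPDistribution(66.79, 10.48, 0.5)),
    # small bed-sensor cohort with very many segments per subject
    "bcg": CohortSpec(
        n_subjects=40, segments_per_subject=76,
        sbp_distribution=BPDistribution(120.99, 15.29, 0.5),
        dbp_distribution=BPDistribution(67.23, 9.30, 0.5)),
    # short fingertip recordings, 3 short segments per subject
    "ppgbp": CohortSpec(
        n_subjects=100, segments_per_subject=3, segment_length=2.1,
        sbp_distribution=BPDistribution(128.02, 20.50, 0.5),
        dbp_distribution=BPDistribution(71.91, 11.20, 0.5)),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _spec_to_jsonable(obj):
    if isinstance(obj, (PulseSpec, CohortSpec, BPDistribution)):
        return {k: _spec_to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def write_cohort_csv(cohort: Cohort, out_dir) -> None:
    """Write a columnar table (one row per sample) plus a JSON sidecar."""
    import pandas as pd
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    sidecar = {"fs": None, "units": {"abp": "mmHg", "ppg": "arbitrary"},
               "records": {}, "seed": cohort.meta.get("seed"),
               "spec": _spec_to_jsonable(cohort.meta.get("spec"))}
    for rec in cohort:
        n = len(rec.ppg)
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "record_id": rec.record_id,
            "t": np.arange(n) / rec.fs,
            "ppg": rec.ppg,
            "abp": rec.abp if rec.abp is not None else np.nan,
        }))
        sidecar["fs"] = rec.fs
        sidecar["records"][rec.record_id] = {
            "subject_id": rec.subject_id,
            "sbp": rec.meta.get("sbp"), "dbp": rec.meta.get("dbp"),
            "heart_rate": rec.meta.get("heart_rate"),
            "artifact": rec.meta.get("artifact"),
        }
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / "records.csv", index=False)
    (out_dir / "records.json").write_text(json.dumps(sidecar, indent=1))


def read_cohort_csv(in_dir) -> Cohort:
    import pandas as pd
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "records.csv")
    sidecar = json.loads((in_dir / "records.json").read_text())
    fs = float(sidecar["fs"])
    records = []
    for rec_id, grp in table.groupby("record_id", sort=False):
        info = sidecar["records"].get(str(rec_id), {})
        abp = grp["abp"].to_numpy()
        records.append(SignalRecord(
            subject_id=str(grp["subject_id"].iloc[0]), record_id=str(rec_id),
            fs=fs, ppg=grp["ppg"].to_numpy(),
            abp=None if np.isnan(abp).all() else abp,
            meta={"sbp": info.get("sbp"), "dbp": info.get("dbp"),
                  "heart_rate": info.get("heart_rate"),
                  "artifact": info.get("artifact")}))
    return Cohort(records, {"seed": sidecar.get("seed")})


def write_cohort_hdf5(cohort: Cohort, path) -> None:
    """Single-file container variant: one HDF5 group per record."""
    import h5py
    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = cohort.meta.get("seed") or 0
        for rec in cohort:
            g = h5.create_group(rec.record_id)
            g.create_dataset("ppg", data=rec.ppg)
            if rec.abp is not None:
                g.create_dataset("abp", data=rec.abp)
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["fs"] = rec.fs
            for key in ("sbp", "dbp", "heart_rate"):
                if rec.meta.get(key) is not None:
                    g.attrs[key] = rec.meta[key]
            g.attrs["artifact"] = rec.meta.get("artifact") or ""


def read_cohort_hdf5(path) -> Cohort:
    import h5py
    records = []
    with h5py.File(path, "r") as h5:
        for rec_id in h5:
            g = h5[rec_id]
            meta = {k: g.attrs.get(k) for k in ("sbp", "dbp", "heart_rate")}
            meta["artifact"] = g.attrs.get("artifact") or None
            records.append(SignalRecord(
                subject_id=str(g.attrs["subject_id"]), record_id=rec_id,
                fs=float(g.attrs["fs"]), ppg=g["ppg"][...],
                abp=g["abp"][...] if "abp" in g else None, meta=meta))
        seed = int(h5.attrs.get("seed", 0))
    return Cohort(records, {"seed": seed})
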