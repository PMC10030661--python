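"""Subject-grouped, multi-label-stratified data splitting.

BP cohorts violate two assumptions of plain random K-fold splitting: many
segments share a subject (so uniform splits leak subject information between
train and test), and SBP/DBP are skewed (so rare, extreme-BP subjects can
vanish from folds).  The remedy implemented here:

1. encode each segment's (SBP, DBP) into a 4x4 grid of classes
   (SBP cut at 100/140/160 mmHg, DBP at 60/80/100 mmHg, half-open on the
   left: the lower boundary belongs to the upper class);
2. count, per subject, the frequencies of the 16 joint classes;
3. assign whole subjects to folds by iterative stratification for
   multi-label data: repeatedly take the joint class with the fewest
   remaining examples, the subject richest in that class, and the fold
   whose remaining desideratum for that class is largest.

A deliberately wrong uniform segment-level split (`leaked_split`) is
provided as the baseline for leakage experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "BPClassEncoding", "FoldAssignment",
    "SBP_EDGES", "DBP_EDGES", "N_JOINT_CLASSES",
    "encode_bp_class", "build_subject_matrix",
    "stratified_subject_kfold", "holdout_split", "leaked_split",
    "audit_split", "total_variation",
]

SBP_EDGES = (100.0, 140.0, 160.0)
DBP_EDGES = (60.0, 80.0, 100.0)
N_JOINT_CLASSES = 16


@dataclass(frozen=True)
class BPClassEncoding:
    sbp_class: int  # 1..4
    dbp_class: int  # 1..4

    @property
    def joint_class(self) -> int:
        """1..16, row-major over (sbp_class, dbp_class)."""
        return 4 * (self.sbp_class - 1) + self.dbp_class


def encode_bp_class(sbp: float, dbp: float) -> BPClassEncoding:
    """Class encoding with half-open [lo, hi) intervals.

    SBP: (1) < 100, (2) [100, 140), (3) [140, 160), (4) >= 160 mmHg.
    DBP: (1) < 60, (2) [60, 80), (3) [80, 100), (4) >= 100 mmHg.
    """
    if not (np.isfinite(sbp) and np.isfinite(dbp)):
        raise DataError(f"non-finite BP values ({sbp}, {dbp})")
    sc = int(np.digitize(sbp, SBP_EDGES)) + 1
    dc = int(np.digitize(dbp, DBP_EDGES)) + 1
    return BPClassEncoding(sbp_class=sc, dbp_class=dc)


def build_subject_matrix(segments) -> pd.DataFrame:
    """Per-subject counts over the 16 joint BP classes.

    ``segments`` is an iterable of objects (or DataFrame rows) carrying
    ``subject_id``, ``sbp``/``sbp_label`` and ``dbp``/``dbp_label``.  Row
    sums equal each subject's segment count; subjects appear iff they have
    at least one labelled segment.
    """
    rows = []
    for seg in _iter_labelled(segments):
        subject, sbp, dbp = seg
        if sbp is None or dbp is None or not np.isfinite([sbp, dbp]).all():
            raise DataError(f"segment of {subject} lacks BP labels")
        rows.append((subject, encode_bp_class(sbp, dbp).joint_class))
    if not rows:
        raise DataError("no labelled segments")
    df = pd.DataFrame(rows, columns=["subject_id", "joint"])
    mat = (df.value_counts(["subject_id", "joint"]).unstack(fill_value=0)
             .reindex(columns=range(1, N_JOINT_CLASSES + 1), fill_value=0))
    mat.columns = [f"class_{c}" for c in mat.columns]
    return mat.sort_index()


def _iter_labelled(segments):
    if isinstance(segments, pd.DataFrame):
        sbp_col = "sbp" if "sbp" in segments.columns else "sbp_label"
        dbp_col = "dbp" if "dbp" in segments.columns else "dbp_label"
        for _, row in segments.iterrows():
            yield row["subject_id"], row[sbp_col], row[dbp_col]
    else:
        for seg in segments:
            yield (seg.subject_id,
                   getattr(seg, "sbp_label", getattr(seg, "sbp", None)),
                   getattr(seg, "dbp_label", getattr(seg, "dbp", None)))


@dataclass
class FoldAssignment:
    """Subject→fold mapping with fold-level distribution bookkeeping."""

    assignment: dict           # subject_id (or segment key) -> fold index
    n_folds: int
    fold_class_counts: pd.DataFrame   # folds x 16 joint classes
    leakage_fraction: float
    seed: int
    mode: str = "stratified"
    fold_weights: tuple | None = None
    meta: dict = field(default_factory=dict)

    def fold_of(self, key) -> int:
        return self.assignment[key]

    def subjects_in(self, fold: int) -> list:
        return [k for k, f in self.assignment.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["subject_id", "fold"])

    def summary(self) -> dict:
        return {
            "K": self.n_folds, "seed": self.seed, "mode": self.mode,
            "leakage_fraction": self.leakage_fraction,
            "fold_class_counts":
                self.fold_class_counts.to_dict(orient="index"),
        }


def _iterative_stratification(matrix: pd.DataFrame, weights: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Greedy iterative stratification of count-weighted subject rows.

    Classic multi-label stratification, generalized to subjects that carry
    *counts* of each label rather than binary indicators, and to unequal
    fold weights.  Processing order: the label with the fewest remaining
    examples first; within it, the subject with the most examples of that
    label; the subject goes to the fold with the largest remaining
    desideratum for that label (ties: largest total remaining desideratum,
    then seeded randomness).
    """
    counts = matrix.to_numpy(dtype=float)
    n_subjects, n_classes = counts.shape
    n_folds = len(weights)
    desire = np.outer(weights, counts.sum(axis=0))      # folds x classes
    desire_total = weights * counts.sum()
    assignment = np.full(n_subjects, -1, dtype=int)
    remaining = np.ones(n_subjects, dtype=bool)

    while remaining.any():
        class_totals = counts[remaining].sum(axis=0)
        active = np.flatnonzero(class_totals > 0)
        if len(active) == 0:
            # subjects with all-zero rows: place by total desideratum
            for i in np.flatnonzero(remaining):
                f = _argmax_tiebreak(desire_total, rng)
                assignment[i] = f
                desire_total[f] -= 1
                remaining[i] = False
            break
        c = active[np.argmin(class_totals[active])]
        cand = np.flatnonzero(remaining & (counts[:, c] > 0))
        i = cand[_argmax_tiebreak(counts[cand, c], rng)]
        f = _argmax_tiebreak(desire[:, c], rng, desire_total)
        assignment[i] = f
        desire[f] -= counts[i]
        desire_total[f] -= counts[i].sum()
        remaining[i] = False
    return assignment


def _argmax_tiebreak(primary: np.ndarray, rng: np.random.Generator,
                     secondary: np.ndarray | None = None) -> int:
    best = np.flatnonzero(primary == primary.max())
    if len(best) > 1 and secondary is not None:
        sec = secondary[best]
        best = best[np.flatnonzero(sec == sec.max())]
    if len(best) == 1:
        return int(best[0])
    return int(rng.choice(best))


def _fold_counts(matrix: pd.DataFrame, assignment: np.ndarray,
                 n_folds: int) -> pd.DataFrame:
    counts = matrix.to_numpy(dtype=float)
    out = np.zeros((n_folds, matrix.shape[1]))
    for f in range(n_folds):
        out[f] = counts[assignment == f].sum(axis=0)
    return pd.DataFrame(out, index=range(n_folds), columns=matrix.columns)


def stratified_subject_kfold(matrix: pd.DataFrame, n_folds: int,
                             seed: int = 0) -> FoldAssignment:
    """Subject-grouped K-fold assignment by iterative stratification.

    All segments of a subject share a fold, so the leakage fraction is zero
    by construction.  Deterministic for a fixed seed.
    """
    if n_folds < 2:
        raise ConfigurationError("K >= 2 required")
    if n_folds > len(matrix):
        raise ConfigurationError(
            f"K={n_folds} exceeds the number of subjects ({len(matrix)})")
    rng = np.random.default_rng(seed)
    weights = np.full(n_folds, 1.0 / n_folds)
    order = matrix.sort_index()
    assignment = _iterative_stratification(order, weights, rng)
    return FoldAssignment(
        assignment=dict(zip(order.index, (int(f) for f in assignment))),
        n_folds=n_folds,
        fold_class_counts=_fold_counts(order, assignment, n_folds),
        leakage_fraction=0.0, seed=seed, mode="stratified")


def holdout_split(matrix: pd.DataFrame, fractions=(0.6, 0.2, 0.2),
                  seed: int = 0, pseudo_subjects: bool = False
                  ) -> FoldAssignment:
    """One stratified train/validation/test split with unequal fold weights.

    Uses the same stratification engine as K-fold with fold weights equal
    to ``fractions``.  When true subject identifiers are unavailable and
    records stand in as pseudo-subjects, set ``pseudo_subjects=True`` — the
    caveat is recorded in the assignment metadata (leakage between sets
    can then no longer be excluded).
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ConfigurationError("all fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1 (got {fractions})")
    rng = np.random.default_rng(seed)
    order = matrix.sort_index()
    assignment = _iterative_stratification(
        order, np.asarray(fractions), rng)
    fa = FoldAssignment(
        assignment=dict(zip(order.index, (int(f) for f in assignment))),
        n_folds=len(fractions),
        fold_class_counts=_fold_counts(order, assignment, len(fractions)),
        leakage_fraction=0.0, seed=seed, mode="holdout",
        fold_weights=fractions)
    if pseudo_subjects:
        fa.meta["pseudo_subjects"] = True
        fa.meta["caveat"] = ("records used as pseudo-subjects: subject "
                             "leakage between sets cannot be excluded")
    return fa


def leaked_split(segments, n_folds: int, seed: int = 0) -> FoldAssignment:
    """Uniform segment-level split — the deliberately wrong baseline.

    Segments (not subjects) are assigned uniformly at random to folds.  The
    reported leakage fraction is the fraction of segments whose subject
    also appears in at least one other fold (i.e. in the training partition
    when that segment's fold is the test set).
    """
    if n_folds < 2:
        raise ConfigurationError("K >= 2 required")
    segs = list(_segment_keys(segments))
    rng = np.random.default_rng(seed)
    folds = rng.integers(0, n_folds, size=len(segs))
    subjects = np.array([s[1] for s in segs])
    leak = 0
    for i, f in enumerate(folds):
        if (subjects[folds != f] == subjects[i]).any():
            leak += 1
    assignment = {key: int(f) for (key, _subj), f in zip(segs, folds)}
    # fold class counts at segment level when labels are available
    counts = _segment_fold_counts(segments, assignment, n_folds)
    return FoldAssignment(
        assignment=assignment, n_folds=n_folds, fold_class_counts=counts,
        leakage_fraction=leak / max(len(segs), 1), seed=seed, mode="leaked")


def _segment_keys(segments):
    if isinstance(segments, pd.DataFrame):
        for _, row in segments.iterrows():
            yield ((row["subject_id"], row["record_id"],
                    row.get("segment_index", 0)), row["subject_id"])
    else:
        for seg in segments:
            yield ((seg.subject_id, seg.record_id,
                    getattr(seg, "segment_index", 0)), seg.subject_id)


def _segment_fold_counts(segments, assignment, n_folds):
    rows = np.zeros((n_folds, N_JOINT_CLASSES))
    for (key, _subj), lab in zip(_segment_keys(segments),
                                 _iter_labelled(segments)):
        _, sbp, dbp = lab
        if sbp is None or dbp is None:
            continue
        j = encode_bp_class(sbp, dbp).joint_class
        rows[assignment[key], j - 1] += 1
    return pd.DataFrame(rows, index=range(n_folds),
                        columns=[f"class_{c}"
                                 for c in range(1, N_JOINT_CLASSES + 1)])


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum() if p.sum() else p
    q = q / q.sum() if q.sum() else q
    return 0.5 * float(np.abs(p - q).sum())


def audit_split(assignment: FoldAssignment, segments) -> dict:
    """Distributional audit of a fold assignment.

    Reports, per fold: SBP/DBP histograms, joint-class frequencies and the
    total-variation distance to the pooled distribution; plus the overall
    leakage fraction (recomputed from the segments for subject-keyed
    assignments, where it must be zero).
    """
    df = pd.DataFrame(
        [(s, b, d) for s, b, d in _iter_labelled(segments)],
        columns=["subject_id", "sbp", "dbp"])
    if assignment.mode == "leaked":
        keys = [k for k, _ in _segment_keys(segments)]
        df["fold"] = [assignment.assignment[k] for k in keys]
    else:
        unknown = set(df["subject_id"]) - set(assignment.assignment)
        if unknown:
            raise DataError(f"assignment missing subjects: {sorted(unknown)}")
        df["fold"] = df["subject_id"].map(assignment.assignment)
    joint = df.apply(
        lambda r: encode_bp_class(r["sbp"], r["dbp"]).joint_class, axis=1)
    global_counts = np.bincount(joint, minlength=N_JOINT_CLASSES + 1)[1:]
    report = {"K": assignment.n_folds, "mode": assignment.mode,
              "folds": {}, "max_tv": 0.0}
    sbp_edges = np.arange(60, 221, 10)
    dbp_edges = np.arange(30, 131, 10)
    for f in range(assignment.n_folds):
        sub = df[df["fold"] == f]
        fold_counts = np.bincount(joint[sub.index],
                                  minlength=N_JOINT_CLASSES + 1)[1:]
        tv = total_variation(fold_counts, global_counts)
        report["folds"][f] = {
            "n_segments": int(len(sub)),
            "n_subjects": int(sub["subject_id"].nunique()),
            "sbp_hist": np.histogram(sub["sbp"], bins=sbp_edges)[0].tolist(),
            "dbp_hist": np.histogram(sub["dbp"], bins=dbp_edges)[0].tolist(),
            "joint_class_counts": fold_counts.tolist(),
            "tv_to_global": tv,
        }
        report["max_tv"] = max(report["max_tv"], tv)

    # leakage recomputed from the data
    if assignment.mode == "leaked":
        report["leakage_fraction"] = assignment.leakage_fraction
    else:
        per_subject_folds = df.groupby("subject_id")["fold"].nunique()
        report["leakage_fraction"] = float(
            (per_subject_folds > 1).mean() if len(per_subject_folds) else 0.0)
    return report
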