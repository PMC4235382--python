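"""ORI vs non-ORI window discrimination with an RBF-kernel SVM.

The positive set is the 300-bp window centred on each ORI midpoint; the
negative set is the 300 bp immediately upstream (lower coordinates,
abutting).  Each feature family is a profile vector across the instance
window: GC profile and GC skew in 50-bp sliding windows at 1-bp step
(251 dims), adjacent-pair information redundancy D_2 in 150-bp windows
(151 dims), or per-base nucleosome occupancy (300 dims).  A scalar mode
(one mean value per instance) is available for comparison.

Evaluation is stratified k-fold cross-validation with per-fold
standardisation fitted on the training split only; confusion totals are
accumulated over held-out folds and reported as sensitivity,
specificity and accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import GenomeSequence, GenomicInterval, SignalTrack
from . import signals as sig

FAMILIES = ("gc_profile", "gc_skew", "d2", "nucleosome")


@dataclass(frozen=True)
class LabeledInstance:
    interval: GenomicInterval
    label: int  # 1 = positive (ORI), 0 = negative (upstream)
    features: np.ndarray
    family: str


@dataclass(frozen=True)
class CVReport:
    family: str
    folds: int
    tp: int
    fp: int
    tn: int
    fn: int
    seed: int

    @property
    def sn(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def acc(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def _features(
    seq_or_track: str | np.ndarray,
    family: str,
    signal_window: int,
    d2_window: int,
    step: int,
    scalar: bool,
) -> np.ndarray:
    if family in ("gc_profile", "gc_skew"):
        vec = sig.window_values(seq_or_track, signal_window, step, stat=family)
    elif family == "d2":
        vec = sig.window_redundancy_values(seq_or_track, d2_window, step, k=0)
    elif family == "nucleosome":
        vec = np.asarray(seq_or_track, dtype=float)
    else:
        raise ValueError(f"unknown feature family {family!r}; expected {FAMILIES}")
    if scalar:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.array([np.nanmean(vec)])
    return vec


def build_instance_sets(
    genome: Sequence[GenomeSequence],
    oris: Sequence[GenomicInterval],
    family: str = "gc_profile",
    track: SignalTrack | None = None,
    instance_window: int = 300,
    signal_window: int = 50,
    d2_window: int = 150,
    step: int = 1,
    feature_mode: str = "profile",
    min_oris: int = 20,
) -> list[LabeledInstance]:
    """Positive/negative labelled windows with per-family feature vectors.

    Negative windows that run off the chromosome or overlap another ORI's
    positive window are dropped with a warning.
    """
    if family == "nucleosome" and track is None:
        raise ValueError("family='nucleosome' requires a SignalTrack")
    if feature_mode not in ("profile", "scalar"):
        raise ValueError("feature_mode must be 'profile' or 'scalar'")
    scalar = feature_mode == "scalar"
    chroms = {g.name: g for g in genome}
    half = instance_window // 2

    positives: list[GenomicInterval] = []
    negatives: list[GenomicInterval | None] = []
    dropped_bounds = 0
    for o in oris:
        mid = o.midpoint
        chrom = chroms.get(o.chrom)
        pos = (mid - half, mid - half + instance_window)
        neg = (pos[0] - instance_window, pos[0])
        if chrom is None or pos[1] > len(chrom) or pos[0] < 0:
            dropped_bounds += 1
            continue
        positives.append(GenomicInterval(o.chrom, *pos, ".", o.label))
        if neg[0] < 0:
            negatives.append(None)
            dropped_bounds += 1
        else:
            negatives.append(GenomicInterval(o.chrom, *neg, ".", o.label))
    if dropped_bounds:
        warnings.warn(
            f"{dropped_bounds} window(s) exceeded chromosome bounds; dropped",
            stacklevel=2,
        )
    # drop negatives overlapping any other ORI's positive window
    dropped_overlap = 0
    clean_negatives: list[GenomicInterval] = []
    for i, neg in enumerate(negatives):
        if neg is None:
            continue
        if any(neg.overlaps(p) for j, p in enumerate(positives) if j != i):
            dropped_overlap += 1
            continue
        clean_negatives.append(neg)
    if dropped_overlap:
        warnings.warn(
            f"{dropped_overlap} negative window(s) overlapped a positive window; "
            "dropped", stacklevel=2,
        )
    if len(positives) < min_oris:
        raise ValueError(
            f"only {len(positives)} usable ORIs (< {min_oris}); cross-validation "
            "infeasible"
        )

    instances = []
    for label, windows in ((1, positives), (0, clean_negatives)):
        for w in windows:
            if family == "nucleosome":
                data: str | np.ndarray = track.values(w.chrom, w.start, w.end)
            else:
                data = chroms[w.chrom].seq[w.start:w.end]
            feats = _features(data, family, signal_window, d2_window, step, scalar)
            instances.append(LabeledInstance(w, label, feats, family))
    dims = {len(inst.features) for inst in instances}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions {sorted(dims)}")
    return instances


def fold_standardizer(
    x_train: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Imputation means, scales and kept-dimension mask from training rows only."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(x_train, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    filled = np.where(np.isnan(x_train), mu, x_train)
    sd = filled.std(axis=0, ddof=0)
    keep = sd > 0
    return mu, sd, keep


def _apply_standardizer(
    x: np.ndarray, mu: np.ndarray, sd: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    filled = np.where(np.isnan(x), mu, x)
    return (filled[:, keep] - mu[keep]) / sd[keep]


def cross_validate_svm(
    instances: Sequence[LabeledInstance],
    folds: int = 10,
    seed: int = 0,
    c: float = 1.0,
    gamma: str | float = "scale",
    kernel: str = "rbf",
) -> CVReport:
    """Stratified k-fold CV of an SVM; returns pooled confusion totals.

    Standardisation (train-fold mean/SD) and NaN imputation (train-fold
    mean) are fitted inside each fold; zero-variance features are dropped
    per fold with a warning.  With identical seed and inputs the result
    is bit-reproducible.
    """
    families = {inst.family for inst in instances}
    if len(families) != 1:
        raise ValueError(f"instances mix feature families {sorted(families)}")
    x = np.vstack([inst.features for inst in instances])
    y = np.array([inst.label for inst in instances])
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < 2:
        raise ValueError("need at least 2 instances per class")
    if folds > min(n_pos, n_neg):
        raise ValueError(f"folds={folds} exceeds minority class size {min(n_pos, n_neg)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    warned_dropped = False
    for train_idx, test_idx in skf.split(x, y):
        mu, sd, keep = fold_standardizer(x[train_idx])
        if not keep.all() and not warned_dropped:
            warnings.warn(
                f"{int((~keep).sum())} zero-variance feature(s) dropped in a fold",
                stacklevel=2,
            )
            warned_dropped = True
        if not keep.any():
            raise ValueError("all features degenerate in a training fold")
        x_train = _apply_standardizer(x[train_idx], mu, sd, keep)
        x_test = _apply_standardizer(x[test_idx], mu, sd, keep)
        clf = SVC(C=c, kernel=kernel, gamma=gamma)
        clf.fit(x_train, y[train_idx])
        pred = clf.predict(x_test)
        truth = y[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    family = next(iter(families))
    return CVReport(family, folds, tp, fp, tn, fn, seed)


def report_table(reports: Sequence[CVReport]) -> pd.DataFrame:
    """One row per feature family with Sn / Sp / Acc at 4 decimals."""
    if not reports:
        raise ValueError("no reports to tabulate")
    rows = [
        {
            "family": r.family,
            "folds": r.folds,
            "TP": r.tp, "FP": r.fp, "TN": r.tn, "FN": r.fn,
            "Sn": round(r.sn, 4), "Sp": round(r.sp, 4), "Acc": round(r.acc, 4),
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
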