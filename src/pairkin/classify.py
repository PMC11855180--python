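"""Mapping method outputs to relationship classes and tallying results.

Classes are ordered S1 < S2 < S3 < S4 < Un (1..5); every tie-break goes to
the more distant class.  The total-cM classifier bins the accumulated
shared-segment length with geometric-midpoint boundaries between the
expected per-class totals; the segment-feature classifier compares
(number of segments, mean segment length) against simulated per-class
centroids by z-scored Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relationship import (
    CLASSES,
    CLASS_LABELS,
    INCONCLUSIVE,
    RELATED_CLASSES,
    ClassCall,
)
from .simulate import simulate_ibd_track, _merged_intervals

__all__ = [
    "CM_CLASS_MEANS",
    "cm_class_bounds",
    "cm_classify",
    "SegmentFeatureReference",
    "build_segment_feature_reference",
    "segment_feature_classify",
    "consensus_classify",
    "ClassRateMatrix",
    "classification_matrix",
    "zero_ibd_fraction",
]

#: Expected total shared cM per class on the default 3280 cM map: the
#: related-class values are the expected per-class totals on this map; the
#: value is the order of magnitude shared by chance.
CM_CLASS_MEANS = {"S1": 2460.0, "S2": 818.0, "S3": 298.0, "S4": 49.0, "Un": 10.0}


def cm_class_bounds(means=None) -> tuple:
    """Geometric-midpoint boundaries between adjacent class means.

    Returns four descending thresholds; a total above the first is S1, and
    so on down to Un below the last.  A total exactly at a boundary goes to
    the more distant class.
    """
    means = CM_CLASS_MEANS if means is None else means
    vals = [means[c.label] for c in CLASSES]
    return tuple(
        float(np.sqrt(vals[i] * vals[i + 1])) for i in range(len(vals) - 1)
    )


def cm_classify(total_cm: float, means=None, method: str = "segment") -> ClassCall:
    """Classify by total accumulated shared cM."""
    if total_cm < 0:
        raise ValueError("total_cm must be >= 0")
    bounds = cm_class_bounds(means)
    for spec, bound in zip(CLASSES[:4], bounds):
        if total_cm > bound:
            return ClassCall(spec.label, method=method, aux={"total_cm": total_cm})
    return ClassCall("Un", method=method, aux={"total_cm": total_cm})


@dataclass(frozen=True)
class SegmentFeatureReference:
    """Per-class centroids of (n_segments, mean segment cM) with pooled SDs.

    Built from simulated true-IBD tracks with the same map and length
    cutoff as the classification inputs.
    """

    centroids: dict  # label -> (mean n_segments, mean segment cM)
    pooled_sd: tuple  # (sd of n_segments, sd of mean segment cM)
    min_cm: float
    n_per_class: int


def build_segment_feature_reference(
    gmap, n_per_class: int = 10_000, min_cm: float = 5.0, seed=0
) -> SegmentFeatureReference:
    """Simulate per-class true-IBD tracks and summarize their features.

    The unrelated class contributes the (0, 0) centroid without simulation
    (frequency-drawn unrelated pairs share no true IBD by construction).
    """
    rng = np.random.default_rng(seed)
    centroids = {}
    var_sum = np.zeros(2)
    n_var = 0
    for spec in RELATED_CLASSES:
        feats = np.empty((n_per_class, 2))
        for i in range(n_per_class):
            _, segs = simulate_ibd_track(spec, gmap, rng)
            merged = _merged_intervals(segs)
            lens = [
                b - a
                for ivals in merged.values()
                for a, b in ivals
                if (b - a) >= min_cm
            ]
            feats[i] = (len(lens), float(np.mean(lens)) if lens else 0.0)
        centroids[spec.label] = tuple(feats.mean(axis=0))
        var_sum += feats.var(axis=0, ddof=1) * (n_per_class - 1)
        n_var += n_per_class - 1
    centroids["Un"] = (0.0, 0.0)
    pooled_sd = tuple(np.sqrt(var_sum / n_var))
    return SegmentFeatureReference(
        centroids=centroids, pooled_sd=pooled_sd, min_cm=min_cm,
        n_per_class=n_per_class,
    )


def segment_feature_classify(
    n_segments: float, mean_segment_cm: float, ref: SegmentFeatureReference,
    method: str = "segment_features",
) -> ClassCall:
    """Nearest per-class centroid in z-scored feature space."""
    if ref is None:
        raise ValueError("segment-feature reference is required")
    x = np.array([n_segments, mean_segment_cm], dtype=float)
    sd = np.asarray(ref.pooled_sd)
    best, best_d = None, np.inf
    for spec in CLASSES:
        d = float(np.sum(((x - np.asarray(ref.centroids[spec.label])) / sd) ** 2))
        if d <= best_d:
            best, best_d = spec.label, d
    return ClassCall(best, method=method,
                     aux={"n_segments": n_segments,
                          "mean_segment_cm": mean_segment_cm})


def consensus_classify(calls, k_required: int, method: str = "consensus") -> ClassCall:
    """Modal class over the given calls, if supported by >= k_required.

    INCONCLUSIVE inputs never count toward agreement; among equally frequent
    classes the more distant one wins.
    """
    calls = list(calls)
    if not 2 <= k_required <= len(calls):
        raise ValueError("k_required must be between 2 and the number of calls")
    votes: dict = {}
    for c in calls:
        if c.label != INCONCLUSIVE:
            votes[c.label] = votes.get(c.label, 0) + 1
    best, best_n = INCONCLUSIVE, 0
    for spec in CLASSES:
        n = votes.get(spec.label, 0)
        if n >= best_n and n > 0:
            best, best_n = spec.label, n
    if best_n < k_required:
        best = INCONCLUSIVE
    return ClassCall(best, method=method, aux={"votes": votes})


@dataclass(frozen=True)
class ClassRateMatrix:
    """Per-(true class x predicted class) counts and row-normalized rates."""

    counts: pd.DataFrame
    rates: pd.DataFrame

    def diagonal_rate(self, label: str) -> float:
        return float(self.rates.loc[label, label])


def classification_matrix(truths, calls) -> ClassRateMatrix:
    """Tally predicted-class rates per true class.

    ``truths`` holds true class labels (or RelationshipSpecs), ``calls``
    the corresponding :class:`ClassCall` objects (or labels).
    """
    t_labels = [getattr(t, "label", t) for t in truths]
    c_labels = [getattr(c, "label", c) for c in calls]
    if len(t_labels) != len(c_labels):
        raise ValueError("truths and calls must have equal length")
    cols = list(CLASS_LABELS) + [INCONCLUSIVE]
    rows = sorted(set(t_labels), key=lambda l: CLASS_LABELS.index(l))
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for t, c in zip(t_labels, c_labels):
        counts.loc[t, c] += 1
    totals = counts.sum(axis=1)
    rates = counts.div(totals.replace(0, 1), axis=0)
    return ClassRateMatrix(counts=counts, rates=rates)


def zero_ibd_fraction(segment_lists, panel) -> float:
    """Fraction of pairs with zero panel markers inside true IBD segments.

    ``segment_lists`` is one list of IBD segments per pair (no length
    cutoff applied).  An empty panel gives 1.0 whenever any pair exists.
    """
    segment_lists = list(segment_lists)
    if not segment_lists:
        raise ValueError("no pairs given")
    cms_all = panel.markers["cm"].to_numpy() if panel.n_markers else np.empty(0)
    n_zero = 0
    for segs in segment_lists:
        covered = 0
        for chrom in {s.chrom for s in segs}:
            idx = panel.chrom_index(chrom)
            if idx.size == 0:
                continue
            cms = cms_all[idx]
            for s in segs:
                if s.chrom != chrom:
                    continue
                covered += int(((cms >= s.start_cm) & (cms <= s.end_cm)).sum())
                if covered:
                    break
            if covered:
                break
        n_zero += covered == 0
    return n_zero / len(segment_lists)
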