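"""End-to-end experiments: simulate pairs, run every method, tally matrices.

This module glues the simulator, the five inference methods and the
classifiers into reproducible experiments.  Every stochastic stage draws
its seed from a single root seed through ``numpy.random.SeedSequence``, so
identical configurations give bit-identical matrices.

The segment detectors are calibrated per panel by a small internal
simulation study (``calibrate_panel``): candidate marker-count thresholds
are scored on calibration pairs simulated once, each with a total-cM bin
table derived from its own observed per-class mean totals, and the value
maximizing mean per-class classification accuracy wins (ties to the more
conservative, larger threshold).  This mirrors how segment thresholds and
cM lookup tables are tuned against panel density in practice; the cheap
density-based defaults remain available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from . import segments as seg
from .classify import (
    classification_matrix,
    cm_classify,
    segment_feature_classify,
)
from .likelihood import lr_classify, lr_classify_batch
from .moments import king_phi, kappa_distance_classify, ml_kappa, phi_threshold_classify
from .relationship import CLASSES, RELATED_CLASSES, ClassCall, get_class
from .segments import SegmentCallParams, WindowParams, total_shared_cm
from .simulate import ErrorModel, inject_errors, simulate_pair, simulate_unrelated_pair

__all__ = [
    "METHODS",
    "classify_pair",
    "classify_pair_all_methods",
    "optimize_min_snps",
    "calibrate_panel",
    "PanelCalibration",
    "panel_method_params",
    "simulate_class_pairs",
    "run_classification_experiment",
    "error_impact_experiment",
    "ExperimentConfig",
    "load_config",
]

#: Method registry keys, in canonical display order.
METHODS = ("segment", "windowed", "king", "lr_linked", "lr_unlinked", "ml_kappa")

#: Methods re-run in the error-impact experiment (the moment and ML
#: estimators are exempt by design).
ERROR_IMPACT_METHODS = ("lr_linked", "windowed", "segment")


def classify_pair(obs, method: str, gmap, freqs=None, seg_params=None,
                  win_params=None, feature_ref=None, seg_cm_means=None,
                  win_cm_means=None) -> ClassCall:
    """Run one inference method plus its default classifier on a pair.

    ``seg_cm_means``/``win_cm_means`` optionally replace the true-sharing
    bin means of the total-cM classifier with calibrated observed-total
    means (see :class:`PanelCalibration`).
    """
    if method == "segment":
        params = seg_params or SegmentCallParams(
            min_snps=seg.default_min_snps(obs.panel)
        )
        called = seg.call_segments(obs, gmap, params)
        return cm_classify(total_shared_cm(called), means=seg_cm_means,
                           method="segment")
    if method == "windowed":
        params = win_params or WindowParams(
            window_size=seg.default_window_size(obs.panel)
        )
        called = seg.windowed_segments(obs, gmap, params)
        return cm_classify(total_shared_cm(called), means=win_cm_means,
                           method="windowed")
    if method == "king":
        return phi_threshold_classify(king_phi(obs))
    if method == "lr_linked":
        return lr_classify(obs, freqs, gmap, mode="linked")
    if method == "lr_unlinked":
        return lr_classify(obs, freqs, mode="unlinked")
    if method == "ml_kappa":
        return kappa_distance_classify(ml_kappa(obs, freqs).kappa_hat)
    if method == "segment_features":
        params = seg_params or SegmentCallParams(
            min_snps=seg.default_min_snps(obs.panel)
        )
        called = seg.call_segments(obs, gmap, params)
        lens = [s.end_cm - s.start_cm for s in called]
        return segment_feature_classify(
            len(lens), float(np.mean(lens)) if lens else 0.0, feature_ref
        )
    raise ValueError(f"unknown method {method!r}")


def classify_pair_all_methods(obs, gmap, freqs=None, methods=METHODS,
                              calibration=None, feature_ref=None) -> dict:
    kw = {}
    if calibration is not None:
        kw = dict(seg_params=calibration.seg_params,
                  win_params=calibration.win_params,
                  seg_cm_means=calibration.seg_cm_means,
                  win_cm_means=calibration.win_cm_means)
    return {
        m: classify_pair(obs, m, gmap, freqs, feature_ref=feature_ref, **kw)
        for m in methods
    }


# ---------------------------------------------------------------------------
# Per-panel segment-caller calibration
# ---------------------------------------------------------------------------

def _ibs0_runs(obs, gmap):
    """Per-chromosome maximal IBS0-free runs as (span_cm, n_markers)."""
    runs = []
    cms_all = obs.panel.markers["cm"].to_numpy()
    for chrom in gmap:
        idx = obs.panel.chrom_index(chrom.id)
        if idx.size == 0:
            continue
        cms = cms_all[idx]
        ga, gb = obs.genotypes_a[idx], obs.genotypes_b[idx]
        ibs0 = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
        breaks = np.flatnonzero(ibs0)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size]])
        for s, e in zip(starts, ends):
            if e - s >= 2:
                runs.append((float(cms[e - 1] - cms[s]), int(e - s)))
    return runs


def _empirical_cm_means(totals_by_class, floor_cm: float = 1.0) -> dict:
    """Per-class mean observed totals, floored so geometric-midpoint bins
    stay well defined when a class shares (or detects) nothing."""
    return {
        label: max(float(np.mean(tots)), floor_cm)
        for label, tots in totals_by_class.items()
    }


def _bin_accuracy(totals_by_class, means) -> float:
    accs = [
        np.mean([cm_classify(t, means=means).label == label for t in tots])
        for label, tots in totals_by_class.items()
    ]
    return float(np.mean(accs))


@dataclass(frozen=True)
class PanelCalibration:
    """Per-panel segment/windowed calibration from simulated pairs.

    A detector reports observed (called) totals, which sit systematically
    below true sharing; classifying them against true-sharing bin means
    penalizes distant classes.  The calibration therefore simulates
    ``n_per_class`` pairs per class once, picks the segment caller's
    marker-count threshold by mean per-class accuracy, and derives each
    detector's total-cM bin table (geometric midpoints) from its own
    observed per-class means -- the same construction as the
    simulation-derived lookup tables used in consumer genealogy.
    """

    seg_params: SegmentCallParams
    win_params: WindowParams
    seg_cm_means: dict
    win_cm_means: dict
    n_per_class: int


def calibrate_panel(panel, gmap, seed=0, n_per_class: int = 60,
                    min_cm: float = 5.0, candidates=None) -> PanelCalibration:
    """Calibrate segment threshold and total-cM bins for one panel.

    Deterministic under ``seed``; every candidate threshold is scored on
    the same simulated calibration pairs (their IBS0-free runs are
    extracted once), each with its own observed-mean bin table.  Ties
    prefer the larger (more conservative) threshold.
    """
    if candidates is None:
        candidates = sorted(
            {16, 24, 32, 40, 48, 56, 64, 72, 80, 96, 112, 128, 160, 192, 256,
             seg.default_min_snps(panel, min_cm)}
        )
    win_params = WindowParams(window_size=seg.default_window_size(panel))
    rng_seq = np.random.SeedSequence([seed, panel.n_markers]).spawn(
        5 * n_per_class
    )
    run_sets = {c.label: [] for c in CLASSES}
    win_totals = {c.label: [] for c in CLASSES}
    i = 0
    for spec in CLASSES:
        for _ in range(n_per_class):
            if spec.label == "Un":
                obs = simulate_unrelated_pair(panel, gmap, rng_seq[i])
            else:
                obs = simulate_pair(spec, panel, gmap, rng_seq[i])
            run_sets[spec.label].append(_ibs0_runs(obs, gmap))
            if panel.n_markers >= win_params.window_size:
                win_totals[spec.label].append(
                    total_shared_cm(
                        seg.windowed_segments(obs, gmap, win_params)
                    )
                )
            else:
                win_totals[spec.label].append(0.0)
            i += 1
    best, best_acc, best_means = candidates[0], -1.0, None
    for cand in candidates:
        totals = {
            label: [
                sum(span for span, n in runs if n >= cand and span >= min_cm)
                for runs in run_sets[label]
            ]
            for label in run_sets
        }
        means = _empirical_cm_means(totals)
        acc = _bin_accuracy(totals, means)
        if acc >= best_acc:
            best, best_acc, best_means = cand, acc, means
    return PanelCalibration(
        seg_params=SegmentCallParams(min_cm=min_cm, min_snps=best),
        win_params=win_params,
        seg_cm_means=best_means,
        win_cm_means=_empirical_cm_means(win_totals),
        n_per_class=n_per_class,
    )


def optimize_min_snps(panel, gmap, seed=0, n_per_class: int = 60,
                      min_cm: float = 5.0, candidates=None) -> int:
    """The calibrated segment-caller marker-count threshold for a panel
    (see :func:`calibrate_panel`)."""
    return calibrate_panel(panel, gmap, seed=seed, n_per_class=n_per_class,
                           min_cm=min_cm, candidates=candidates
                           ).seg_params.min_snps


def panel_method_params(panel, gmap, seed=0, calibrate: bool = True):
    """Per-panel parameters for the two segment detectors.

    With ``calibrate`` (default) runs :func:`calibrate_panel`; otherwise
    falls back to the density formula and the true-sharing bin means.
    """
    if calibrate:
        return calibrate_panel(panel, gmap, seed=seed)
    return PanelCalibration(
        seg_params=SegmentCallParams(min_snps=seg.default_min_snps(panel)),
        win_params=WindowParams(window_size=seg.default_window_size(panel)),
        seg_cm_means=None,
        win_cm_means=None,
        n_per_class=0,
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration for a classification or error-impact experiment."""

    panel_size: int = 9618
    classes: tuple = tuple(c.label for c in RELATED_CLASSES) + ("Un",)
    n_pairs: int = 100
    seed: int = 0
    methods: tuple = METHODS
    calibrate_segments: bool = True
    error_models: tuple = ()
    min_cm: float = 5.0


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ExperimentConfig.__dataclass_fields__:
        if key in raw:
            val = raw[key]
            if key == "error_models":
                val = tuple(ErrorModel(*row) for row in val)
            elif isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
    return ExperimentConfig(**kwargs)


def simulate_class_pairs(spec_label, panel, gmap, n_pairs, seed):
    """Simulate ``n_pairs`` pairs of one class with per-pair child seeds."""
    spec = get_class(spec_label)
    class_idx = [c.label for c in CLASSES].index(spec.label)
    seeds = np.random.SeedSequence([seed, class_idx]).spawn(n_pairs)
    out = []
    for s in seeds:
        if spec.label == "Un":
            out.append(simulate_unrelated_pair(panel, gmap, s))
        else:
            out.append(simulate_pair(spec, panel, gmap, s))
    return out


def run_classification_experiment(config: ExperimentConfig, panel, gmap):
    """Simulate pairs per class and classify with every requested method.

    Returns (matrices, calls): ``matrices`` maps method -> ClassRateMatrix;
    ``calls`` maps method -> (truth labels, ClassCall list) for reuse.
    """
    cal = panel_method_params(
        panel, gmap, seed=config.seed, calibrate=config.calibrate_segments
    )
    truths = []
    per_method: dict = {m: [] for m in config.methods}
    batch_methods = {"lr_linked": "linked", "lr_unlinked": "unlinked"}
    for label in config.classes:
        pairs = simulate_class_pairs(label, panel, gmap, config.n_pairs, config.seed)
        truths.extend([label] * len(pairs))
        for m in config.methods:
            if m in batch_methods:
                per_method[m].extend(
                    lr_classify_batch(pairs, gmap=gmap, mode=batch_methods[m])
                )
            else:
                per_method[m].extend(
                    classify_pair(obs, m, gmap,
                                  seg_params=cal.seg_params,
                                  win_params=cal.win_params,
                                  seg_cm_means=cal.seg_cm_means,
                                  win_cm_means=cal.win_cm_means)
                    for obs in pairs
                )
    matrices = {
        m: classification_matrix(truths, per_method[m]) for m in config.methods
    }
    return matrices, (truths, per_method)


def error_impact_experiment(config: ExperimentConfig, panel, gmap):
    """Re-run error-sensitive methods on the same pairs per error model.

    The design is paired: the same simulated pairs (same seeds) are
    classified once error-free and once after each error model is injected
    into individual A, so matrix differences isolate the error effect.  The
    moment and ML estimators are exempt.
    """
    error_models = config.error_models or (ErrorModel(),)
    methods = tuple(m for m in config.methods if m in ERROR_IMPACT_METHODS)
    cal = panel_method_params(
        panel, gmap, seed=config.seed, calibrate=config.calibrate_segments
    )
    base_pairs = []
    truths = []
    for label in config.classes:
        for obs in simulate_class_pairs(label, panel, gmap, config.n_pairs,
                                        config.seed):
            base_pairs.append(obs)
            truths.append(label)
    results = {}
    err_seeds = np.random.SeedSequence([config.seed, 0x5EED]).spawn(
        len(base_pairs)
    )
    for em in error_models:
        noisy_pairs = [
            obs if em == ErrorModel() else inject_errors(obs, em, es)
            for obs, es in zip(base_pairs, err_seeds)
        ]
        per_method: dict = {}
        for m in methods:
            if m in ("lr_linked", "lr_unlinked"):
                per_method[m] = lr_classify_batch(
                    noisy_pairs, gmap=gmap, mode=m.removeprefix("lr_")
                )
            else:
                per_method[m] = [
                    classify_pair(obs=noisy, method=m, gmap=gmap,
                                  seg_params=cal.seg_params,
                                  win_params=cal.win_params,
                                  seg_cm_means=cal.seg_cm_means,
                                  win_cm_means=cal.win_cm_means)
                    for noisy in noisy_pairs
                ]
        results[em] = {
            m: classification_matrix(truths, per_method[m]) for m in methods
        }
    return results
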