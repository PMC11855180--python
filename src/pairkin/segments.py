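"""IBD segment detection from genotype pairs.

Two detectors are provided.  The plain segment approach calls maximal runs
of consecutive markers with no opposite-homozygote (IBS0) site as
half-identical segments, retained above a minimum genetic length and a
minimum marker count (the marker count guards against chance IBS0-free runs
and must grow with panel density).  The windowed-kinship approach slides a
fixed-size marker window, seeds on the fraction of markers sharing at least
one allele (f), merges overlapping seed windows into superwindows, and
calls a superwindow IBD when its best window-level kinship estimate reaches
the threshold a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentCallParams",
    "WindowParams",
    "CalledSegment",
    "call_segments",
    "windowed_segments",
    "total_shared_cm",
    "default_min_snps",
    "default_window_size",
]


@dataclass(frozen=True)
class SegmentCallParams:
    """Thresholds for the plain segment caller."""

    min_cm: float = 5.0
    min_snps: int = 16

    def __post_init__(self):
        if not self.min_cm > 0:
            raise ValueError("min_cm must be positive")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")


@dataclass(frozen=True)
class WindowParams:
    """Thresholds for the windowed-kinship caller.

    ``window_size``: markers per window; ``f_min``: minimum fraction of
    window markers with at least one shared allele for a seed window;
    ``a_min``: minimum window kinship for an IBD call; ``step``: marker
    offset between successive window starts (None = ``window_size``, i.e.
    non-overlapping consecutive windows; 1 = fully sliding); ``call_rule``:
    how a merged superwindow is tested against ``a_min`` ("max" = largest
    member-window kinship, "pooled" = one kinship over the merged span);
    ``min_cm``: minimum genetic span of a reported superwindow.
    """

    window_size: int = 60
    f_min: float = 0.95
    a_min: float = 0.23
    step: int | None = None
    call_rule: str = "max"
    min_cm: float = 5.0

    def __post_init__(self):
        if self.window_size < 10:
            raise ValueError("window_size must be >= 10")
        if not (0 < self.f_min < 1 and 0 < self.a_min < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.step is not None and self.step < 1:
            raise ValueError("step must be >= 1")
        if self.call_rule not in ("max", "pooled"):
            raise ValueError("call_rule must be 'max' or 'pooled'")

    @property
    def effective_step(self) -> int:
        return self.window_size if self.step is None else self.step


@dataclass(frozen=True)
class CalledSegment:
    """A called IBD segment (genetic coordinates, inner marker span)."""

    chrom: str
    start_cm: float
    end_cm: float
    n_snps: int
    source: str  # "segment" or "windowed"


def total_shared_cm(segments) -> float:
    """Total accumulated shared cM over called segments."""
    return float(sum(s.end_cm - s.start_cm for s in segments))


def default_min_snps(panel, min_cm: float = 5.0) -> int:
    """Density-scaled default for the per-segment marker-count threshold.

    ``max(16, round(0.6 * expected markers in min_cm at mean panel
    density))``; configurable because the optimal value depends on allele
    frequencies as well as density (see ``optimize_min_snps`` in the
    experiment module for a calibrated per-panel choice).
    """
    spans = [
        grp["cm"].max() - grp["cm"].min()
        for _, grp in panel.markers.groupby("chrom", sort=False)
    ]
    genome_cm = float(np.sum(spans))
    if genome_cm <= 0:
        return 16
    density = panel.n_markers / genome_cm
    return max(16, int(round(0.6 * min_cm * density)))


def default_window_size(panel, anchor_markers: int = 9618,
                        anchor_window: int = 60) -> int:
    """Window size scaled proportionally to panel size, clamped to [30, 300].

    Anchored so a ~10,000-marker panel uses a window of 60 markers.
    """
    w = int(round(anchor_window * panel.n_markers / anchor_markers))
    return int(np.clip(w, 30, 300))


def _ibs0_mask(ga, gb):
    return ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))


def call_segments(obs, gmap, params: SegmentCallParams) -> list:
    """Half-identical segment calling with zero IBS0 tolerance.

    Maximal runs of consecutive markers containing no opposite-homozygote
    site; a run's span is the cM distance from its first to its last marker
    and it is retained iff span >= min_cm and marker count >= min_snps.
    """
    out = []
    cms_all = obs.panel.markers["cm"].to_numpy()
    for chrom in gmap:
        idx = obs.panel.chrom_index(chrom.id)
        if idx.size == 0:
            continue
        cms = cms_all[idx]
        ibs0 = _ibs0_mask(obs.genotypes_a[idx], obs.genotypes_b[idx])
        # run boundaries: positions of IBS0 markers split the chromosome
        breaks = np.flatnonzero(ibs0)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size]])  # exclusive of IBS0 site
        for s, e in zip(starts, ends):
            n = e - s
            if n < params.min_snps:
                continue
            span = cms[e - 1] - cms[s]
            if span >= params.min_cm:
                out.append(
                    CalledSegment(chrom.id, float(cms[s]), float(cms[e - 1]),
                                  int(n), "segment")
                )
    return out


def _window_stats(ga, gb, W, step):
    """Sliding-window f and kinship via cumulative sums.

    Returns (start indices, f, a) for windows of W markers at the given
    step; the window kinship uses the robust IBS-based estimator with the
    higher-heterozygosity individual as reference.
    """
    n = len(ga)
    ibs0 = _ibs0_mask(ga, gb).astype(np.int64)
    hh = ((ga == 1) & (gb == 1)).astype(np.int64)
    ha = (ga == 1).astype(np.int64)
    hb = (gb == 1).astype(np.int64)

    def wsum(x):
        c = np.concatenate([[0], np.cumsum(x)])
        return c[W:] - c[:-W]

    s_ibs0, s_hh, s_ha, s_hb = map(wsum, (ibs0, hh, ha, hb))
    starts = np.arange(0, n - W + 1, step)
    s_ibs0, s_hh, s_ha, s_hb = (x[starts] for x in (s_ibs0, s_hh, s_ha, s_hb))
    f = 1.0 - s_ibs0 / W
    nref = np.maximum(s_ha, s_hb)
    noth = np.minimum(s_ha, s_hb)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(
            nref > 0,
            (s_hh - 2 * s_ibs0) / (2 * nref) + 0.5 - (nref + noth) / (4 * nref),
            -np.inf,
        )
    return starts, f, a


def _pooled_kinship(ga, gb):
    """One robust kinship estimate over a marker span (higher-heterozygosity
    reference); -inf when undefined."""
    hh = int(((ga == 1) & (gb == 1)).sum())
    opp = int(_ibs0_mask(ga, gb).sum())
    na, nb = int((ga == 1).sum()), int((gb == 1).sum())
    nref, noth = max(na, nb), min(na, nb)
    if nref == 0:
        return float("-inf")
    return (hh - 2 * opp) / (2 * nref) + 0.5 - (nref + noth) / (4 * nref)


def windowed_segments(obs, gmap, params: WindowParams) -> list:
    """Windowed-kinship IBD calling.

    Windows of ``window_size`` markers are laid out at ``effective_step``
    (non-overlapping by default); windows with f >= f_min are seeds;
    overlapping or adjacent seed windows merge into superwindows; a
    superwindow is called IBD iff its kinship statistic (per ``call_rule``)
    reaches a_min; called superwindows spanning >= min_cm are reported.
    """
    out = []
    W = params.window_size
    cms_all = obs.panel.markers["cm"].to_numpy()
    for chrom in gmap:
        idx = obs.panel.chrom_index(chrom.id)
        if idx.size < W:
            continue
        cms = cms_all[idx]
        ga, gb = obs.genotypes_a[idx], obs.genotypes_b[idx]
        starts, f, a = _window_stats(ga, gb, W, params.effective_step)
        seeds = np.flatnonzero(f >= params.f_min)
        if seeds.size == 0:
            continue
        # coverage of the union of seed windows
        cover = np.zeros(idx.size + 1, dtype=np.int64)
        np.add.at(cover, starts[seeds], 1)
        np.add.at(cover, starts[seeds] + W, -1)
        covered = np.cumsum(cover[:-1]) > 0
        d = np.diff(np.concatenate([[0], covered.astype(np.int8), [0]]))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive
        for rs, re in zip(run_starts, run_ends):
            if params.call_rule == "pooled":
                ok = _pooled_kinship(ga[rs:re], gb[rs:re]) >= params.a_min
            else:
                in_run = seeds[(starts[seeds] >= rs) & (starts[seeds] + W <= re)]
                ok = in_run.size > 0 and a[in_run].max() >= params.a_min
            if not ok:
                continue
            span = cms[re - 1] - cms[rs]
            if span >= params.min_cm:
                out.append(
                    CalledSegment(chrom.id, float(cms[rs]), float(cms[re - 1]),
                                  int(re - rs), "windowed")
                )
    return out
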