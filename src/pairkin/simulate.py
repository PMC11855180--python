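"""Gene-dropping genome simulator for pairs of relatives with true IBD.

Pairs are produced by dropping gametes through the explicit pedigree that
connects them via a common-ancestor couple.  Each transmitted haplotype is a
piecewise mosaic of founder haplotypes; comparing the founder labels of the
pair's four haplotypes yields the true IBD track (level 1 = half-identical,
level 2 = fully identical, possible only for full siblings).  Founder
haplotype alleles are drawn independently per marker from panel frequencies
(linkage equilibrium), so genotypes are consistent with the IBD track by
construction.

Crossovers follow a Haldane (Poisson) model by default; a stationary
gamma-renewal option provides positive interference for sensitivity checks.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace

import numpy as np

from .relationship import RelationshipSpec, build_pedigree, UN

__all__ = [
    "IBDSegment",
    "PairObservation",
    "ErrorModel",
    "ERROR_MODEL_GRID",
    "sample_crossovers",
    "simulate_ibd_track",
    "simulate_pair",
    "simulate_unrelated_pair",
    "inject_errors",
    "true_ibd_stats",
    "TrueIBDStats",
]


@dataclass(frozen=True)
class IBDSegment:
    """A true IBD segment in both genetic and physical coordinates."""

    chrom: str
    start_cm: float
    end_cm: float
    start_bp: float
    end_bp: float
    level: int  # 1 = half-identical, 2 = fully identical

    def __post_init__(self):
        if not self.end_cm > self.start_cm:
            raise ValueError("IBD segment must have end_cm > start_cm")
        if self.level not in (1, 2):
            raise ValueError("IBD level must be 1 or 2")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass(frozen=True)
class ErrorModel:
    """Per-marker genotyping error rates applied to one individual.

    ``rate_hom_to_het``: a homozygote becomes heterozygous;
    ``rate_hom_to_opp``: a homozygote becomes the opposite homozygote;
    ``rate_het_to_hom``: a heterozygote collapses to a homozygote (either
    one with probability 1/2).
    """

    rate_hom_to_het: float = 0.0
    rate_hom_to_opp: float = 0.0
    rate_het_to_hom: float = 0.0

    def __post_init__(self):
        rates = (self.rate_hom_to_het, self.rate_hom_to_opp, self.rate_het_to_hom)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("error rates must lie in [0, 1]")
        if self.rate_hom_to_het + self.rate_hom_to_opp > 1:
            raise ValueError("homozygote error rates must sum to <= 1")


#: Default error-rate grid for sensitivity experiments, as (hom->het,
#: hom->opposite hom, het->hom) per-marker probabilities.
ERROR_MODEL_GRID = (
    ErrorModel(0.02, 0.0, 0.0),
    ErrorModel(0.005, 0.0, 0.0),
    ErrorModel(0.0, 0.0, 0.005),
    ErrorModel(0.0, 0.0, 0.02),
    ErrorModel(0.0, 0.001, 0.0),
    ErrorModel(0.0, 0.01, 0.0),
)


@dataclass(frozen=True)
class PairObservation:
    """Two individuals' genotypes on a panel, plus optional true IBD.

    Genotypes are alt-allele doses in {0, 1, 2}; phased haplotypes are
    retained internally when the observation came from the simulator.
    ``true_ibd`` is None for real data.
    """

    panel: object
    genotypes_a: np.ndarray
    genotypes_b: np.ndarray
    true_ibd: list | None = None
    haplotypes_a: np.ndarray | None = field(default=None, repr=False)
    haplotypes_b: np.ndarray | None = field(default=None, repr=False)
    spec: RelationshipSpec | None = None

    def __post_init__(self):
        ga = np.asarray(self.genotypes_a, dtype=np.int8)
        gb = np.asarray(self.genotypes_b, dtype=np.int8)
        n = self.panel.n_markers if self.panel is not None else len(ga)
        if len(ga) != n or len(gb) != n:
            raise ValueError("genotype vectors must match the panel marker list")
        for g in (ga, gb):
            if g.size and (g.min() < 0 or g.max() > 2):
                raise ValueError("genotype codes must be in {0, 1, 2}")
        object.__setattr__(self, "genotypes_a", ga)
        object.__setattr__(self, "genotypes_b", gb)

    @property
    def n_markers(self) -> int:
        return len(self.genotypes_a)


# ---------------------------------------------------------------------------
# Crossovers and haplotype tracks
# ---------------------------------------------------------------------------

def sample_crossovers(length_cm: float, rng, model: str = "poisson",
                      shape: float = 2.63) -> np.ndarray:
    """Sample ordered crossover positions (cM) along one chromosome.

    ``poisson`` (default): count ~ Poisson(length/100), positions uniform
    (Haldane, no interference).  ``gamma``: stationary gamma-renewal process
    with shape ``shape`` and mean inter-crossover distance 100 cM, giving
    positive crossover interference.
    """
    if not length_cm > 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng(rng)
    if model == "poisson":
        n = rng.poisson(length_cm / 100.0)
        return np.sort(rng.random(n) * length_cm)
    if model == "gamma":
        scale = 100.0 / shape
        # stationary start: burn the renewal process in well before 0
        # (6 mean intervals; the forward-recurrence tail beyond that is
        # negligible for the shapes in use)
        pos = -6.0 * 100.0 + rng.gamma(shape, scale)
        out = []
        while pos < length_cm:
            if pos >= 0:
                out.append(pos)
            pos += rng.gamma(shape, scale)
        return np.asarray(out)
    raise ValueError(f"unknown crossover model {model!r}")


def _slice_track(track, a, b, out):
    """Append the [a, b) portion of ``track`` to ``out`` (list of
    (end_cm, label) segments with implicit start at the previous end)."""
    ends = [seg[0] for seg in track]
    i = bisect_left(ends, a)
    if i < len(track) and ends[i] == a:
        i += 1
    while i < len(track):
        end, lab = track[i]
        e = min(end, b)
        if out and out[-1][1] == lab:
            out[-1] = (e, lab)
        else:
            out.append((e, lab))
        if end >= b:
            break
        i += 1


def _meiosis(rng, hap0, hap1, length_cm, model, shape):
    """Recombine two parental haplotype tracks into one gamete track."""
    xs = sample_crossovers(length_cm, rng, model=model, shape=shape)
    cur = int(rng.integers(2))
    haps = (hap0, hap1)
    if xs.size == 0:
        return list(haps[cur])
    out: list = []
    a = 0.0
    for b in list(xs) + [length_cm]:
        if b > a:
            _slice_track(haps[cur], a, b, out)
            a = b
        cur ^= 1
    return out


def _drop_pair_chrom(rng, ped, length_cm, model, shape):
    """Gene-drop one chromosome; returns the pair's 4 haplotype tracks."""
    labels = ped.founder_labels
    haps = {}
    for i, p in enumerate(ped.parents):
        if p is None:
            haps[i] = (
                [(length_cm, int(labels[i, 0]))],
                [(length_cm, int(labels[i, 1]))],
            )
        else:
            haps[i] = tuple(
                _meiosis(rng, *haps[parent], length_cm, model, shape)
                for parent in p
            )
    ia, ib = ped.pair
    return haps[ia] + haps[ib]


def _ibd_from_tracks(tracks, length_cm):
    """Piecewise IBD level (0/1/2) from the pair's four label tracks.

    Returns a list of (start_cm, end_cm, level) with level >= 1 only.
    """
    ends = np.unique(
        np.concatenate([[seg[0] for seg in t] for t in tracks])
    )
    starts = np.concatenate([[0.0], ends[:-1]])
    mids = (starts + ends) / 2
    lab = np.empty((4, len(ends)), dtype=np.int64)
    for t_idx, t in enumerate(tracks):
        t_ends = np.array([seg[0] for seg in t])
        t_labs = np.array([seg[1] for seg in t])
        lab[t_idx] = t_labs[np.searchsorted(t_ends, mids, side="right").clip(max=len(t) - 1)]
    a0, a1, b0, b1 = lab
    level = ((a0 == b0) | (a0 == b1)).astype(np.int8) + (
        (a1 == b0) | (a1 == b1)
    ).astype(np.int8)
    segs = []
    i = 0
    n = len(ends)
    while i < n:
        j = i
        while j + 1 < n and level[j + 1] == level[i]:
            j += 1
        if level[i] >= 1:
            segs.append((float(starts[i]), float(ends[j]), int(level[i])))
        i = j + 1
    return segs


def simulate_ibd_track(spec: RelationshipSpec, gmap, rng,
                       model: str = "poisson", shape: float = 2.63):
    """Gene-drop a pair and return (tracks, ibd_segments) without genotypes.

    ``tracks`` maps chromosome id -> the pair's four haplotype label tracks;
    ``ibd_segments`` is a list of :class:`IBDSegment`.
    """
    if spec.label == "Un":
        return {}, []
    rng = np.random.default_rng(rng)
    ped = build_pedigree(spec)
    tracks = {}
    segments = []
    for chrom in gmap:
        t = _drop_pair_chrom(rng, ped, chrom.length_cm, model, shape)
        tracks[chrom.id] = t
        for s, e, lev in _ibd_from_tracks(t, chrom.length_cm):
            segments.append(
                IBDSegment(
                    chrom=chrom.id,
                    start_cm=s,
                    end_cm=e,
                    start_bp=float(chrom.cm_to_bp(s)),
                    end_bp=float(chrom.cm_to_bp(e)),
                    level=lev,
                )
            )
    return tracks, segments


def _haplotype_alleles(panel, gmap, tracks, founder_haps):
    """Evaluate the four tracks at panel markers; returns (4, n_markers)."""
    n = panel.n_markers
    out = np.zeros((4, n), dtype=np.int8)
    markers = panel.markers
    for chrom in gmap:
        idx = panel.chrom_index(chrom.id)
        if idx.size == 0:
            continue
        cms = markers["cm"].to_numpy()[idx]
        for h in range(4):
            t = tracks[chrom.id][h]
            t_ends = np.array([seg[0] for seg in t])
            t_labs = np.array([seg[1] for seg in t])
            pos = np.searchsorted(t_ends, cms, side="right").clip(max=len(t) - 1)
            out[h, idx] = founder_haps[t_labs[pos], idx]
    return out


def simulate_pair(spec: RelationshipSpec, panel, gmap, rng,
                  model: str = "poisson", shape: float = 2.63) -> PairObservation:
    """Simulate one related pair on a panel, with true IBD populated.

    Founder haplotypes are i.i.d. Bernoulli(freq) per marker (linkage
    equilibrium); the pair's genotypes are read off the dropped haplotype
    mosaics, so they agree with the true IBD track by construction.
    """
    if spec.label == "Un":
        raise ValueError("use simulate_unrelated_pair for unrelated pairs")
    rng = np.random.default_rng(rng)
    tracks, segments = simulate_ibd_track(spec, gmap, rng, model=model, shape=shape)
    ped = build_pedigree(spec)
    n_labels = 2 * ped.n_founders
    freqs = panel.freqs
    founder_haps = (
        rng.random((n_labels, panel.n_markers)) < freqs[None, :]
    ).astype(np.int8)
    haps = _haplotype_alleles(panel, gmap, tracks, founder_haps)
    return PairObservation(
        panel=panel,
        genotypes_a=haps[0] + haps[1],
        genotypes_b=haps[2] + haps[3],
        true_ibd=segments,
        haplotypes_a=haps[:2],
        haplotypes_b=haps[2:],
        spec=spec,
    )


def simulate_unrelated_pair(panel, gmap=None, rng=None) -> PairObservation:
    """Two independent Hardy-Weinberg genotype draws; empty true IBD."""
    rng = np.random.default_rng(rng)
    freqs = panel.freqs
    haps = (rng.random((4, panel.n_markers)) < freqs[None, :]).astype(np.int8)
    return PairObservation(
        panel=panel,
        genotypes_a=haps[0] + haps[1],
        genotypes_b=haps[2] + haps[3],
        true_ibd=[],
        haplotypes_a=haps[:2],
        haplotypes_b=haps[2:],
        spec=UN,
    )


def inject_errors(obs: PairObservation, em: ErrorModel, rng) -> PairObservation:
    """Mutate individual A's genotypes per-marker independently.

    hom->het replaces one allele; hom->opposite replaces both; het->hom
    collapses to either homozygote with probability 1/2.  The true IBD track
    is left untouched (errors are observational).
    """
    rng = np.random.default_rng(rng)
    g = obs.genotypes_a.copy()
    u = rng.random(g.shape)
    hom = (g == 0) | (g == 2)
    het = g == 1
    to_het = hom & (u < em.rate_hom_to_het)
    to_opp = hom & (u >= em.rate_hom_to_het) & (
        u < em.rate_hom_to_het + em.rate_hom_to_opp
    )
    to_hom = het & (u < em.rate_het_to_hom)
    g[to_het] = 1
    g[to_opp] = 2 - g[to_opp]
    g[to_hom] = 2 * rng.integers(0, 2, size=int(to_hom.sum()), dtype=np.int8)
    return replace(obs, genotypes_a=g, haplotypes_a=None)


# ---------------------------------------------------------------------------
# True-IBD summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueIBDStats:
    total_cm: float
    n_segments: int
    mean_segment_cm: float
    n_panel_snps_in_ibd: int


def _merged_intervals(segments):
    """Union of IBD>=1 intervals per chromosome (half-identical counted
    once): sorted, overlapping/abutting intervals merged."""
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append((s.start_cm, s.end_cm))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for a, b in ivals[1:]:
            if a <= out[-1][1] + 1e-12:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        merged[chrom] = out
    return merged


def true_ibd_stats(obs: PairObservation, min_cm: float = 5.0) -> TrueIBDStats:
    """Summarize the true IBD track of a simulated pair.

    Level-1 and level-2 regions are counted once by cM length (half-identical
    union); merged segments shorter than ``min_cm`` are excluded;
    ``n_panel_snps_in_ibd`` counts panel markers inside retained segments.
    """
    if obs.true_ibd is None:
        raise ValueError("observation has no true IBD track (real data?)")
    merged = _merged_intervals(obs.true_ibd)
    total = 0.0
    n_seg = 0
    n_snps = 0
    markers = obs.panel.markers if obs.panel is not None else None
    for chrom, ivals in merged.items():
        kept = [(a, b) for a, b in ivals if (b - a) >= min_cm]
        n_seg += len(kept)
        total += sum(b - a for a, b in kept)
        if kept and markers is not None:
            idx = obs.panel.chrom_index(chrom)
            if idx.size:
                cms = markers["cm"].to_numpy()[idx]
                for a, b in kept:
                    n_snps += int(((cms >= a) & (cms <= b)).sum())
    mean_seg = total / n_seg if n_seg else 0.0
    return TrueIBDStats(total, n_seg, mean_seg, n_snps)
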