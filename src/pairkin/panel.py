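"""SNP panel definitions and schematic fixture panels.

A :class:`PanelDef` is an ordered marker table (chrom, bp, cM, alt-allele
frequency).  Fixture panels emulate published forensic/genealogy marker sets
by size only: marker positions are uniform over the genetic map and allele
frequencies are drawn from a truncated Beta distribution with the U-shaped
spectrum typical of ascertained SNP-array content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PanelDef",
    "make_fixture_panels",
    "read_panel",
    "write_panel",
    "read_freqs",
    "DEFAULT_PANEL_SIZES",
]

#: Post-filtering autosomal biallelic marker counts of the panels emulated by
#: the fixture generator (Signature, FORCE, Kintelligence, 25K, 95K, GSA).
DEFAULT_PANEL_SIZES = {
    "Signature": 92,
    "FORCE": 4073,
    "Kintelligence": 9618,
    "25K": 17231,
    "95K": 53593,
    "GSA": 142350,
}


@dataclass(frozen=True)
class PanelDef:
    """A SNP panel: name plus an ordered marker table.

    ``markers`` is a DataFrame with columns ``chrom`` (str), ``bp`` (int),
    ``cm`` (float, position within chromosome) and ``freq`` (alt-allele
    frequency in (0, 1)), sorted by (chrom order of first appearance, bp).
    """

    name: str
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        m = self.markers
        required = ["chrom", "bp", "cm", "freq"]
        if list(m.columns[:4]) != required and not set(required).issubset(m.columns):
            raise ValueError(f"panel markers need columns {required}")
        m = m.reset_index(drop=True)
        if not ((m["freq"] > 0) & (m["freq"] < 1)).all():
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for _, grp in m.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing:
                raise ValueError("panel markers must be sorted by (chrom, bp)")
        object.__setattr__(self, "markers", m)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def freqs(self) -> np.ndarray:
        return self.markers["freq"].to_numpy()

    def chrom_index(self, chrom_id) -> np.ndarray:
        """Row indices of markers on one chromosome (contiguous block)."""
        return np.flatnonzero((self.markers["chrom"] == str(chrom_id)).to_numpy())

    def __len__(self):
        return self.n_markers


def _truncated_beta(rng, n, a, b, lo, hi):
    """Inverse-CDF sampling of Beta(a, b) truncated to [lo, hi]."""
    u = rng.random(n)
    flo, fhi = stats.beta.cdf([lo, hi], a, b)
    return stats.beta.ppf(flo + u * (fhi - flo), a, b)


def make_fixture_panel(
    gmap,
    size: int,
    seed,
    name: str = "panel",
    beta_shape=(0.8, 0.8),
    freq_bounds=(0.05, 0.95),
) -> PanelDef:
    """Build one schematic panel of ``size`` markers on ``gmap``.

    Marker genetic positions are i.i.d. uniform over total map length (so
    per-chromosome counts are proportional to chromosome cM length);
    frequencies are truncated-Beta draws.  Deterministic under ``seed``.
    """
    if size < 1:
        raise ValueError("panel size must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length_cm for c in gmap])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    pos = np.sort(rng.random(size) * cum[-1])
    chrom_idx = np.clip(np.searchsorted(cum, pos, side="right") - 1, 0, len(gmap) - 1)
    within_cm = pos - cum[chrom_idx]
    freqs = _truncated_beta(rng, size, *beta_shape, *freq_bounds)

    rows = []
    for i, c in enumerate(gmap):
        sel = chrom_idx == i
        if not sel.any():
            continue
        cms = within_cm[sel]
        bps = np.round(c.cm_to_bp(cms)).astype(np.int64)
        rows.append(
            pd.DataFrame(
                {"chrom": c.id, "bp": bps, "cm": cms, "freq": freqs[sel]}
            )
        )
    markers = pd.concat(rows, ignore_index=True)
    return PanelDef(name=name, markers=markers)


def make_fixture_panels(gmap, sizes, seed, names=None) -> list:
    """Build several fixture panels; each size gets an independent stream."""
    ss = np.random.SeedSequence(seed).spawn(len(list(sizes)))
    sizes = list(sizes)
    if names is None:
        names = [f"panel{s}" for s in sizes]
    return [
        make_fixture_panel(gmap, int(size), child, name=name)
        for size, child, name in zip(sizes, ss, names)
    ]


def write_panel(panel: PanelDef, path) -> None:
    """Write a panel as a TSV with columns chrom, bp, cM, alt_freq."""
    df = panel.markers.rename(columns={"cm": "cM", "freq": "alt_freq"})
    df.to_csv(path, sep="\t", index=False)


def read_panel(path, name=None) -> PanelDef:
    """Read a panel TSV (chrom, bp, cM, alt_freq); validates sort order and
    frequency range."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "bp", "cM", "alt_freq"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(required)}")
    bad = df[(df["alt_freq"] <= 0) | (df["alt_freq"] >= 1)]
    if len(bad):
        raise ValueError(
            f"panel file: frequency outside (0,1) at line {bad.index[0] + 2}"
        )
    for chrom_id, grp in df.groupby("chrom", sort=False):
        if not grp["bp"].is_monotonic_increasing:
            raise ValueError(f"panel file: unsorted bp on chromosome {chrom_id}")
    df = df.rename(columns={"cM": "cm", "alt_freq": "freq"})
    df["chrom"] = df["chrom"].astype(str)
    return PanelDef(name=name or str(path), markers=df)


def read_freqs(path) -> pd.DataFrame:
    """Read a frequency table TSV (chrom, bp, alt_freq), validated."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "bp", "alt_freq"}
    if not required.issubset(df.columns):
        raise ValueError(f"frequency file must have columns {sorted(required)}")
    bad = df[(df["alt_freq"] <= 0) | (df["alt_freq"] >= 1)]
    if len(bad):
        raise ValueError(
            f"frequency file: frequency outside (0,1) at line {bad.index[0] + 2}"
        )
    df["chrom"] = df["chrom"].astype(str)
    return df
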