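"""Genetic maps: piecewise-linear bp <-> cM coordinate systems per autosome.

A :class:`GeneticMap` holds, per chromosome, a set of strictly increasing
(bp, cM) anchor points between which genetic position is interpolated
linearly.  The default map is schematic: 22 autosomes whose sex-averaged
genetic lengths follow a deCODE-like relative profile, rescaled to a
configurable total (3280 cM by default), with physical coordinates laid out
at a constant 1 Mb per cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GeneticMap",
    "build_default_map",
    "read_map",
    "write_map",
    "DEFAULT_TOTAL_CM",
]

# Relative sex-averaged autosome genetic lengths (cM), deCODE-like profile.
# Only the proportions matter; build_default_map rescales to the requested total.
_CHROM_CM_PROFILE = np.array(
    [
        286.3, 268.6, 223.2, 214.5, 204.1, 192.0, 187.2, 168.0, 166.4, 181.1,
        158.2, 174.7, 125.9, 120.8, 141.9, 134.0, 128.5, 117.5, 107.0, 108.3,
        62.8, 74.1,
    ]
)

#: Default total sex-averaged autosomal map length in cM.  Chosen so that the
#: expected half-or-fully identical fraction of a full-sibling pair (3/4)
#: corresponds to 2460 cM of expected sharing.
DEFAULT_TOTAL_CM = 3280.0


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of a genetic map.

    Parameters
    ----------
    id : str
        Chromosome name (e.g. ``"1"``).
    bp : ndarray
        Anchor physical positions (1-based), strictly increasing.
    cm : ndarray
        Anchor genetic positions in cM, strictly increasing, ``cm[0] == 0``.
    """

    id: str
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError(f"chromosome {self.id}: need >=2 (bp, cM) anchors")
        if not (np.all(np.diff(bp) > 0) and np.all(np.diff(cm) > 0)):
            raise ValueError(
                f"chromosome {self.id}: anchors must be strictly increasing in bp and cM"
            )

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    @property
    def length_bp(self) -> float:
        return float(self.bp[-1])

    def bp_to_cm(self, bp) -> np.ndarray:
        """Interpolate genetic position (cM) at physical position(s)."""
        return np.interp(bp, self.bp, self.cm)

    def cm_to_bp(self, cm) -> np.ndarray:
        """Interpolate physical position at genetic position(s) in cM."""
        return np.interp(cm, self.cm, self.bp)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of :class:`Chromosome` coordinate systems."""

    chromosomes: tuple

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids in map")

    @property
    def total_cm(self) -> float:
        """Total map length: sum of per-chromosome terminal cM values."""
        return float(sum(c.length_cm for c in self.chromosomes))

    @property
    def chrom_ids(self) -> list:
        return [c.id for c in self.chromosomes]

    def chrom(self, chrom_id) -> Chromosome:
        for c in self.chromosomes:
            if c.id == str(chrom_id):
                return c
        raise KeyError(f"chromosome {chrom_id!r} not in map")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)


def build_default_map(
    n_chrom: int = 22,
    total_cm: float = DEFAULT_TOTAL_CM,
    bp_per_cm: float = 1_000_000.0,
) -> GeneticMap:
    """Build the schematic default map.

    ``n_chrom`` autosomes receive cM lengths proportional to the bundled
    deCODE-like profile (its first ``n_chrom`` entries), rescaled to sum to
    ``total_cm``; physical positions run at a constant ``bp_per_cm``.
    """
    if n_chrom < 1 or n_chrom > len(_CHROM_CM_PROFILE):
        raise ValueError(f"n_chrom must be in 1..{len(_CHROM_CM_PROFILE)}")
    if not total_cm > 0:
        raise ValueError("total_cm must be positive")
    profile = _CHROM_CM_PROFILE[:n_chrom]
    lengths = profile * (total_cm / profile.sum())
    chroms = []
    for i, L in enumerate(lengths):
        chroms.append(
            Chromosome(
                id=str(i + 1),
                bp=np.array([1.0, L * bp_per_cm]),
                cm=np.array([0.0, L]),
            )
        )
    return GeneticMap(tuple(chroms))


def write_map(gmap: GeneticMap, path) -> None:
    """Write a map as a TSV with columns chrom, bp, cM (anchor rows)."""
    rows = []
    for c in gmap:
        for bp, cm in zip(c.bp, c.cm):
            rows.append((c.id, int(round(bp)), cm))
    pd.DataFrame(rows, columns=["chrom", "bp", "cM"]).to_csv(
        path, sep="\t", index=False
    )


def read_map(path) -> GeneticMap:
    """Read a TSV map file (columns chrom, bp, cM) into a :class:`GeneticMap`.

    Raises ``ValueError`` naming the offending chromosome if anchors are not
    strictly increasing.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    chroms = []
    for chrom_id, grp in df.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy(dtype=float)
        cm = grp["cM"].to_numpy(dtype=float)
        if not (np.all(np.diff(bp) > 0) and np.all(np.diff(cm) > 0)):
            raise ValueError(
                f"map file: non-monotone anchors on chromosome {chrom_id}"
            )
        cm = cm - cm[0]
        chroms.append(Chromosome(id=str(chrom_id), bp=bp, cm=cm))
    return GeneticMap(tuple(chroms))
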