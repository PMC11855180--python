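"""Readers and writers for the formats the pipeline touches.

Simulated pairs are written as minimal VCF 4.2 with phased GT fields plus a
sidecar true-IBD TSV; real data come back in through ``read_vcf_pair``
(cyvcf2), aligned to a panel by (chrom, pos), with multi-allelic records
skipped and missing genotypes excluded.  A :class:`RunManifest` records the
seeds and input/output digests of a pipeline run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import IBDSegment, PairObservation

__all__ = [
    "write_pair_vcf",
    "read_vcf_pair",
    "write_ibd_table",
    "read_ibd_table",
    "RunManifest",
]


def _phase(g, haps, i):
    """Phased allele pair for marker i: real phase when available, else a
    canonical ordering of the dose."""
    if haps is not None:
        return int(haps[0, i]), int(haps[1, i])
    return (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))


def write_pair_vcf(obs: PairObservation, path, gmap=None,
                   sample_a: str = "A", sample_b: str = "B") -> None:
    """Write a pair as minimal VCF 4.2 with phased GT and AF INFO."""
    m = obs.panel.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gmap is not None:
            for c in gmap:
                fh.write(f"##contig=<ID={c.id},length={int(c.length_bp)}>\n")
        else:
            for chrom in m["chrom"].unique():
                length = int(m.loc[m["chrom"] == chrom, "bp"].max()) + 1
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_a}\t{sample_b}\n"
        )
        chroms = m["chrom"].to_numpy()
        bps = m["bp"].to_numpy()
        freqs = m["freq"].to_numpy()
        for i in range(obs.n_markers):
            a0, a1 = _phase(obs.genotypes_a[i], obs.haplotypes_a, i)
            b0, b1 = _phase(obs.genotypes_b[i], obs.haplotypes_b, i)
            fh.write(
                f"{chroms[i]}\t{int(bps[i])}\tm{i}\tA\tG\t.\tPASS\t"
                f"AF={freqs[i]:.6f}\tGT\t{a0}|{a1}\t{b0}|{b1}\n"
            )


def read_vcf_pair(path, sample_a: str, sample_b: str, panel) -> PairObservation:
    """Read two samples' genotypes from a VCF, aligned to panel markers.

    Multi-allelic records are skipped; markers missing from the VCF or with
    missing genotypes are excluded (the observation is restricted to the
    matched subset of the panel).  Raises if a sample is absent or if no
    marker overlaps the panel.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    for s in (sample_a, sample_b):
        if s not in samples:
            raise ValueError(f"sample {s!r} not present in {path}")
    ia, ib = samples.index(sample_a), samples.index(sample_b)
    wanted = {
        (str(c), int(b)): i
        for i, (c, b) in enumerate(
            zip(panel.markers["chrom"], panel.markers["bp"])
        )
    }
    n_multiallelic = 0
    got: dict = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        key = (str(rec.CHROM), int(rec.POS))
        if key not in wanted:
            continue
        g = rec.genotypes
        pa, pb = g[ia], g[ib]
        if min(pa[0], pa[1], pb[0], pb[1]) < 0:  # missing genotype
            continue
        got[wanted[key]] = (pa[0] + pa[1], pb[0] + pb[1])
    if not got:
        raise ValueError("no VCF record overlaps the panel markers")
    idx = np.array(sorted(got), dtype=int)
    sub = panel.markers.iloc[idx].reset_index(drop=True)
    sub_panel = type(panel)(name=f"{panel.name}|{path}", markers=sub)
    ga = np.array([got[i][0] for i in idx], dtype=np.int8)
    gb = np.array([got[i][1] for i in idx], dtype=np.int8)
    obs = PairObservation(panel=sub_panel, genotypes_a=ga, genotypes_b=gb,
                          true_ibd=None)
    object.__setattr__(obs, "n_multiallelic_skipped", n_multiallelic)
    return obs


def write_ibd_table(segment_lists, path, pair_ids=None) -> None:
    """Write true-IBD tracks as a TSV: pair_id, chrom, start/end bp & cM, level."""
    rows = []
    for j, segs in enumerate(segment_lists):
        pid = pair_ids[j] if pair_ids is not None else f"pair{j}"
        for s in segs:
            rows.append(
                (pid, s.chrom, int(s.start_bp), int(s.end_bp),
                 s.start_cm, s.end_cm, s.level)
            )
    pd.DataFrame(
        rows,
        columns=["pair_id", "chrom", "start_bp", "end_bp",
                 "start_cm", "end_cm", "level"],
    ).to_csv(path, sep="\t", index=False)


def read_ibd_table(path) -> dict:
    """Read a true-IBD TSV back into pair_id -> list of IBDSegment."""
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.pair_id, []).append(
            IBDSegment(
                chrom=str(row.chrom), start_cm=row.start_cm, end_cm=row.end_cm,
                start_bp=row.start_bp, end_bp=row.end_bp, level=int(row.level),
            )
        )
    return out


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, file digests."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""
    digests: dict = field(default_factory=dict)

    def record_seed(self, stage: str, seed) -> None:
        self.seeds[stage] = int(seed) if np.isscalar(seed) else str(seed)

    def record_file(self, role: str, path) -> None:
        self.digests[role] = {"path": str(path), "sha256": _digest(path)}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "seeds": self.seeds,
                 "version": self.version, "digests": self.digests},
                fh, indent=2, sort_keys=True,
            )
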