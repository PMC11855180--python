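"""Relationship classes, pairwise pedigrees and single-locus IBD machinery.

The five classes studied are full siblings (S1, 1st degree), first cousins
(S2, 3rd), second cousins (S3, 5th), third cousins (S4, 7th) and unrelated
(Un).  Each related class connects the pair through a common-ancestor
couple; ``kappa = (k0, k1, k2)`` are the Cotterman coefficients -- the
probabilities that the pair shares 0, 1 or 2 alleles identical by descent at
a locus.  ``RelationshipSpec.kappa`` always holds the closed-form pedigree
values; a separate table of published reference vectors (one of which is
internally inconsistent but used verbatim by the kappa-distance classifier)
is exported as :data:`REPORTED_KAPPA`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RelationshipSpec",
    "ClassCall",
    "S1",
    "S2",
    "S3",
    "S4",
    "UN",
    "CLASSES",
    "RELATED_CLASSES",
    "CLASS_LABELS",
    "INCONCLUSIVE",
    "REPORTED_KAPPA",
    "kinship_coefficient",
    "build_pedigree",
    "exact_ibd_distribution",
    "sample_locus_ibd",
    "get_class",
]

INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class RelationshipSpec:
    """A pairwise relationship hypothesis.

    ``meioses`` is the number of meioses separating the pair along one path
    through the common-ancestor couple (full siblings: 2 per parental
    lineage; first/second/third cousins: 4/6/8).
    """

    label: str
    degree: int | None
    kappa: tuple
    meioses: int
    n_common_ancestors: int

    def __post_init__(self):
        k = tuple(float(x) for x in self.kappa)
        if len(k) != 3 or abs(sum(k) - 1.0) > 1e-12 or any(x < 0 for x in k):
            raise ValueError("kappa must be three non-negative values summing to 1")
        object.__setattr__(self, "kappa", k)

    @property
    def phi(self) -> float:
        """Kinship coefficient: kappa1/4 + kappa2/2."""
        return self.kappa[1] / 4 + self.kappa[2] / 2


S1 = RelationshipSpec("S1", 1, (0.25, 0.5, 0.25), 2, 2)
S2 = RelationshipSpec("S2", 3, (0.75, 0.25, 0.0), 4, 2)
S3 = RelationshipSpec("S3", 5, (0.9375, 0.0625, 0.0), 6, 2)
S4 = RelationshipSpec("S4", 7, (1 - 1 / 64, 1 / 64, 0.0), 8, 2)
UN = RelationshipSpec("Un", None, (1.0, 0.0, 0.0), 0, 0)

#: Ordered from closest to most distant; ties in classifiers break toward
#: the later (more distant) entry.
CLASSES = (S1, S2, S3, S4, UN)
RELATED_CLASSES = (S1, S2, S3, S4)
CLASS_LABELS = tuple(c.label for c in CLASSES)

#: Published reference kappa vectors used verbatim by the kappa-distance
#: classifier.  Note the third-cousin vector (0.97, 0.0312, 0) does not match
#: the closed-form (63/64, 1/64, 0) and does not sum to 1; it is kept as
#: printed for comparability.
REPORTED_KAPPA = {
    "S1": (0.25, 0.5, 0.25),
    "S2": (0.75, 0.25, 0.0),
    "S3": (0.9375, 0.0625, 0.0),
    "S4": (0.97, 0.0312, 0.0),
    "Un": (1.0, 0.0, 0.0),
}


def get_class(label: str) -> RelationshipSpec:
    for c in CLASSES:
        if c.label == label:
            return c
    raise KeyError(f"unknown relationship class {label!r}")


def kinship_coefficient(kappa) -> float:
    """phi = kappa1/4 + kappa2/2 for an outbred pair."""
    return kappa[1] / 4 + kappa[2] / 2


@dataclass(frozen=True)
class ClassCall:
    """A predicted relationship class from one method.

    ``label`` is one of S1..S4, Un, or INCONCLUSIVE; ``aux`` carries the raw
    statistic behind the call (phi-hat, total cM, log-likelihoods, ...).
    """

    label: str
    method: str = ""
    aux: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.label not in CLASS_LABELS + (INCONCLUSIVE,):
            raise ValueError(f"invalid class label {self.label!r}")

    @property
    def class_id(self):
        """1..5 for S1..Un (5 = unrelated), None if inconclusive."""
        if self.label == INCONCLUSIVE:
            return None
        return CLASS_LABELS.index(self.label) + 1


# ---------------------------------------------------------------------------
# Pairwise pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pedigree:
    """A pairwise pedigree: ``parents[i]`` is None for founders, else a
    (mother_idx, father_idx) tuple; ``pair`` holds the two target indices.

    Founder ``i`` (i-th None entry) carries haplotype labels (2i, 2i+1).
    """

    parents: tuple
    pair: tuple

    @property
    def n_founders(self) -> int:
        return sum(1 for p in self.parents if p is None)

    @property
    def founder_labels(self) -> np.ndarray:
        """Per-individual haplotype label pairs; -1 for non-founders."""
        out = np.full((len(self.parents), 2), -1, dtype=int)
        f = 0
        for i, p in enumerate(self.parents):
            if p is None:
                out[i] = (2 * f, 2 * f + 1)
                f += 1
        return out


def build_pedigree(spec: RelationshipSpec) -> Pedigree:
    """Explicit pedigree connecting the pair through a common-ancestor couple.

    S1: two children of one founder couple.  S2..S4: the two siblings each
    marry an unrelated founder, repeated for 1..3 further generations.
    """
    if spec.label == "Un":
        return Pedigree(parents=(None, None), pair=(0, 1))
    if spec.label not in {"S1", "S2", "S3", "S4"}:
        raise ValueError(f"no pedigree defined for {spec.label!r}")
    parents: list = [None, None]  # common-ancestor couple
    a, b = len(parents), len(parents) + 1
    parents += [(0, 1), (0, 1)]  # the two siblings
    n_extra = spec.meioses // 2 - 1  # generations below the siblings
    for _ in range(n_extra):
        sa = len(parents); parents.append(None)
        sb = len(parents); parents.append(None)
        na = len(parents); parents.append((a, sa))
        nb = len(parents); parents.append((b, sb))
        a, b = na, nb
    return Pedigree(parents=tuple(parents), pair=(a, b))


def _propagate(ped: Pedigree, bits: np.ndarray) -> np.ndarray:
    """Drop founder haplotype labels through the pedigree at one locus.

    ``bits`` has shape (n_meioses, n); bit ``m`` selects which of the
    parent's two haplotypes meiosis ``m`` transmits, for each of n
    replicates.  Returns IBD state (0/1/2) per replicate for the pair.
    """
    labels = ped.founder_labels
    n = bits.shape[1]
    haps = {}
    for i, p in enumerate(ped.parents):
        if p is None:
            haps[i] = (
                np.full(n, labels[i, 0]),
                np.full(n, labels[i, 1]),
            )
    m = 0
    for i, p in enumerate(ped.parents):
        if p is None:
            continue
        transmitted = []
        for parent in p:
            h0, h1 = haps[parent]
            transmitted.append(np.where(bits[m], h1, h0))
            m += 1
        haps[i] = tuple(transmitted)
    ia, ib = ped.pair
    a0, a1 = haps[ia]
    b0, b1 = haps[ib]
    # labels are distinct within each individual, so the size of the
    # bipartite matching is the size of the set intersection
    ibd = ((a0 == b0) | (a0 == b1)).astype(np.int8) + (
        (a1 == b0) | (a1 == b1)
    ).astype(np.int8)
    return ibd


def exact_ibd_distribution(spec: RelationshipSpec) -> tuple:
    """Exact locus-wise (k0, k1, k2) by exhaustive enumeration of all
    inheritance vectors through the pedigree.

    Each non-founder meiosis contributes one binary choice; all 2^m choices
    are enumerated, so the result is exact (probabilities are dyadic).
    """
    ped = build_pedigree(spec)
    n_meioses = 2 * sum(1 for p in ped.parents if p is not None)
    if n_meioses == 0:
        return (1.0, 0.0, 0.0)
    n = 1 << n_meioses
    idx = np.arange(n, dtype=np.uint32)
    bits = np.stack([(idx >> m) & 1 for m in range(n_meioses)]).astype(bool)
    ibd = _propagate(ped, bits)
    counts = np.bincount(ibd, minlength=3)
    return tuple(counts / n)


def sample_locus_ibd(spec: RelationshipSpec, n: int, rng) -> np.ndarray:
    """Gene-drop ``n`` independent replicate loci; returns IBD states (0/1/2).

    A Monte-Carlo counterpart of :func:`exact_ibd_distribution` drawing each
    meiosis's transmission uniformly at random.
    """
    rng = np.random.default_rng(rng)
    ped = build_pedigree(spec)
    n_meioses = 2 * sum(1 for p in ped.parents if p is not None)
    if n_meioses == 0:
        return np.zeros(n, dtype=np.int8)
    bits = rng.integers(0, 2, size=(n_meioses, n), dtype=np.int8).astype(bool)
    return _propagate(ped, bits)
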