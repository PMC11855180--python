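"""Moment and maximum-likelihood point estimators of pairwise relatedness.

Implements the robust kinship estimator built from identity-by-state counts
(heterozygote concordance and opposite homozygotes), an EM maximum-
likelihood estimator of the three Cotterman coefficients under the
composite (linkage-free) likelihood, and the threshold / nearest-centroid
classifiers that map these statistics to relationship classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import genotype_pair_tables
from .relationship import CLASSES, ClassCall, REPORTED_KAPPA

__all__ = [
    "IBSCounts",
    "KappaEstimate",
    "ibs_counts",
    "king_robust_phi",
    "king_phi",
    "ml_kappa",
    "phi_threshold_classify",
    "kappa_distance_classify",
    "PHI_CLASS_BOUNDS",
]


@dataclass(frozen=True)
class IBSCounts:
    """IBS count summary for a pair of genotype vectors.

    ``n_het_het``: markers where both are heterozygous; ``n_opp_hom``:
    opposite homozygotes; ``n_het_a``/``n_het_b``: per-individual
    heterozygote counts; ``n_markers``: markers tallied.
    """

    n_het_het: int
    n_opp_hom: int
    n_het_a: int
    n_het_b: int
    n_markers: int

    def __post_init__(self):
        c = (self.n_het_het, self.n_opp_hom, self.n_het_a, self.n_het_b)
        if any(x < 0 for x in c) or max(c) > self.n_markers:
            raise ValueError("inconsistent IBS counts")
        if self.n_het_het > min(self.n_het_a, self.n_het_b):
            raise ValueError("n_het_het cannot exceed either heterozygote count")


def ibs_counts(obs) -> IBSCounts:
    """Exact IBS tallies over the observation's markers."""
    ga, gb = obs.genotypes_a, obs.genotypes_b
    het_a = ga == 1
    het_b = gb == 1
    opp = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
    return IBSCounts(
        n_het_het=int((het_a & het_b).sum()),
        n_opp_hom=int(opp.sum()),
        n_het_a=int(het_a.sum()),
        n_het_b=int(het_b.sum()),
        n_markers=len(ga),
    )


def king_robust_phi(counts: IBSCounts) -> float:
    """Robust kinship estimate with individual A as the reference.

    phi-hat = (N_AaAa - 2 N_AAaa) / (2 N_Aa^(a))
              + 1/2 - (N_Aa^(a) + N_Aa^(b)) / (4 N_Aa^(a)).

    Which individual serves as reference is the caller's choice (see
    :func:`king_phi` for the heterozygosity convention); raises if the
    reference individual has no heterozygous markers.
    """
    if counts.n_het_a <= 0:
        raise ValueError("kinship undefined: reference individual has no heterozygotes")
    na, nb = counts.n_het_a, counts.n_het_b
    return (
        (counts.n_het_het - 2 * counts.n_opp_hom) / (2 * na)
        + 0.5
        - (na + nb) / (4 * na)
    )


def king_phi(obs, reference: str = "higher") -> float:
    """Robust kinship for a pair, resolving the reference individual.

    ``reference`` chooses which individual's heterozygote count enters the
    denominator: ``"higher"`` (default) uses the individual with the larger
    heterozygote count, ``"lower"`` the other convention, ``"a"`` uses
    individual A as given.
    """
    c = ibs_counts(obs)
    if reference not in ("higher", "lower", "a"):
        raise ValueError("reference must be 'higher', 'lower' or 'a'")
    swap = (reference == "higher" and c.n_het_b > c.n_het_a) or (
        reference == "lower" and c.n_het_b < c.n_het_a
    )
    if swap:
        c = IBSCounts(c.n_het_het, c.n_opp_hom, c.n_het_b, c.n_het_a, c.n_markers)
    return king_robust_phi(c)


@dataclass(frozen=True)
class KappaEstimate:
    """ML estimate of the Cotterman coefficients for one pair."""

    kappa_hat: tuple
    loglik: float
    n_markers: int
    converged: bool = True
    n_iter: int = 0


def ml_kappa(obs, freqs=None, max_iter: int = 500, tol: float = 1e-8) -> KappaEstimate:
    """Maximum-likelihood (k0, k1, k2) on the simplex via EM.

    Maximizes the composite log-likelihood sum_m log sum_k k_k P(ga, gb |
    k, p_m); the E-step computes the per-marker posterior over the IBD
    level, the M-step averages it.  Stops at relative log-likelihood change
    below ``tol`` or ``max_iter`` iterations (non-convergence is reported on
    the estimate, with the last iterate).
    """
    freqs = obs.panel.freqs if freqs is None else np.asarray(freqs, dtype=float)
    if len(freqs) < 2:
        raise ValueError("need at least 2 markers")
    T = genotype_pair_tables(freqs)
    combo = 3 * obs.genotypes_a.astype(np.int64) + obs.genotypes_b
    P = T[np.arange(len(combo)), combo, :]  # (M, 3)
    kappa = np.full(3, 1.0 / 3.0)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = P @ kappa
        mix = np.maximum(mix, 1e-300)
        ll = float(np.log(mix).sum())
        post = P * kappa[None, :] / mix[:, None]
        kappa = post.mean(axis=0)
        kappa = np.maximum(kappa, 0.0)
        kappa /= kappa.sum()
        if ll - ll_prev <= tol * (abs(ll) + 1.0) and it > 1:
            converged = True
            break
        ll_prev = ll
    return KappaEstimate(
        kappa_hat=tuple(kappa),
        loglik=float(np.log(np.maximum(P @ kappa, 1e-300)).sum()),
        n_markers=len(combo),
        converged=converged,
        n_iter=it,
    )


# Geometric-midpoint bin boundaries between expected kinship values per
# class: 2^(-3), 2^(-5), 2^(-7), 2^(-9).  Values at a boundary fall to the
# more distant class.
PHI_CLASS_BOUNDS = (0.125, 0.03125, 0.0078125, 0.001953125)


def phi_threshold_classify(phi_hat: float, method: str = "king") -> ClassCall:
    """Degree bins around expected kinship per class (0.25, 0.0625, ...)."""
    for spec, bound in zip(CLASSES[:4], PHI_CLASS_BOUNDS):
        if phi_hat > bound:
            return ClassCall(spec.label, method=method, aux={"phi_hat": phi_hat})
    return ClassCall("Un", method=method, aux={"phi_hat": phi_hat})


def kappa_distance_classify(kappa_hat, reference=None,
                            method: str = "ml_kappa") -> ClassCall:
    """Nearest reference kappa vector by Euclidean distance.

    ``reference`` maps class labels to (k0, k1, k2); by default the
    published reference vectors (:data:`REPORTED_KAPPA`) are used verbatim.
    Ties break toward the more distant class.
    """
    reference = REPORTED_KAPPA if reference is None else reference
    k = np.asarray(kappa_hat, dtype=float)
    best, best_d = None, np.inf
    for spec in CLASSES:
        d = float(np.sum((k - np.asarray(reference[spec.label])) ** 2))
        if d <= best_d:
            best, best_d = spec.label, d
    return ClassCall(best, method=method,
                     aux={"kappa_hat": tuple(k), "distance_sq": best_d})
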