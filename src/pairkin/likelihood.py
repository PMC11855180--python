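"""Pairwise relationship likelihoods, with and without genetic linkage.

The unlinked (composite) likelihood treats markers as independent and mixes
the conditional genotype-pair probabilities over the Cotterman coefficients.
The linked likelihood runs a forward algorithm over a Markov approximation
of the pairwise IBD process along the genetic map: for unilineal classes a
two-state chain (IBD 0/1) with stationary distribution (k0, k1) and switch
intensity m/100 per cM (m = meioses separating the pair); full siblings are
modelled exactly as two independent per-parent two-state chains (2 meioses
each), whose IBD-count sum gives a three-state chain.  Chromosomes are
independent (the chain restarts at stationarity), and the forward pass is
scaled per marker to avoid underflow.
"""

from __future__ import annotations

import numpy as np

from .relationship import (
    CLASSES,
    ClassCall,
    RelationshipSpec,
    INCONCLUSIVE,
)

__all__ = [
    "genotype_pair_prob",
    "genotype_pair_tables",
    "unlinked_loglik",
    "linked_loglik",
    "lr_classify",
    "ibd_transition_matrix",
]

_LOG10 = np.log(10.0)


def genotype_pair_tables(p) -> np.ndarray:
    """Conditional genotype-pair probability tables P(ga, gb | IBD=k, p).

    ``p`` is an array of alt-allele frequencies of shape (M,); the result has
    shape (M, 9, 3) where axis 1 indexes the genotype pair as 3*ga + gb and
    axis 2 the IBD level k.  For each (marker, k) the 9 entries sum to 1;
    the k=2 slice is diagonal (identical genotypes only).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    q = 1 - p
    g0, g1, g2 = q * q, 2 * p * q, p * p  # Hardy-Weinberg genotype probs
    T = np.zeros((p.size, 9, 3))
    marg = np.stack([g0, g1, g2], axis=1)
    # k = 0: independent genotypes
    T[:, :, 0] = (marg[:, :, None] * marg[:, None, :]).reshape(-1, 9)
    # k = 1: one shared allele plus one random allele each
    k1 = np.stack(
        [
            q ** 3, q * q * p, np.zeros_like(p),
            q * q * p, p * q, p * p * q,
            np.zeros_like(p), p * p * q, p ** 3,
        ],
        axis=1,
    )
    T[:, :, 1] = k1
    # k = 2: identical genotypes
    T[:, 0, 2] = g0
    T[:, 4, 2] = g1
    T[:, 8, 2] = g2
    return T


def genotype_pair_prob(g_a: int, g_b: int, p: float, k: int) -> float:
    """P(g_a, g_b | IBD=k) for one biallelic marker with alt frequency p."""
    for g in (g_a, g_b):
        if g not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {g!r}")
    if k not in (0, 1, 2):
        raise ValueError(f"invalid IBD level {k!r}")
    T = genotype_pair_tables(p)
    return float(T[0, 3 * g_a + g_b, k])


def _pair_probs(obs, freqs):
    """Per-marker (M, 3) conditional probabilities for an observation."""
    freqs = obs.panel.freqs if freqs is None else np.asarray(freqs, dtype=float)
    T = genotype_pair_tables(freqs)
    combo = 3 * obs.genotypes_a.astype(np.int64) + obs.genotypes_b
    return T[np.arange(len(combo)), combo, :]


def unlinked_loglik(obs, freqs=None, kappa=(1.0, 0.0, 0.0)) -> float:
    """Composite log-likelihood treating markers as independent.

    Returns -inf when some marker is impossible under ``kappa`` (e.g.
    opposite homozygotes with kappa = (0, 0, 1)).
    """
    probs = _pair_probs(obs, freqs) @ np.asarray(kappa, dtype=float)
    if np.any(probs <= 0):
        return float("-inf")
    return float(np.log(probs).sum())


def ibd_transition_matrix(spec: RelationshipSpec, d_cm: float) -> np.ndarray:
    """Transition matrix of the IBD chain over ``d_cm`` centiMorgans.

    Unilineal classes: 2x2 over (IBD0, IBD1), P(d) = Pi + exp(-a d)(I - Pi)
    with a = meioses/100 and Pi the rank-one stationary projector.  Full
    siblings: 3x3 over IBD counts, the sum of two independent symmetric
    per-parent chains with flip probability (1 - exp(-4d/100))/2.  Unrelated:
    the degenerate single-state chain (identity).
    """
    if d_cm < 0:
        raise ValueError("distance must be non-negative")
    if spec.label == "Un":
        return np.array([[1.0]])
    if spec.label == "S1":
        phi = 0.5 * (1.0 - np.exp(-4.0 * d_cm / 100.0))  # per-parent flip prob
        s, f = 1 - phi, phi
        return np.array(
            [
                [s * s, 2 * s * f, f * f],
                [s * f, s * s + f * f, s * f],
                [f * f, 2 * s * f, s * s],
            ]
        )
    k0, k1, _ = spec.kappa
    pi = np.array([[k0, k1], [k0, k1]])
    c = np.exp(-spec.meioses / 100.0 * d_cm)
    return pi + c * (np.eye(2) - pi)


def _stationary_and_states(spec):
    if spec.label == "Un":
        return np.array([1.0]), np.array([0])
    if spec.label == "S1":
        return np.array([0.25, 0.5, 0.25]), np.array([0, 1, 2])
    return np.array(spec.kappa[:2]), np.array([0, 1])


def linked_loglik(obs, freqs, gmap, spec: RelationshipSpec) -> float:
    """Forward-algorithm log-likelihood under the linked IBD chain."""
    lls = _linked_loglik_batch(
        obs.genotypes_a[None, :], obs.genotypes_b[None, :], obs.panel,
        freqs, gmap, spec,
    )
    return float(lls[0])


def _linked_loglik_batch(G_a, G_b, panel, freqs, gmap, spec) -> np.ndarray:
    """Vectorized forward pass over many pairs sharing one panel.

    ``G_a``/``G_b`` have shape (P, M).  Returns (P,) log-likelihoods.
    """
    freqs = panel.freqs if freqs is None else np.asarray(freqs, dtype=float)
    T9 = genotype_pair_tables(freqs)  # (M, 9, 3)
    pi, states = _stationary_and_states(spec)
    combo = (3 * G_a.astype(np.int64) + G_b)  # (P, M)
    P = combo.shape[0]
    logl = np.zeros(P)
    cms_all = panel.markers["cm"].to_numpy()
    for chrom in gmap:
        idx = panel.chrom_index(chrom.id)
        if idx.size == 0:
            continue
        cms = cms_all[idx]
        if np.any(np.diff(cms) < 0):
            raise ValueError("panel markers are not sorted along the map")
        trans = [
            ibd_transition_matrix(spec, d) for d in np.diff(cms)
        ]
        emis = T9[idx][:, :, states]  # (m, 9, S)
        f = pi[None, :] * emis[0][combo[:, idx[0]], :]  # (P, S)
        scale = f.sum(axis=1)
        bad = scale <= 0
        scale[bad] = 1.0
        logl += np.where(bad, -np.inf, np.log(scale))
        f /= scale[:, None]
        for j in range(1, idx.size):
            f = (f @ trans[j - 1]) * emis[j][combo[:, idx[j]], :]
            scale = f.sum(axis=1)
            bad = scale <= 0
            scale[bad] = 1.0
            logl += np.where(bad, -np.inf, np.log(scale))
            f /= scale[:, None]
    return logl


def _unlinked_loglik_batch(G_a, G_b, panel, freqs, kappa) -> np.ndarray:
    freqs = panel.freqs if freqs is None else np.asarray(freqs, dtype=float)
    T9 = genotype_pair_tables(freqs)
    combo = 3 * G_a.astype(np.int64) + G_b
    probs = T9[np.arange(T9.shape[0])[None, :], combo, :] @ np.asarray(kappa)
    with np.errstate(divide="ignore"):
        lls = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
    return lls.sum(axis=1)


def lr_classify(obs, freqs=None, gmap=None, mode: str = "linked",
                lr_threshold: float | None = None) -> ClassCall:
    """Maximum-likelihood class over {S1, S2, S3, S4, Un}.

    Ties break toward the more distant class.  If ``lr_threshold`` is given,
    the call is INCONCLUSIVE unless the best class beats the runner-up by a
    likelihood ratio of at least that factor.
    """
    if mode not in ("linked", "unlinked"):
        raise ValueError("mode must be 'linked' or 'unlinked'")
    lls = {}
    for spec in CLASSES:
        if mode == "linked":
            if gmap is None:
                raise ValueError("linked mode requires a genetic map")
            lls[spec.label] = linked_loglik(obs, freqs, gmap, spec)
        else:
            lls[spec.label] = unlinked_loglik(obs, freqs, spec.kappa)
    return _argmax_call(lls, f"lr_{mode}", lr_threshold)


def lr_classify_batch(pairs, freqs=None, gmap=None, mode: str = "linked",
                      lr_threshold: float | None = None) -> list:
    """Vectorized :func:`lr_classify` over pairs sharing one panel."""
    pairs = list(pairs)
    if not pairs:
        return []
    panel = pairs[0].panel
    G_a = np.stack([p.genotypes_a for p in pairs])
    G_b = np.stack([p.genotypes_b for p in pairs])
    lls = {}
    for spec in CLASSES:
        if mode == "linked":
            lls[spec.label] = _linked_loglik_batch(G_a, G_b, panel, freqs,
                                                   gmap, spec)
        elif mode == "unlinked":
            lls[spec.label] = _unlinked_loglik_batch(G_a, G_b, panel, freqs,
                                                     spec.kappa)
        else:
            raise ValueError("mode must be 'linked' or 'unlinked'")
    return [
        _argmax_call({k: float(v[i]) for k, v in lls.items()},
                     f"lr_{mode}", lr_threshold)
        for i in range(len(pairs))
    ]


def _argmax_call(lls: dict, method: str, lr_threshold=None) -> ClassCall:
    best = None
    for spec in CLASSES:  # iteration order: ties go to the later, more
        ll = lls[spec.label]  # distant class via >=
        if best is None or ll >= lls[best]:
            best = spec.label
    if lr_threshold is not None:
        others = [v for k, v in lls.items() if k != best]
        if others and max(others) > lls[best] - np.log(lr_threshold):
            return ClassCall(INCONCLUSIVE, method=method, aux=dict(lls))
    return ClassCall(best, method=method, aux=dict(lls))
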