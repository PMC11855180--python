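# Methods

This note documents the models behind `pairkin`, the defaults that matter,
what the synthetic data do and do not emulate, and the numerical choices a
maintainer would want to know about.

## Relationship classes and pedigrees

Five pairwise classes are modelled: full siblings (S1, 1st degree), first
cousins (S2, 3rd), second cousins (S3, 5th), third cousins (S4, 7th) and
unrelated (Un).  Every related class connects the pair through a
common-ancestor *couple*; half-relationships (single common ancestor) and
inbred pedigrees are out of scope.  `RelationshipSpec.kappa` carries the
closed-form Cotterman coefficients obtained by enumerating inheritance
vectors through the pedigree (`exact_ibd_distribution`, exact because each
of the 2m meiosis choices is binary): S1 (¼, ½, ¼), S2 (¾, ¼, 0),
S3 (15⁄16, 1⁄16, 0), S4 (63⁄64, 1⁄64, 0).  A separate table
`REPORTED_KAPPA` holds the reference vectors used verbatim by the
κ-distance classifier; its third-cousin entry (0.97, 0.0312, 0) is kept
as circulated in forensic practice even though it is internally inconsistent (it
neither sums to 1 nor matches the third-cousin kinship of 1⁄256 ≈ 0.004).
We keep it for comparability and flag it here rather than silently
correcting it; the inconsistency only affects the κ-classifier's
S4-vs-Un boundary, not the estimators.

## Genetic map

The default map has 22 autosomes with sex-averaged lengths proportional to
a deCODE-like profile, rescaled to 3280 cM total, and physical coordinates
at a constant 1 Mb/cM.  The total is chosen so that the expected
half-or-fully-identical sharing of full siblings, ¾ of the map, equals the
reference value of 2460 cM.  Coordinates are 1-based bp; cM positions are
interpolated linearly between anchors; segments are closed intervals in
cM.  Sex-specific recombination is not modelled.

## Simulator

Gametes are dropped through the pedigree per chromosome.  Each transmitted
haplotype is a piecewise mosaic of founder-haplotype labels; the pair's
true IBD track is read off by comparing the four label tracks (level 1 =
half-identical, level 2 = fully identical, which only siblings can reach).
Founder haplotype alleles are drawn i.i.d. per marker from panel
frequencies, i.e. founders are in linkage equilibrium and Hardy–Weinberg
proportions.  This removes any dependence on external reference haplotypes
and makes the likelihood's no-LD assumption exactly true — which also
means the simulation cannot probe LD-induced biases (see Limitations).
Unrelated pairs are independent frequency draws, so "background
relatedness" of a finite population sample is absent by construction and
their true sharing is exactly zero.

Crossovers: Haldane model by default (count ~ Poisson(L/100), positions
uniform).  A stationary gamma-renewal alternative (`model="gamma"`, shape
ν = 2.63, mean spacing 100 cM) supplies positive crossover interference.
Mean segment counts and mean shared cM are insensitive to the choice, but
the *tail* of the segment-count distribution is not: under Haldane the
third-cousin segment count is overdispersed (mean 4.4, variance 5.9) and
~2.4% of third-cousin pairs share nothing, while under interference the
variance tightens and the zero-sharing fraction is ~1.4%, matching the
~1.5% figure expected under interference-based whole-genome simulation.  The
zero-IBD acceptance computation therefore uses the interference model; all
mean-level summaries use the Poisson default.

Genotyping errors are injected per marker, independently, into individual
A only: hom→het replaces one allele, hom→opposite replaces both, het→hom
collapses to either homozygote with probability ½ each (the ½ split is our
choice; the error taxonomy itself does not specify it).  The true IBD
track is left untouched — errors are observational.

### Fixture panels

Schematic panels emulate published marker sets by *size only* (92, 4,073,
9,618, 17,231, 53,593, 142,350 markers after filtering): positions i.i.d.
uniform over the map in cM, frequencies Beta(0.8, 0.8) truncated to
[0.05, 0.95] (a U-shaped, array-ascertainment-like spectrum).  Real panels'
marker identities, their LD structure and their population-specific
frequencies are deliberately not reproduced, so per-panel results here
characterise density, not the actual products.

## Inference methods

**Linked likelihood.**  The pairwise IBD process along a chromosome is
approximated as a Markov chain: for unilineal classes a two-state chain
(IBD 0/1) with stationary distribution (κ₀, κ₁) and transition matrix
P(d) = Π + e^(−ad)(I − Π), a = m/100 per cM with m the separating meioses;
for siblings, two independent per-parent two-state chains (2 meioses each)
whose sum gives an exact three-state chain.  Emissions are the standard
conditional genotype-pair tables P(g₁, g₂ | k, p); chromosomes restart at
stationarity; the forward pass is scaled per marker, so likelihoods are
returned in log space without underflow.  The sibling chain is exact under
Haldane; the unilineal chains are the usual close approximation (the exact
process is not Markov).  At the "fictive map" spacing of 100 cM the chain
is close to, but not exactly at, stationarity (residual e^(−m)); exact
equality with the unlinked likelihood is reached only as distances → ∞,
and the tests check both regimes.

**Unlinked likelihood.**  The same emission tables mixed over κ with
markers independent; impossible observations (probability zero under the
hypothesis) yield −∞, reported as such.

**ML κ (EM).**  Maximises the composite (linkage-ignoring) likelihood over
the 2-simplex; E-step is the per-marker posterior over the IBD level,
M-step its average.  Relative tolerance 1e-8, cap 500 iterations.  EM's
monotone but slow crawl near simplex vertices means the cap can be hit
with the estimate already at the boundary to three decimals;
`KappaEstimate.converged` records this honestly.

**KING-robust φ̂.**  Implemented exactly from heterozygote-concordance
counts (formula in the README).  The reference individual i is the one
with the *higher* heterozygote count by default (the originally
published estimator uses the
opposite) — simulated sibling pairs give mean φ̂ 0.2513 vs 0.2482 under the
two conventions, so the choice is nearly immaterial at these marker
counts; both are exposed via `king_phi(..., reference=)`.

**Segment approach.**  Maximal runs of consecutive markers with no
opposite-homozygote (IBS0) site, zero IBS0 tolerance; a run is a segment
iff its first-to-last-marker span is ≥ `min_cm` (default 5 cM) and it has
≥ `min_snps` markers.  The span convention is the inner marker span, which
shrinks calls slightly at low density.  `min_snps` is the critical,
density-dependent knob: too low and chance IBS0-free runs flood the
genome, too high and true segments at the 5 cM scale are lost.  A density
formula (`default_min_snps` = max(16, 0.6 × expected markers per 5 cM)) is
adequate for dense panels (~130 at 142,350 markers) but bottoms out at
mid densities, so the pipeline default is a small calibration study
(`calibrate_panel`): simulate a few dozen pairs per class once, extract
their IBS0-free runs, and score a fixed candidate grid by mean per-class
accuracy (ties to the larger threshold).  Crucially, each candidate is
scored with a total-cM bin table derived from its own observed per-class
mean totals, because called totals sit systematically below true sharing
(over-short segments are dropped, runs over-extend, chance runs add up) and
fixed true-sharing bins would trade classes off against each other.
Deterministic under its seed; for the 9,618-marker fixture it selects
70–100 markers (≈25–33 cM at that density).

**Windowed kinship.**  Non-overlapping windows of W markers (default 60,
scaled with panel size in [30, 300]); a window is a *seed* if its fraction
of markers with at least one shared allele is f ≥ 0.95; adjacent seeds
merge into superwindows; a superwindow is called IBD iff its kinship
statistic reaches a = 0.23, and calls spanning ≥ 5 cM are reported.  The
call rule is the one genuinely open design point: pooling a single
KING-style kinship over the merged span rejects ~half of true
single-window first-cousin segments (the estimate's SD over 60 markers is
~0.07 against a 0.25-vs-0.23 margin) and collapses first-cousin recovery
to ~⅓ of the expectation, so the default tests the *maximum* member-window
kinship instead (`call_rule="max"`; `"pooled"` remains available).  With
the max rule the per-class totals reproduce the expected qualitative
pattern, including the known inflation of unrelated pairs' called cM on
dense panels.

## Classifiers

φ̂ is binned with geometric-midpoint boundaries between expected kinships
(2⁻³, 2⁻⁵, 2⁻⁷, 2⁻⁹); total cM with geometric midpoints between per-class
expected totals (2460, 818, 298, 49, and 10 cM for chance sharing), i.e.
≈1418, 494, 121, 22 cM by default — the external total-cM lookup table
used in consumer genealogy is proprietary, and these derived bins stand in
for it.  The bin means are configurable, and the pipeline substitutes
calibrated observed-total means for the two segment detectors (the same
construction as the simulation-derived lookup tables it replaces).  κ̂ goes to the nearest reference vector in
Euclidean distance; segment features (count, mean length) to the nearest
simulated per-class centroid after z-scoring by pooled SD (raw counts and
cM are incommensurate).  Every tie, in every classifier, breaks toward the
more distant class, to keep false relatedness conservative.  Consensus
classification reports the modal class if at least k methods agree,
otherwise "inconclusive"; an optional LR>threshold abstention flag exists
but is off by default.

## Reproducibility

Every stochastic operation takes an explicit seed or Generator; experiment
drivers derive per-pair seeds from a single root via
`numpy.random.SeedSequence`, so identical configurations give bit-identical
classification matrices, and the error-impact experiment re-uses the same
pairs across error rows (paired design).  CLI runs write a JSON manifest
with config, seeds and file digests.

## Problem sizes

Acceptance-level computations use 2,000 gene-dropped pairs per class for
mean-sharing summaries (Monte-Carlo SE ≈ 4 cM for first cousins), 5,000
for third cousins, 10,000 for the zero-IBD fraction (binomial SE ≈ 0.12
percentage points), and 500 simulated first-cousin pairs for per-method
classification rates — sizes at which the Monte-Carlo error is well inside
the tolerances being checked while a full run stays in the minutes range
on one CPU.

## Known limitations

- Founders in linkage equilibrium: no LD, hence no LD-driven inflation of
  the linked LR on very dense panels — a documented real-data phenomenon
  this simulator intentionally cannot reproduce.
- Unrelated pairs are frequency draws, not members of a finite cohort, so
  their method outputs have no background-relatedness component.
- The unilineal linked-likelihood chain is an approximation to the exact
  (non-Markov) IBD process; classification rates, not likelihood values,
  are the supported output.
- Segment and windowed callers operate on unphased genotype pairs; no
  haplotype-aware (phase-using) IBD calling, no IBD2 calling from
  genotypes, no mutation/silent-allele model.
- X/Y chromosomes, sex-specific maps, half-relationships, once-removed
  relationships and >2-person likelihoods are out of scope.
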