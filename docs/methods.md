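# Methods

This note documents the statistical model, numerical choices and known
limitations of `clockminer`, in the spirit of the methods documentation of
packages like statsmodels or msprime.

## Evidence model and scoring

The unit of evidence is a binary *hit*: gene *g* is, or is not, present in
evidence dataset *l* (circadian transcription-factor binding near the gene,
circadian protein abundance, or interaction with a core clock protein).
Confidence calibration across heterogeneous assays is deliberately avoided:
every dataset contributes its weight (1, except one unusually thorough
BMAL1 ChIP-seq study at 3) whenever the gene is a hit.  The built-in
registry (`paper_registry()`) carries the 19 published sources with their
master-list hit counts; the weighted hit-count total over the inventory is
5601, a fixed-point the tests assert.  A gene present in every dataset
scores 16 (ChIP-seq class, the weight-3 set counted at its weight) + 3
(proteomics) + 2 (PPI) = 21.

Class-weighted scores S(g) = α·chip + β·prot + γ·ppi keep the dataset
weights *inside* the class sums, so the equal split α=β=γ=1/3 reproduces
total/3 exactly.  Scores for observed genes and for permutation nulls are
combined by one shared routine, so equal class sums produce bit-identical
floats and significance thresholding uses plain ≥ with no epsilon.

## Permutation null

The null assigns each dataset's hit count uniformly at random, without
replacement, to the master list, independently across datasets.  Two
consequences drive the implementation:

* the per-gene marginal null score is Σ<sub>d</sub> w<sub>d</sub>·
  Bernoulli(h<sub>d</sub>/n), identical for every gene — so all n scores of
  every iteration are pooled into one empirical distribution (1000
  iterations × 1000 genes = 10⁶ pooled draws by default), maximizing
  resolution;
* that marginal admits an exact convolution (`exact_null`), used as an
  independent oracle for the Monte-Carlo shuffle and as a fast replacement
  inside heavy simulations.  Under pre-factors, the three class sums are
  convolved separately and combined over the ≤ 17·4·3 grid of class-sum
  triples.

"More extreme" means ≥ the observed score.  P-values from a shuffle null
are floored at 1/(iterations·n); scores beyond the support take the nearest
tail value.  The significance threshold is the smallest support value with
tail < level; when no support value qualifies, an exact null returns the
next integer above its support (its tail truly vanishes there) while a
shuffle null raises an error if the requested level is below its
resolution.  The shuffle is vectorized over iterations (per dataset, the h
smallest of n i.i.d. uniforms form a uniform h-subset), batched to bound
memory; a 1000-iteration null over the full registry takes about a second
on one CPU.

The shuffle ignores inter-dataset correlation (e.g. multiple REV-ERB
cistromes); the analysis compensates with the stringent 0.001 level rather
than modelling the correlation.  Under the published hit counts the exact
tail brackets the threshold tightly: P(S ≥ 13) = 7.1·10⁻⁴ < 0.001 ≤
P(S ≥ 12) = 3.7·10⁻³.

## Robustness screen

Pre-factors are sampled uniformly on the simplex slice
{α+β+γ=1, 0.165 < each < 0.5} by rejection from a symmetric Dirichlet(1,1,1)
— provably uniform on the slice, whose area fraction is
T² − 3·max(T−U, 0)² with T = 1−3·0.165, U = 0.5−0.165, ≈ 16.8% of the
simplex (the tests check the acceptance rate against this).  Draws are
generated one at a time so a fixed seed yields nested draw sequences; the
bound 0.165 is taken literally (not 1/6) and the inequalities are strict.
Each draw rebuilds the null under its own pre-factors (shuffle with an
independent seed derived from the master seed, or the exact convolution);
robust candidates are the intersection of the per-draw significant sets
over 100 draws at the 0.001 level.

A boundary property worth knowing: a gene holding exactly the minimal
significant evidence profile (weighted total 13, class sums 10/2/1) clears
the equal-weight threshold but is non-significant for roughly 14% of
admissible pre-factor draws, so the 100-draw screen prunes it essentially
always.  That is the screen working as designed — it removes genes whose
significance depends on the weighting.  Recovery tests therefore plant
*high-evidence* candidates (class sums 11/2/2, weighted total 15), which
are significant under every admissible weighting (worst-case per-draw
p ≈ 8·10⁻⁵); the generator's default planting remains the minimal profile
for boundary studies.

## Circular phase regression

Peak phases of significantly rhythmic transcripts (rhythm-detection
FDR < 0.05), pooled across tissues without per-gene weighting, are modelled
as von Mises with mean direction

    E(phi) = mu + 2*arctan(c_E*S_E + c_D*S_D + c_RRE*S_RRE)

and common concentration κ.  The TF-group scores are weighted within-group
ChIP-seq hit sums normalized by the group maximum (E-box 6 — the weight-3
BMAL1 set enters at weight 3; D-box 1; RRE 5); PER/CRY binding sets, which
lack DNA-binding domains, feed no group.  All fitting is in radians;
reported phases convert by 24/(2π) h per radian.  With the written
convention (μ in CT hours plus a radian-valued arctan term converted to
hours) the fitted coefficients reproduce the qualitative biology: a pure
E-box gene peaks near CT 9, D-box+RRE near CT 0; the 2·arctan link bounds
predictions within μ ± 12 h, i.e. it cannot wrap past the antipode.

**Fitting.**  The log-likelihood ℓ = −n·log(2π·I₀(κ)) + κ·Σ cos(θᵢ − μ −
2·arctan(cᵀsᵢ)) is linear in κ given the mean structure, so the fit
maximizes C(μ, c) = Σ cos(residual) and then sets κ̂ = A⁻¹(C/n), where
A(κ) = I₁(κ)/I₀(κ) is inverted by bracketed root-finding on the
exponentially-scaled Bessel ratio.  This one-shot profile is exactly
equivalent to alternating schemes that re-profile κ each outer step.
Because the arctan link can make C multimodal, the optimizer (L-BFGS-B with
analytic gradients) is restarted from μ₀ = circular mean shifted by
{0, +6, −6, 12} h with c₀ = 0, plus any user start; accepted quasi-Newton
steps never decrease C and the history is retained on the results object so
ascent is testable.  Constant regressor columns are detected, flagged
unidentifiable and fixed at 0 (the intercept-only fit then reduces to
μ̂ = circular mean, κ̂ = A⁻¹(R̄)).  Standard errors come from the observed
information, computed by central differences of the analytic score in
(μ, c, κ); Wald intervals on simulated data achieve nominal coverage at
n ≈ 3000 in the acceptance checks.

**Rayleigh test.**  Mean-direction significance per TF-binding combination
uses Z = n·R̄² with the second-order tail correction
p = e^(−Z)·(1 + (2Z − Z²)/(4n)), clipped to [0, 1]; the type-I error at
α = 0.05 is verified to lie in [0.035, 0.065] over 1000 uniform-phase
replicates, and the values agree with an independent implementation to
within the difference between published correction variants.  The circular
median of a combination is the observed phase minimizing mean absolute
circular deviation, ties broken toward the smaller CT value.

## Synthetic data

The generator reproduces the study conditions: 1000 genes, the 19 published
hit counts, 14 tissues.  Background hits are independent
Bernoulli(h_d/n) per dataset — the per-gene marginal of the shuffle null —
with an exact-totals mode (one literal shuffle draw) for oracle
comparisons.  Phases are drawn from the generative twin of the phase model
at the published parameter values (μ = 17.97 CT, c = (−2.25, 0.67, 0.41),
κ = 0.58): a gene-tissue record is rhythmic with probability
`circadian_fraction` (default 0.085, chosen so a gene is rhythmic in ≥ 1 of
14 tissues with probability ≈ 0.70, matching the master list), in which
case FDR ~ U(0, 0.05) and phase ~ von Mises about the model mean; otherwise
FDR ~ U(0.05, 1) and phase uniform.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: correlation of hits between related datasets
(shared cistromes), tissue-specific binding (the model assumes liver
binding generalizes), per-gene heterogeneity of κ, and any dependence of
rhythmicity calls on expression level.  Parameter-recovery results
demonstrate correctness of the estimator under the model, not adequacy of
the model for any particular dataset.

## Problem sizes and determinism

Defaults throughout are the analysis's own: 1000-gene master list, 1000
null iterations (10⁶ pooled scores), 100 robustness draws, 0.001 level,
~3000 pooled phase observations and 50 replicates for coverage studies;
simulation-heavy checks use the exact convolution null per draw, which is
analytically identical to the shuffle marginal and orders of magnitude
faster.  Every stochastic routine takes an explicit seed (NumPy
`SeedSequence`-derived streams; per-draw seeds spawn deterministically from
the master seed), and the pipeline writes a manifest with the merged
configuration, seeds and input digests so identical manifests reproduce
identical outputs.

## Known limitations

* Gene identifiers are opaque strings; ID mapping, peak-to-gene assignment
  and rhythm detection are upstream of this package.
* The hypergeometric overrepresentation annotation states the standard
  test, with the background universe a required input; it is a documented
  assumption, not a reproduction guarantee of any published annotation.
* The per-draw robustness nulls assume dataset independence, as does the
  main null.
* Wald intervals for κ rely on asymptotic normality; at small n or κ near 0
  profile intervals would be preferable and are not implemented.
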