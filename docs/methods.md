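# Methods

## Model and assumptions

All analyses operate on summary statistics: one (effect, SE) pair per
variant per trait, assumed to come from large-sample GWAS so that effect
estimates are approximately normal with known variance. The causal model is
linear: a one-unit (one SD, for continuous traits) increase in the exposure
changes the outcome by θ (on the log odds-ratio scale for binary outcomes).
Instruments must satisfy the usual three IV conditions — association with
the exposure (relevance), no association with confounders (exchangeability),
and no effect on the outcome except through the exposure (exclusion
restriction). The estimators differ in how much of the third condition they
assume: IVW requires all instruments valid; MR-Egger allows directional
pleiotropy that is independent of instrument strength (InSIDE); the weighted
median tolerates up to half the weight coming from invalid instruments;
MR-PRESSO detects and removes individual violators.

Two-sample conventions apply throughout: exposure and outcome effects come
from non-overlapping samples, exposure-side uncertainty is ignored in the
ratio SE (the no-measurement-error approximation, reasonable when
per-variant F = (β_X/σ_X)² is large), and instruments are assumed
independent after LD clumping.

## Pipeline stages and defaults

**Instrument selection.** Variants below a p-value threshold (default
5 × 10⁻⁸; a relaxed 5 × 10⁻⁶ is conventional for small exposure GWAS) are
greedily clumped: keep the smallest-p variant, discard everything with
r² ≥ 0.01 against it, repeat. Equal p-values are broken lexicographically by
variant id so results are order-independent. Variants absent from the LD
panel are treated as unlinked with a logged warning; r² = 0 never counts as
linkage, so a zero threshold prunes each LD-connected component to its top
variant.

**Harmonization.** Outcome rows are aligned to the exposure's effect
allele: identical pairs kept, swapped pairs sign-flipped (eaf
complemented), strand-complementary pairs complemented then re-matched,
anything else dropped as mismatching. Palindromic variants (A/T, G/C) are
removed by default because strand orientation is unresolvable from summary
data; an optional allele-frequency rescue (both traits' eaf outside
0.5 ± 0.08 on the same side) can be enabled but is off by default. Missing
eaf is tolerated everywhere except that rescue.

**Estimators.**

* IVW uses multiplicative random effects by default: the fixed-effects SE is
  scaled by max(1, √(Q/(J−1))). The floor keeps under-dispersed instrument
  sets (Q < df) at the fixed-effects SE, so fixed and random effects
  coincide unless there is excess heterogeneity. P-values use a normal
  reference; a single instrument falls back to the Wald ratio.
* MR-Egger orients rows so β_X ≥ 0 internally (never mutating the input),
  fits weighted least squares with intercept, scales SEs by
  max(1, √(Q/(J−2))), and uses a t reference with J−2 df — the heavier tails
  acknowledge the small effective sample.
* The weighted median uses the simple (non-penalized) weights β_X²/σ_Y² and
  interpolates the weighted quantile at 0.5 (cumulative midpoint positions
  S_j − w_j/2). Its SE is the sample SD of the estimate over 1000
  parametric-bootstrap replicates drawing β* ~ N(β̂, σ) around the observed
  data; the seed is mandatory so results are reproducible. This
  data-centered bootstrap — the same scheme the field's reference tools
  use — is structurally conservative for a quantile estimator: resampling
  around noisy observations convolves the observed ratio noise with fresh
  noise, inflating the SE by up to √2. Our calibration run measures the
  inflation at about 1.18 (bootstrap SE 0.061 vs true sampling SD 0.052)
  and the resulting 95% CI coverage at ~0.98 rather than 0.95. We keep the
  standard scheme and note the conservatism rather than substituting a
  model-centered bootstrap.
* MR-PRESSO computes each variant's weighted squared residual from the
  leave-itself-out IVW slope, simulates the null by redrawing
  β*_X ~ N(β̂_X, σ_X) and β*_Y ~ N(θ̂_(−j)β̂_X, σ_Y) (exposure effects held
  fixed when exposure SEs are unavailable, logged either way), and uses
  add-one empirical p-values (never exactly zero; the global p is bounded
  below by 1/(n_sim+1)). Defaults: n_sim = 1000, outlier α = 0.05 on the
  Bonferroni-adjusted scale, 1000 random-removal draws for the distortion
  test, which is reported only when outliers exist; a corrected estimate is
  emitted only when at least one variant is flagged.

**Colocalization.** Wakefield ABFs use prior effect SD 0.2 for continuous
traits and 0.15 for binary (log-OR) traits; configuration priors are
p1 = p2 = 10⁻⁴ (variant causal for one trait) and p12 = 10⁻⁵ (shared),
the field-standard values. All hypothesis masses are accumulated in log
space; the H3 term Σ_{j≠k} BF1_j·BF2_k is computed as the stable
log-difference a + log1p(−exp(b−a)) with a = lse(L1)+lse(L2) and
b = lse(L1+L2), so catastrophic cancellation cannot occur; a single-variant
region (or b ≥ a numerically) gets exactly zero H3 mass. The decision rule
is PP4 strictly greater than the threshold (default 0.70). Regions are
caller-supplied variant lists; no gene-annotation logic is included.

**Multivariable MR and mediation.** MVMR is weighted least squares of β̂_Y
on the K exposure-beta columns without intercept, weights 1/σ_Y², SEs with
the same overdispersion floor (df n−K); a rank-deficient design raises a
collinearity error naming the redundant exposures. The mediation
decomposition runs, for each mediator separately: β_total and β1 from
univariable IVW; β2 and β_direct from one two-exposure MVMR of the outcome
on (mediator, exposure), instrumented by the union of both traits'
instruments restricted to variants present in all three tables. The
indirect effect is β_total − β_direct with SE √(σ_total² + σ_direct²) — a
working independence assumption, since the covariance between two separate
fits is unavailable from summary data — and the proportion mediated is
β_indirect/β_total with delta SE √(σ_ind²/β_t² + β_ind²σ_t²/β_t⁴). This SE
is conservative relative to a covariance-aware form (the indirect and total
estimates share the total's sampling error); a product-of-coefficients
(β1·β2) cross-check is provided. Proportions from correlated mediators
analysed one at a time can legitimately sum above 1.

**Mediator screen.** Step 1 (exposure→mediator IVW) and step 2
(mediator→outcome IVW, each mediator instrumented by its own variants) are
each Benjamini–Hochberg-adjusted across mediators at FDR < 0.05; candidates
must pass both. Mediators that cannot be harmonized or instrumented are
skipped with a recorded reason, never silently dropped.

**Enrichment.** Over-representation uses the exact upper-tail
hypergeometric probability P(X ≥ k), BH-adjusted across pathways and ranked
by p. This is a deliberately transparent substitute for web-service
enrichment tools whose internal statistics are unpublished; rank agreement,
not p-value agreement, is the meaningful comparison.

## The synthetic-data generator

`simulate_two_sample` draws true instrument effects b_j ~ N(0.15, 0.08²),
observed β_X ~ N(b, 0.01) and β_Y ~ N(θb + α, 0.05), with pleiotropy
offsets α on a configurable fraction of instruments (directional or
balanced). The defaults give per-variant F ≈ 100–900 (mean ≈ 290), matching
the strong-instrument regime of metabolite and lipid GWAS, and J = 50
instruments with θ = 0.3. `simulate_region` draws marginal regional
z-scores MVN(Σλ, Σ) under AR(1) LD (ρ = 0.9, 200 variants) with the causal
non-centrality λ placed per scenario (shared / distinct / one-trait /
none), |z| ≈ 10 at the causal variant (effect 0.1 SD at n = 10 000).
`simulate_mediation` builds an exposure→mediator→outcome chain with path
coefficients (0.6, −0.4) and direct effect −0.1 by default, independent
instrument sets per trait, and a truth record carrying the implied
proportion mediated.

What the generator deliberately does **not** emulate: realistic allele
frequency spectra, winner's curse in instrument selection, sample overlap
between exposure and outcome panels, binary-trait likelihood effects (case
fractions), population stratification, or indels/multi-allelics. Passing
tests therefore demonstrate correctness of the estimators under their
stated sampling model, not robustness to those real-data pathologies.

## Problem sizes used in validation

Calibration uses 500 replicates at J = 50 (bias, coverage) plus 200
replicates for the pleiotropy contrast; Cochran's Q type-I error uses 1000
null replicates; MR-PRESSO detection uses 200 replicates (J = 20, one
variant displaced by 10σ_Y) and null-uniformity 500 replicates at
n_sim = 500; colocalization regimes use 100 regional replicates per
configuration; mediation recovery uses 500 replicates of the default chain.
The bundled demo study (47 usable forward instruments after clumping, three
mediators, two regions, 30 reverse instruments) runs in well under a minute
and is byte-reproducible from its config and seed.

## Known limitations

No mode-based estimators, Steiger filtering, penalized/robust IVW variants,
multi-exposure PRESSO, multiple-causal-variant or SuSiE-style
colocalization, conditional regional analysis, non-linear MR, joint
(network) mediation, or figure rendering. Proportion-mediated CIs are
symmetric first-order delta intervals and can extend beyond [0, 1] for
weakly identified chains; bootstrap or Fieller intervals would be a natural
extension.
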