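# Methods

## Design

The pipeline estimates how much of a trait's effect on a disease outcome is
mediated by liability to an intermediate disease, using only GWAS summary
statistics from three non-overlapping samples (trait, mediator, outcome).
It assumes the standard instrumental-variable conditions (relevance,
independence, exclusion restriction apart from explicitly modelled
pleiotropy), linear structural relations on the analysis scale, and no
trait-by-mediator interaction. Effects for binary traits are log-odds and
are kept on that scale throughout; the non-collapsibility of odds ratios is
addressed by re-running with a linear-model mediator GWAS as a sensitivity
analysis (a different input file, not different code), never by rescaling.

## Instrument selection and harmonisation

Instruments are variants with p < 5×10⁻⁸ (strict inequality), greedily
LD-clumped: the smallest-p remaining variant becomes an index and removes
all same-chromosome variants within ±10 Mb with r² > 0.001 against it. The
window is interpreted as ±10 Mb around the index — the convention of the
standard clumping tools — because a total 10 Mb span would halve the
stated window; the choice is configurable (`window_bp`) and recorded in the
run manifest. Ties on p break on (chromosome, position, variant id) so
output is independent of input row order. LD is consumed as a correlation
matrix (square or long TSV); variants missing from it are treated as
independent with a logged warning, and cross-chromosome pairs are always
independent. Instruments with fewer than ten post-clump variants are
removed (ten passes).

Harmonisation matches variants by id, flips outcome betas (and complements
frequencies) for swapped alleles, maps strand-complemented records back,
and resolves palindromic (A/T, C/G) variants purely by effect-allele
frequency: both frequencies must fall outside [0.5−w, 0.5+w] (default
w = 0.08, configurable); same-side frequencies keep the sign, opposite
sides flip it; anything else — including a missing frequency — is dropped
and counted. Finally every variant is oriented so the effect allele
increases the exposure. Orientation is applied last because MR-Egger is not
invariant to allele coding. Harmonisation is idempotent and conserves
records (matched = retained + palindromic drops + incompatible drops).

## Estimators

* **IVW**: no-intercept weighted regression of outcome on exposure betas,
  weights 1/se_out². Multiplicative random effects scale the SE by
  √(Q/(k−1)) floored at 1 (fixed-effects floor), matching the standard
  two-sample MR software family; pure fixed effects is a config switch. A
  single-variant set degenerates to the Wald ratio with first-order SE
  se_out/|β_X|.
* **MR-Egger**: the same regression with an unconstrained intercept; the
  intercept estimates average directional pleiotropy. Inference is t with
  k−2 degrees of freedom — the small-k regime where the t/normal choice
  matters; all other estimators use the normal approximation with the
  95% multiplier 1.959964. I²_GX measures dilution from measurement error
  in the exposure associations; (1 − I²_GX)·100 is reported as the maximum
  relative attenuation of the Egger slope towards the null (0.93 → 7%).
* **Weighted median**: interpolated 50th weighted percentile of the
  per-variant ratios, weights (β_X/se_out)²; SE by seeded parametric
  bootstrap (default 1000 replicates; the seed is mandatory in config).
* **Modes**: argmax of a Gaussian-kernel density of the ratios on a fixed
  512-point grid spanning [min θ − 3h, max θ + 3h]; bandwidth
  h = φ·0.9·min(sd, IQR/1.349)·k^(−1/5) with φ = 1 by default. Uniform
  weights give the simple mode, inverse-variance weights the weighted mode.
* Variants with β_X = 0 after orientation are excluded from ratio-based
  estimators with a warning and retained for regression-based ones.
* **MVMR-IVW**: no-intercept weighted regression on both exposures'
  associations; an identically zero exposure column is excluded from the
  fit (its coefficient reported as 0), and a condition number above 1e8
  raises a collinearity error naming the pair. Conditional F for one
  exposure regresses its associations on the other's (weights 1/se² of the
  chosen exposure, cross-trait sampling covariance taken as 0) and returns
  Q_x/(L−K+1); the modified heterogeneity statistic Q_A uses df = L−K
  against the χ² 5% critical value. Conventions are written to the run
  manifest because software packages differ here. The zero cross-trait
  covariance is a documented limitation where trait and mediator cohorts
  overlap.
* **Mediation**: indirect = b₁·b₂ (trait→mediator × mediator→outcome
  direct), SE = √(b₂²se₁² + b₁²se₂²) — the two-term product-of-coefficients
  delta formula with no covariance term, as the two estimates come from
  separate fits. The total effect is the univariate IVW estimate of the
  trait on the outcome (not direct + indirect). Proportion mediated is a
  point estimate by default (an optional delta-method CI sits behind a
  flag); out-of-range proportions are reported as computed and flagged,
  never truncated, because they are diagnostic.

## Screening

"Supportive" evidence means BH-adjusted p strictly below α = 0.05,
computed within each analysis family (trait→mediator, mediator→trait,
trait→outcome per outcome); a joint-correction switch exists because the
family definition is a genuine design choice. A trait progresses to stage 2
for an outcome iff it is a cause-only of the mediator (forward supportive,
reverse not) and supportive for that outcome. Traits failing the
ten-instrument rule carry a distinct `ineligible-instruments` status rather
than disappearing. The MVMR instrument set is the union of both exposures'
significant variants, clumped using the p-values of the exposure with the
smaller pre-clump instrument.

## Synthetic data

`simulate_study` draws per-variant effects γ on the trait (uniform
magnitude in [0.04, 0.10], random sign — large enough to be genome-wide
significant at consortium-scale samples) plus the mediator's own
instruments δ, and builds true associations through the linear system
M = β_XM·X + δ·G_M, Y = θ_X·X + θ_M·M + α·G_X. Observed betas add Gaussian
noise with se = 1/√(n·2f(1−f)), independent across the three samples.
Defaults are θ_X = 0.2, β_XM = 0.3, θ_M = 0.5 and sample sizes of
200 000/200 000/180 000 — the scale of the consortium GWAS this design is
used with. Allele labels, frequencies (uniform on [0.05, 0.95]),
palindromic variants (10%), swapped-allele (30%) and strand-flipped (10%)
records exercise harmonisation end to end. LD is emulated with exchangeable
blocks: one causal variant per block, tags at ρ times its associations, and
a block-diagonal correlation matrix. Summary statistics are simulated
directly — no individual-level genotypes — which is sufficient for
two-sample MR and orders of magnitude faster.

What the generator does **not** emulate: genome-wide polygenicity,
MAF-dependent effect-size architecture, sample overlap between cohorts,
population stratification, or LD beyond exchangeable blocks. Passing tests
therefore demonstrate correctness of the estimators and decision logic
under the stated model, not robustness to those real-data complications.

`simulate_screening_study` builds multi-trait studies sharing one mediator
and one GWAS per outcome. Its effect scales (γ ∈ [0.05, 0.09] at
n = 200 000 for traits; δ ∈ [0.10, 0.16] at n = 50 000 for the mediator)
were chosen so each trait's instrument set stays disjoint from the
mediator's: trait variants sit safely below genome-wide significance in the
mediator GWAS, which keeps the bidirectionality classification of an
engineered study deterministic at the constructed truth. With shared
instruments (as in the bidirectional fixtures) reverse-direction estimates
pick up heterogeneity-inflated SEs — a realistic phenomenon the tests
acknowledge by asserting on the screening scale rather than genome-wide
significance.

## Verification problem sizes

The statistical checks use sizes chosen to make Monte-Carlo error small
relative to the effects being verified: parameter recovery averages 500
studies of 60+60 variants with exposure-side GWAS of 5×10⁶ (so
weak-instrument attenuation, which scales with se²_X/var(β_X), is an order
of magnitude below the 3-Monte-Carlo-SE tolerance set by outcome noise);
null CI coverage uses 1000 replicates; the Egger intercept type-I check
uses 2000 replicates with equal allele frequencies, the regime where the
pleiotropy-plus-noise residual is homoscedastic and the t reference exact;
the realised-FDR check uses 1000 replicates of 15 all-null analyses, where
the random-effects floor makes IVW p-values slightly conservative and the
realised FDR lands at or below the nominal 5%.

## Numerical choices and degenerate inputs

P-values are floored at 1e-300 to keep them in (0, 1] under extreme z
scores. Zero exposure betas raise an error in the Wald ratio, are excluded
from ratio estimators, and a fully zero exposure column raises a
degenerate-instrument error in IVW. Empty harmonised intersections raise an
input error; a harmonised set emptied by palindrome drops is returned empty
with counts. LD matrices are validated for symmetry, unit diagonal and
|r| ≤ 1. All stochastic components (bootstraps, simulations) derive from a
single configured seed, which is what makes pipeline reruns byte-identical.

## Known limitations

No MR-PRESSO, contamination-mixture, Steiger filtering or MVMR-Egger (out
of scope by design); no liability-scale conversion for binary traits; no
computation of LD from reference panels; cross-trait sampling covariance in
MVMR fixed at zero; the proportion mediated is undefined when the total
effect is zero and is reported as missing with a flag.
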