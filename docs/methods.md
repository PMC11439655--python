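# Methods

This note documents the statistical models implemented in `pqtlmr`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions that were
genuinely open.

## Data model and harmonization

Summary statistics are per-variant marginal estimates: identifier,
chromosome, 1-based position, effect/other allele, effect-allele frequency,
β, SE, p, and sample size. Case-control effects live on the log-odds scale,
protein effects in SD units. All genomic windows (±1 Mb cis, ±500 kb
colocalization, 10,000 kb clumping) are inclusive on both ends.

Printed p-values in public summary files are rounded, so they are carried
but never used for inference: every test recomputes significance from β/SE.
On read, a row whose stated p-value disagrees with the β/SE-implied value
by more than a factor of 10 triggers a warning, not a rejection.

Harmonization matches exposure and outcome by variant identifier (a strict
mode could additionally demand positional agreement; identifiers are how
public summary files are keyed). Swapped alleles negate the outcome β and
reflect its EAF; strand flips are recognised through allele complements.
Palindromic variants (A/T, C/G) are kept only when both EAFs are on the
same side of 0.5 and at least `palindrome_eaf_margin = 0.08` away from it
(i.e. dropped when either EAF is in [0.42, 0.58]) — a conventional
frequency-based disambiguation, since strand cannot be inferred from the
alleles themselves.

## Instrument selection

Filters run in a fixed order — significance, cis classification, clumping,
strength — and every excluded variant is logged with its reason, so
selection partitions the input. The F statistic uses k = 1 per variant
(each SNP judged alone, the conventional reading of the "F > 10 per
instrument" rule); a set-level F with k = number of retained instruments is
available as `InstrumentSet.f_set` for reporting. MAF is always derived
from EAF rather than read as a separate column.

Clumping is greedy: repeatedly take the most significant remaining variant,
then drop all remaining variants within the window whose r² with it
exceeds the threshold. Ties are broken by |z| and then by identifier, so
the result does not depend on input row order. One caveat verified during
development: the kept set is *not* monotone in the r² threshold — tightening
it can remove a variant that would itself have clumped away others, which
reshuffles (and can even enlarge) the index set. Monotonicity does hold for
the p-value and F filters.

## SMR

For the top cis-pQTL (largest |z| among selected instruments),
b_SMR = b_GWAS/b_pQTL and T = (z²_G·z²_P)/(z²_G+z²_P) is referred to χ²₁;
se_SMR = |b_SMR|/√T and is reported as missing when T = 0. The statistic
accounts for sampling error on both sides of the ratio, and is
scale-equivariant in the pQTL effect. FDR correction
(Benjamini–Hochberg, via statsmodels) is applied across all proteins in a
run; the report carries both raw and adjusted p. The HEIDI
heterogeneity-in-dependent-instruments test is out of scope. Odds ratios
are exp(β) with 95% CIs at z = 1.959964, reported to 2 decimals.

## Colocalization

Per-variant Wakefield log-ABFs use effect-size prior variances
W = 0.15² for the standardized quantitative (protein) trait and W = 0.2²
on the log-odds scale for the case-control trait — the conventional
single-trait priors for this framework. Per-variant hypothesis priors
default to p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵. Hypothesis weights are

- H0: 1, H1: p1·S1, H2: p2·S2, H3: p1·p2·(S1·S2 − S12), H4: p12·S12,

with S1 = Σᵢ exp(l1ᵢ), S2 = Σᵢ exp(l2ᵢ), S12 = Σᵢ exp(l1ᵢ+l2ᵢ). All sums
use log-sum-exp; ln(1−r) is computed as ln V − ln(W+V) for stability at
small V; the H3 difference is evaluated in log space via
log1p(−exp(log S12 − log S1 − log S2)) and floored at zero (it is exactly
zero with a single shared variant and can only go negative through
rounding). Posteriors therefore sum to 1 to 10⁻⁹ by construction.

The region is centred on the gene TSS (±500 kb, inclusive) — the
annotation the pipeline carries — rather than on the lead pQTL, and all
region variants enter (no pre-clumping). The model assumes at most one
causal variant per trait in the region; with several shared causal
variants the posterior concentrates on the dominant pair, and planted
scenarios in this package keep that pair unambiguous (see below).

## Two-sample MR and sensitivity analyses

Wald ratios use the first-order SE, se_out/|β_exp| (a second-order version
is a one-line change; first-order is the default for strong, F > 10
instruments). IVW is the weight-w = 1/se² mean; fixed-effects
SE = (Σw)^−1/2; Cochran's Q with J−1 df drives the model switch: random
effects — the fixed SE inflated by √max(1, Q/df) — exactly when the Q
p-value < 0.05, matching the screen's stated rule. IVW inference is normal;
MR-Egger uses weighted least squares (statsmodels WLS, weights 1/se²_out)
of outcome on exposure effects oriented so every β_exp > 0, with
multiplicative overdispersion floored at 1 and t-inference on J−2 df. The
weighted median interpolates the ratio estimates at cumulative weight 0.5;
its SE is a seeded parametric bootstrap (default 1,000 draws of each ratio
from N(b, se²), weights fixed).

Leave-one-out refits IVW (auto model) per omitted variant and flags an
omission that flips the sign or moves the estimate by more than one SE *of
the refit* — the full-fit SE is inflated by precisely the heterogeneity an
outlier causes, and would mask the omissions the diagnostic exists to
catch.

MR-PRESSO: the observed residual sum of squares uses leave-one-out IVW
slopes and weights 1/se²_out; the null distribution redraws exposure
effects around their estimates and outcome effects around the
leave-one-out predictions (default 1,000 replicates — desk-scale; the test's
resolution is 1/(n_sim+1) and the count is configurable). Empirical
p-values use (r+1)/(n+1) and can never be zero. The per-variant test is
Bonferroni-corrected over J; the distortion test compares the
outlier-removed slope against slopes from random same-sized removals in the
simulated data (two-sided empirical p). The distortion result is reported
but gates nothing downstream.

## Evidence tiers

Tier 1 = SMR (P_FDR < 0.05) + colocalization (PP.H4 > 0.80) + discovery MR
(p < 0.05) + replication MR (p < 0.05); tier 2 drops replication; tier 3
drops both MR stages; failing SMR or colocalization yields no tier.
Direction consistency between the SMR and discovery IVW estimates is
computed and reported, but only enforced in `strict` mode — the tier rule
itself uses the four stage flags. FDR correction applies only at the SMR
stage; the validation MR stages use raw p < 0.05.

## Synthetic data

Summary statistics are simulated directly from their asymptotic sampling
distribution on the standardized scale: marginal estimates
β̂ ~ MVN(R·b, R/n) for LD matrix R (AR(1) by default) and joint effects b,
then rescaled per variant — protein SEs 1/√(2f(1−f)n), case-control SEs
1/√(2f(1−f)·n·s(1−s)) with case proportion s. MAFs are uniform on
(0.05, 0.5); positions are evenly spaced over 1 Mb. The causal
protein→outcome effect θ is expressed in log-odds per SD of protein, so the
GWAS standardized joint effect at a protein causal variant is
θ·b_protein·√(s(1−s)) and the per-allele Wald ratio recovers θ directly.

Defaults are chosen to emulate the scale of the real resources this
pipeline targets: a 35,559-sample pQTL panel, a discovery GWAS of 247,173
with 54% cases and a replication GWAS of 201,713 with 9.3% cases. Region
scenarios default to 200 variants, ρ = 0.9, n = 10,000 per trait,
var_explained = 0.10 (a strong top cis-pQTL) and θ = 0.35 (the magnitude
of the largest published protein–breast-cancer effects); H3 places the two
causal variants far enough apart that |r| ≤ 0.1. Independent-instrument
scenarios draw true exposure effects from N(0.15, 0.05²) truncated
positive, with per-variant SEs 0.01 (exposure) and 0.015 (outcome) —
typical per-allele magnitudes at these panel sizes — and support balanced
or directional pleiotropy on an invalid fraction plus planted outcome
outliers.

The multi-protein cohort generator plants evidence tiers: each protein
gets one region (its own chromosome) with five independent cis signals
(variance explained 0.05, 0.01, 0.01, 0.008, 0.008 — a dominant lead keeps
the top variant and the coloc lead pair unambiguous), separated by ≥ 33
variants so pairwise r² clears the clumping threshold. Tier-1/2 proteins
satisfy the exclusion restriction (GWAS effects proportional to protein
effects at every site; tier 2 sets the replication effect to zero); tier-3
proteins colocalize at the lead site but carry opposing pleiotropic
outcome effects at the other sites, chosen so the IVW-weighted mean ratio
is exactly zero — heterogeneity then inflates the random-effects SE and
validation MR fails, while SMR and colocalization still pass. Null
proteins are H0 (no signal), H3 (LD-confounded), or sub-threshold ("weak")
scenarios.

What the generator does *not* emulate: genome-wide LD maps (one AR(1)
region per protein), allele-frequency–dependent effect-size architecture,
sample overlap between exposure and outcome studies, population
stratification, or strand ambiguity in the simulated files (alleles are
emitted consistently). Passing tests therefore demonstrate the estimators'
statistical behaviour under the assumed sampling model, not robustness to
those real-data pathologies.

Two stage outcomes are intentionally stochastic at their nominal rates: a
tier-2 protein's replication stage is a true null tested at α = 0.05, so
roughly 5% of tier-2 plantings will "falsely replicate" into tier 1 at an
arbitrary seed; the tier-3 discovery failure is near-deterministic but not
exact. The end-to-end determinism check is about byte-stability given a
seed, which is exact.

## Numerical and reproducibility choices

- Every Monte-Carlo component (weighted-median bootstrap, MR-PRESSO,
  generators) takes an explicit seed; the pipeline derives all randomness
  from the single seed in its config.
- Proteins are processed and written in sorted name order, so outputs are
  byte-identical across runs regardless of filesystem enumeration.
- Files are written with `%.17g`/round-trip float handling so write→read
  preserves every bit.
- p-values are floored at the smallest positive double rather than
  reported as 0.
- Degenerate inputs are explicit errors (no instruments, empty overlap,
  β_pQTL = 0) or logged drops, never silent NaNs.

## Known limitations

Single-causal-variant colocalization (no SuSiE-style multi-signal
decomposition); no trans-pQTL analysis; no multivariable MR, Steiger
filtering or mode-based estimators; LD is an input, never computed from
genotypes; no genome-build liftover. The pipeline's resume logic skips
rewriting completed stage outputs but recomputes in memory — correctness
over cleverness at these problem sizes.
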