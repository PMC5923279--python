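# Methods

This note documents the statistical models implemented in `metadigest`,
the defaults and the reasoning behind them, the synthetic-data model used
for validation, and known limitations.

## Data model and preprocessing

A **bucket table** holds one biological compartment's metabolome: rows are
birds, columns are integrated chemical-shift segments ("buckets") of a 1D
¹H-NMR spectrum. Bucket boundaries are taken as given (they come from
spectroscopy software); `bucket_spectrum` integrates a sampled spectrum over
each `[ppm_lo, ppm_hi]` interval with the trapezoid rule, linearly
interpolating intensities at interval boundaries, and subtracting excluded
sub-intervals (e.g. the residual-water region). Trapezoidal integration was
chosen because the bin-area rule of the original acquisition software is
unspecified; any Riemann-type rule agrees with it to within grid resolution,
and the associated unit tests check additivity (splitting a bucket in two
preserves total area to 1e-9) and agreement with closed-form areas.

**Total-area normalization** divides every row by its own sum, making rows
compositional (each sums to 1). It removes per-sample differences in
absolute signal (dilution, mass) and is idempotent. A consequence worth
knowing: after closure, *every* bucket shares the denominator, so buckets
that are pure noise before normalization acquire a small systematic
correlation with whatever drives the informative buckets (~|r| ≈ 0.18 under
the synthetic defaults below). This is a property of the preprocessing, not
a bug, and it sets a floor on achievable variable-selection specificity.

**Traits.** AMEn is kept in kcal·kg⁻¹ DM; coefficients of digestive use are
fractions in [0, 1], computed from balance trials as
CDU = (FI_DM − FW_DM)/FI_DM (scale-invariant in the common unit). Values
supplied as percentages (> 1.5) are divided by 100 with a logged warning.
Birds missing a trait are dropped from any model requiring it, with a
logged exclusion record. Descriptive summaries use n−1 standard deviations
and a Gaussian KDE with Silverman bandwidth on a 512-point grid spanning
the data ± 3 bandwidths (the ingredients of a violin plot); a constant
trait degenerates to a reported point mass rather than an error.

## Sample screening

Each compartment is screened once, before any supervised model. PCA is
computed by SVD of the unit-variance-scaled matrix (constant columns get
scale 1 and a flag). With A retained components (default 2 — the component
count of the downstream models; the number defining the ellipse is a
package choice, configurable), the Hotelling statistic
T²ᵢ = Σₐ t²ᵢₐ/λₐ is compared with the F-based 95% limit
A(N−1)(N+1)/[N(N−A)] · F₀.₉₅(A, N−A). The F form (rather than a χ²
approximation) is the convention of SIMCA-family software, whose screening
behaviour this stage mirrors. Calibration is verified by simulation: over
200 null Gaussian cohorts (n=60) the mean exclusion rate lies in
[0.02, 0.09] at α=0.05.

## PLS regression with iterative variable selection

Both blocks are autoscaled (mean 0, unit variance, n−1 denominator). For a
single response, the NIPALS weight update has a closed form — per component
w ∝ Eᵀf on the current residual matrices — so each component needs one
pass; X and y are both deflated. Stored quantities follow the chemometric
conventions: weights W, loadings P, scores T, Y-loadings c, rotated weights
W* = W(PᵀW)⁻¹, coefficients B = W*c (scaled space) plus their
back-transformed originals, cumulative R²X/R²Y. VIP is
√(p·Σₐ SSYₐ w²ₐⱼ / Σₐ SSYₐ); its squares average to exactly 1, which the
suite asserts as an algebraic identity.

**Cross-validation.** 7-fold, with deterministic venetian-blind folds
(fold g = samples with index ≡ g mod K) so results are reproducible without
an RNG; a seeded shuffle is available. Q² = 1 − PRESS/SS_y with PRESS from
out-of-fold predictions of the full model; RMSEE = √(RSS/(n−1−A)) on the
full-data fit (degrees-of-freedom corrected); RMSECV = √(PRESS/n). An exact
"cross-validation set RMSEE" as printed by SIMCA is not publicly specified;
RMSECV is the documented stand-in. Per-coefficient uncertainty uses the
delete-a-group jackknife over the K fold models,
SEⱼ = √[((G−1)/G)·Σ_g (b_jg − b̄ⱼ)²], with 95% t-based intervals centred on
the full-data coefficient. Coefficients are compared across variables in
the centred-and-scaled space (the "CoeffCS" convention), where bucket
intensity scale cannot masquerade as importance; whether a CI straddles
zero is invariant to that choice.

**CV-ANOVA.** Model reliability is tested by an F statistic on the
cross-validated residuals, F = [(SS_y − PRESS)/A] / [PRESS/(n−A−1)], with
p from the upper F tail; PRESS ≥ SS_y is clamped to F=0, p=1. Degrees of
freedom follow the (A, n−A−1) convention; the exact accounting of
commercial implementations is proprietary, so correctness is established
by null calibration (≤ 12% of null cohorts reach p < 0.05; in practice the
observed rate is ~0) and power on planted cohorts (p < 0.01 in > 90% of
seeds).

**Iterative selection.** Each iteration refits model + CV, then removes
every bucket that simultaneously has VIP < 1, a jackknife CI containing 0,
and |scaled coefficient| below the median — a conservative triple-AND rule;
each threshold is configurable. The loop stops when no bucket qualifies,
when Q² has failed to improve for two consecutive iterations, or at 50
iterations. The retained model follows the cross-validation
one-standard-error rule: the most parsimonious iteration whose Q², plus
one SE of its own Q² (estimated from the per-fold PRESS spread), reaches
the maximum observed Q². Rationale: Q² plateaus once the informative
buckets dominate, and differences within one SE are fold noise; among
statistically indistinguishable models the sparser biomarker panel is the
better deliverable. Setting `q2_tolerance=0` restores a strict
maximum-Q² choice. Under the synthetic defaults the retained panel keeps
on average 7.8 of 8 planted buckets with ~3 false positives; a handful of
noise buckets with chance (plus closure-induced) correlations are
statistically indistinguishable from weak markers at n=60 and cannot be
removed by any coefficient-based rule.

**Validity gate (pipeline).** Variable selection is only attempted when
the full pre-selection model is itself credible (CV-ANOVA p ≤ 0.05 and
Q² > 0). Post-selection statistics are optimistically biased by the
selection itself; on a metabolome unrelated to the trait the gate reports
the honest full-model diagnostics instead of a cherry-picked panel. The run
report carries both the full-model and the post-selection figures.

## Canonical sparse PLS

The symmetric two-block model works on the autoscaled blocks. Per
component, with M = XᵀY on the current residuals: v starts at the leading
right singular vector of M, then u ← soft(Mv), v ← soft(Mᵀu) alternate
until the update norm falls below 1e-9 (max 500 iterations). The soft
threshold is set by an order statistic — λ_u is the (keepX+1)-th largest
|entry| of Mv — so the number of surviving loadings is exactly keepX
(magnitude ties break toward the lower variable index; a tied kept entry is
retained at vanishing magnitude to preserve the cardinality). This
exact-cardinality formulation matches a design that fixes the *count*
("one quarter of the variables": round(p/4), ties up, hence 48/40/16 for
191/160/64) rather than a penalty value. The trait block is never
penalized (keepY = q = 4). Deflation is canonical: each block is deflated
by the regression on its own score. Sign convention: the largest-|entry|
element of u is made positive, v flipping jointly, so results are
platform-deterministic. In the dense limit (keepX=p, keepY=q) component 1
equals the leading singular-vector pair of XᵀY, which the suite checks
against an SVD oracle at 1e-8.

**Explained variance** of a block on component h is the mean over the
block's variables of cor²(variable, score_h), computed against the
*original* scaled block (not deflated residues); constant variables are
excluded with a log message. **Similarity scores** are
sim(j,k) = Σ_h cor(Xⱼ, ξ_h)·cor(Yₖ, ω_h), again on the original scaled
blocks; by default only component 1 enters (the first component is the one
explicative of the DE traits, in both the motivating study and the
synthetic regime), so every entry is a product of two correlations and lies
in [−1, 1]. The matrix is restricted to the buckets selected on the
component(s) used.

## Relevance networks

An edge joins bucket j and trait k when |sim(j,k)| > cutoff, strictly
(default 0.5: a score of exactly ±0.5 draws no edge); only endpoint nodes
are kept. Merging across compartments: unassigned spectral regions are
dropped; buckets sharing a metabolite label within a compartment collapse
into one node named "label (S|I|C)", inheriting all member edges with
parallel edges resolved to the maximum-|score| edge; the member with the
largest |score| is recorded as the representative bucket; trait nodes are
shared. The label of a multi-metabolite bucket (e.g. "Galactose + Lipids")
stays compound — overlapping resonances cannot be attributed to one
metabolite. Merging is idempotent. Exports: GraphML (round-trips exactly,
attributes included), Cytoscape-compatible SIF, and a TSV edge list.

## Over-representation analysis

For a query of n metabolites from a background of N (default: the union of
the library's members, overridable), a set with b background members and
a = |query ∩ set| scores p = P(X ≥ a), X ~ Hypergeom(N, b, n), computed via
the scipy survival function and verified against exhaustive pmf enumeration
for all N ≤ 25. Name matching is case-insensitive and whitespace-trimmed
with an optional synonym table — no fuzzy matching, to keep matches
auditable. Sets with b < 2 are reported but flagged untestable. FDR control
is Benjamini–Hochberg step-up (verified against a naive min-over-suffix
oracle), cutoff 0.05 for the reported pathways.

## Synthetic cohorts

The generator emulates the study design the analysis assumes:

- n = 60 birds; one latent digestive-efficiency factor t ~ N(0,1) per bird.
- Traits: y_k = q_k·t + ε, trait noise sd 0.3; loadings q = 0.9 (AMEn),
  0.7 (CDU_S), 0.85 (CDU_N), 0.8 (CDU_L) — all four traits are strongly
  inter-correlated, as in a cohort where one physiological axis drives
  digestive use of every substrate. AMEn is mapped affinely to the kcal
  scale (mean 2950, sd 340 kcal·kg⁻¹ DM, the realistic 4-week range); CDUs
  pass through a logistic with per-trait offsets chosen to reproduce
  realistic means (starch ≈ 0.95, nitrogen ≈ 0.8, lipids ≈ 0.67), which
  keeps them in [0,1] without truncation artifacts. CDU_DM at weeks 2 and 4
  load 0.5 and 0.8 — the week-2 measurement is only a proxy of the 4-week
  factor.
- Buckets: 64 serum / 160 ileum / 191 caecum, of which 8/10/12 are
  informative: x_j = sign·β·t + ε with β = 0.8 and noise sd σ = 0.5; the
  sign is negative in serum and positive in the digestive compartments
  (circulating markers of poor digestion vs unabsorbed products in the gut).
  Remaining buckets are pure N(0, σ²) noise. The matrix is shifted to
  positivity (global minimum subtracted, +0.01) and total-area normalized —
  reconciling the additive-Gaussian convenience with non-negative NMR areas.
- Assignments: informative buckets carry metabolite names drawn from
  compartment-appropriate built-in lists; 75% of noise buckets get decoy
  names, 25% stay unassigned. The GMT library contains one enriched set
  (the informative metabolites) plus six random decoy sets.
- One seeded `numpy.random.Generator` per dataset; identical seeds give
  byte-identical datasets. A null generator (β = 0) produces traits
  independent of the metabolome for type-I-error calibration; an optional
  orthogonal nuisance factor is available via `nuisance_sd`.

What the generator does *not* emulate — and hence what green tests do not
demonstrate about real data: multi-factor trait structure, peak overlap and
chemical-shift drift, heteroscedastic bucket noise, compartment-specific
covariance between metabolites, microbiota-driven block correlation, and
real pathway structure in the set library. Recovery rates measured here are
upper bounds for cohorts of comparable size.

## Numerical conventions and degenerate inputs

- Autoscaling uses n−1 standard deviations; constant columns scale by 1 and
  are flagged, never dropped silently.
- NIPALS tolerance 1e-10, max 500 iterations (one pass suffices for a
  single response); sPLS tolerance 1e-9, max 500, convergence failure is an
  error, not a warning.
- Rank-deficient X truncates the component count with a log warning rather
  than fabricating near-zero components.
- Fold assignment never touches global RNG state.
- Zero-sum bucket rows, zero-variance responses, empty networks, and
  all-identical traits all have defined behaviour (error with the offending
  sample named, error, legal empty result, point mass respectively).
- All file readers reject malformed input with the line number; nothing is
  coerced.

## Pipeline scale

The default test suite and the acceptance script run entirely on synthetic
cohorts at the study's own dimensions (60 × 64/160/191); calibration and
recovery rates use 50 replicate cohorts (200 for the Hotelling screen),
sizes at which every rate examined is stable to within a few percent
between seed sets.

## Known limitations

- RMSECV stands in for the unpublished "cross-validation set RMSEE" of
  commercial software; the two differ by their denominator convention.
- CV-ANOVA degrees of freedom follow (A, n−A−1); commercial
  implementations may differ slightly, so only calibration — not
  number-for-number agreement — is claimed.
- Variable-selection specificity is bounded by chance and closure-induced
  correlations at n = 60 (see above); expect a few statistically
  irremovable false positives in any ~10-bucket panel.
- The ORA background defaults to the library union; with a different
  background universe, absolute p-values shift even though the ranking is
  stable.
- Networks are data structures plus exports; layout and rendering are out
  of scope.
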