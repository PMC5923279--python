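# metadigest

Chemometric analysis linking ¹H-NMR metabolome bucket tables to digestive-
efficiency (DE) traits in poultry.

Digestive efficiency — summarized by the apparent metabolisable energy
corrected to zero nitrogen retention (AMEn, kcal·kg⁻¹ DM) and the
coefficients of digestive use of starch, nitrogen and lipids
(CDU = (intake − excreta)/intake) — is heritable but expensive to measure:
it requires individual balance trials. A cheaper route is to look for
metabolic biomarkers: bucket (binned) ¹H-NMR spectra of serum and of ileal
and caecal contents, related to the DE traits by two-block latent-variable
models. `metadigest` implements that full workflow for researchers in
livestock metabolomics and chemometrics:

1. **Data model** — bucket tables (samples × integrated ppm segments,
   total-area normalized so each row sums to 1), trait tables, bucket →
   metabolite assignment maps, GMT metabolite-set libraries; all plain-text
   TSV with strict, line-numbered validation.
2. **Sample screening** — PCA on unit-variance-scaled buckets;
   Hotelling's T² at the 95% limit,
   T²ᵢ = Σₐ t²ᵢₐ/λₐ vs [A(N−1)(N+1)/N(N−A)]·F₀.₉₅(A, N−A),
   excludes outlying birds before any supervised model.
3. **PLS biomarker regression** — NIPALS PLS of AMEn on a bucket table with
   VIP (mean VIP² = 1), 7-fold cross-validation (R²Y, Q² = 1 − PRESS/SS,
   RMSEE, RMSECV), delete-a-group jackknife coefficient confidence
   intervals, CV-ANOVA (F = [(SS − PRESS)/A]/[PRESS/(n−A−1)]), and an
   iterative variable-selection loop that removes buckets with low VIP,
   zero-straddling jackknife CI *and* sub-median |coefficient| until Q²
   stops improving.
4. **Canonical sparse PLS** — symmetric two-block model between the bucket
   table and the 4-trait block, LASSO-style soft thresholding keeping
   exactly ⌈p/4⌋ buckets per component (191 → 48, 160 → 40, 64 → 16),
   per-block explained variance, and first-component similarity scores
   sim(j,k) = cor(Xⱼ, ξ₁)·cor(Yₖ, ω₁).
5. **Relevance networks** — bipartite bucket–trait graphs with edges where
   |sim| > 0.5 (strict), merged across compartments into one global network
   (unassigned buckets dropped, same-metabolite buckets collapsed onto the
   strongest representative); export as GraphML / SIF / TSV.
6. **Enrichment** — hypergeometric over-representation of the network's
   metabolites in a GMT library, Benjamini–Hochberg FDR, 0.05 cutoff.
7. **Synthetic cohorts** — a generator that plants a single latent DE
   factor into ~60 birds and 64/160/191 buckets per compartment (a small
   informative minority; negative loadings in serum, positive in digestive
   contents), which makes every stage testable end to end without data
   downloads.

## Worked example

```python
import metadigest as md

cfg = md.PipelineConfig(outdir="run", seed=1,
                        synthetic=md.SyntheticConfig(seed=1))
report = md.run_pipeline(cfg)
```

or, equivalently, `metadigest run-all --synthetic --seed 1 --out run`.
On the default synthetic cohort (seed 1) the serum compartment prints:

```
serum: excluded 2 outlier(s) of 60
PLS (AMEn): 11 buckets retained, R2Y=0.830, Q2=0.777, RMSEE=108.2 kcal/kg DM, CV-ANOVA p=1.23e-18
sPLS: keepX=16, component-1 Y explained variance 89%
network: 8 buckets + 4 traits, 32 edges
enrichment: top set 'digestive_efficiency_markers' (28/28), FDR p=6.75e-17
```

Reading: two birds fell outside the 95% Hotelling ellipse and were dropped;
the iterative selection pruned 64 serum buckets to an 11-bucket biomarker
panel that explains 83% of AMEn variance in fit and 78% in 7-fold
cross-validation, with an estimation error of ±108 kcal·kg⁻¹ DM; the model
is highly significant by CV-ANOVA. The sparse canonical model kept
one-quarter of the buckets (16) and its first component captures 89% of the
variance of the four DE traits; thresholding the similarity matrix at ±0.5
leaves 8 buckets connected to the traits, and after merging all
compartments the planted marker set is the top-enriched pathway (all 28 of
its metabolites recovered). Per-compartment outputs (coefficient tables
with VIP and jackknife CIs, observed-vs-predicted tables, similarity
matrices, GraphML/SIF networks, the enrichment table and `report.json`)
land in the output directory.

All randomness flows from the seeds; a rerun with the same configuration is
byte-identical.

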