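# Methods

## Data model

All statistics operate on per-CpG methylated/unmethylated read counts.
Coordinates are 1-based inclusive; chromosome names are exact strings
(no "chr" normalisation — silent renaming hides data errors). Coverage
files are taken as strand-collapsed; stranded cytosine reports are
destranded by summing the `+` strand C at position p with the `-`
strand C at p+1 and reporting the pair at p (lone bottom-strand sites
are reported at p−1). Destranding conserves total counts exactly.

The united matrix keeps only sites observed in **every** library
(`require_all=True` by default): the per-site regressions downstream
assume a complete design. The union mode (absent cells at coverage 0)
exists for exploratory use.

## Preprocessing

Order of operations: destrand → per-sample coverage filter → unite →
coverage normalisation → binomial methylation call.

- **Coverage filter.** Per sample, sites with coverage < 10 are
  dropped, as are sites strictly above the sample's empirical 99th
  percentile (linear-interpolation/type-7 percentile, computed on the
  pre-filter distribution). The percentile is per sample, mirroring how
  per-library PCR-duplicate pileups arise.
- **Normalisation.** Sample s is scaled by f_s = M*/M_s (M_s its
  median coverage, M* the largest sample median); methylated and
  unmethylated counts are scaled separately and rounded half-up, which
  preserves meth ≤ coverage.
- **Conversion error.** Pooled Σmeth/Σcov over all lambda-spike sites
  of all libraries (a single library-set-wide rate). An exact zero is
  replaced by half a pseudo-count, 0.5/Σcov, so the binomial null is
  non-degenerate.
- **Methylation call.** One-sided *upper-tail* exact binomial test per
  cell — the null is that apparent methylation is non-conversion error,
  so only excess methylation counts as evidence; a two-sided test has
  no meaning here. BH is applied jointly across all site×sample cells
  (single family; per-sample stratification would change the implicit
  prior per library). A site enters the analysis set when methylated in
  ≥ 1 sample.

## Differential methylation

With a single binary group covariate the binomial logistic regression
has a closed-form MLE: the fitted proportions are the pooled group
fractions, and the pooled fit is the null. The deviance
2(ℓ_alt − ℓ_null) is therefore computed exactly (no iterative fit) and
referred to χ²₁; boundary MLEs (perfect separation) contribute
0·log 0 = 0 terms and never overflow. Replicates are treated as
independent binomial observations — no overdispersion correction, the
classical default for this test; with pooled 10-individual libraries
the residual between-replicate overdispersion is real but modest, and
the acceptance checks measure the realised false-positive rate rather
than assume nominal calibration.

Thresholds: q < 0.05 (BH within comparison) **and** |Δ| > 0.15 (both
strict), with Δ the pooled-fraction difference. "Consistently"
hyper/hypomethylated means significant with the same sign in both
successive comparisons (day 0→8 and day 8→16); the hyper and hypo sets
are disjoint by construction. Gene-level calls need ≥ 2 DMPs in the
feature and |weighted-methylation difference| ≥ 0.15 across the whole
feature; CpGs overlapping two genes count in both (no exclusion rule is
defensible without strand-aware annotation). A fixed-effects
weighted-methylation summary by sex×age is written for inspection
(`weighted_methylation.tsv`).

## Epigenetic drift

**VMP screen.** Per site, methylation fractions are compressed into
(0,1) by y′ = (y(n−1) + 0.5)/n (the standard boundary remedy; affine,
so order-preserving), a beta regression on (age, sex) is fitted as the
mean-trend model (non-converged sites are excluded and flagged, never
silently zeroed), and the Breusch–Pagan test is run on the linear fit
of the same transformed response on (age, sex) in its studentized
(Koenker) form, LM = n·R² of the auxiliary regression of squared
residuals, df = 2. Holm–Bonferroni is applied across all tested sites.

Two power facts matter and are inherent to the screen, not to this
implementation:

1. **The LM statistic is bounded by the sample count.** R²_aux ≤ 1, so
   LM ≤ n. At n = 18 the smallest achievable p-value is
   χ²₂-tail(18) ≈ 1.2×10⁻⁴. Holm across m sites demands p < 0.05/m, so
   for m > ~400 *no site can ever be family-wise significant*,
   regardless of effect size. With the default fixture (≈2,700
   methylated sites) VMP recall after Holm is exactly 0, and the
   per-site screen at raw p < 0.05 recovers ~10% of true drift sites
   at the default precision schedule (φ 80→10). The screen's p-values
   still *rank* drift sites far below stable ones (verified by rank
   test); at this design size the screen is an ordering device, not a
   detector. Designs with tens of samples per site are needed for
   family-wise VMP discovery by this route.
2. **The χ² reference is asymptotic.** At n = 18 the null distribution
   of the Koenker p-value deviates visibly from uniform (Kolmogorov
   distance ≈ 0.1 even with ideal normal errors); at n = 200 it is
   uniform to ≈ 0.02. Calibration checks therefore simulate
   homoscedastic sites at n = 200.

**Entropy.** The per-sample entropy is the normalized mean binary
entropy of the methylation fractions over a chosen site set (the
pipeline uses the age-significant DMPs, the set on which entropy is a
meaningful ageing readout). The prefactor 1/(N·ln ½) makes the
logarithm base irrelevant and pins the range to [0,1]; 0·ln 0 = 0. An
alternative "as-printed" variant with second term (1−MF)(1−ln MF) is
available behind a flag for comparison; it is not normalised to [0,1]
(its use is discouraged — the binary-entropy form is the one consistent
with an entropy bounded by 1, and is what the package reports).

Because binary entropy is concave, increasing the *dispersion* of
fractions around a fixed mean strictly lowers mean entropy (Jensen);
entropy growth with age comes from methylation means moving toward 0.5
— exactly what a mostly-unmethylated genome gaining methylation with
age does. The generator's age-trending classes are parameterised
accordingly (hyper 0.15→0.45, hypo 0.85→0.55 over days 0→16).

The entropy model is a beta regression of entropy on age + sex +
age×sex; the interaction is tested by likelihood ratio (χ², 1 df), and
per-sex age slopes by Wald tests on stratified refits (the same
inference target as marginal-means machinery, with a simpler
contract). Sexes with fewer than 3 distinct ages skip the slope test
with a warning.

Beta regression throughout is maximum likelihood for the
mean–precision parameterisation (shape1 = μφ, shape2 = (1−μ)φ) with a
logit mean link and log-precision link internally, Wald standard
errors from the observed information, and an honest convergence flag.

## Epigenetic clock

Elastic net with mixing α = 0.5 by default (the conventional midpoint —
"elastic net" means 0 < α < 1; exposed as a flag), on internally
standardized fractions, coefficients returned on the original scale.
The λ path descends geometrically over 100 points from the smallest
all-zero λ (path floor 10⁻³ of the top). λ is the CV-MSE minimiser over
seeded folds (a 1-SE rule is available); fold assignment is stratified
by age — samples are shuffled within age groups and dealt round-robin —
because unstratified 3-folds on 18 samples risk folds missing an age
entirely. λ = 0 is solved exactly by least squares; path fits during CV
use a relaxed coordinate-descent tolerance (1e-6) and the final refit a
tight one (1e-10).

In-sample accuracy of a clock trained on age-selected CpGs is
optimistic by construction; the model object carries the
cross-validated predictions as the honest counterpart. Two evaluation
caveats: with k samples tied at each of three ages, Spearman ρ of even
a perfect predictor is capped below 1 (≈ 0.944 at 6 ties per age — the
average-rank ceiling), and in-sample RMSE can be near zero when the
support is large relative to n. Spearman p uses the t approximation at
all n (documented; small-n p-values are indicative only). Age
acceleration is the residual of chronological age regressed on
epigenetic age (OLS with intercept, residuals sum to 0; affine
relations between the ages are absorbed). The sex comparison uses the
Wilcoxon rank-sum statistic W = rank-sum(A) − n_A(n_A+1)/2, exact by
enumeration when n_A+n_B ≤ 12 without ties, tie-corrected normal
approximation otherwise.

## Enrichment

Universe = background genes with ≥ 1 GO annotation (unannotated genes
carry no information for the hypergeometric model); terms with K ≥ 1
carrier are tested, p = P(X ≥ k), BH across terms. Two backgrounds:
all methylated genes (for VMP and clock gene lists) — a gene is
methylated when its weighted methylation, averaged over the replicates
of a sex×age group, exceeds 0.05 (the lambda-spike weighted-methylation
level) in at least one group, strictly — and all differentially
methylated genes (for the consistent hyper/hypo sets). No ancestor
propagation is performed on the GO graph; term lists are taken as
given.

## Synthetic methylome

The generator draws coverage per cell from a negative binomial
(mean 30, dispersion 20, clamped ≥ 1) and methylated counts from a
beta-binomial with per-class mean/precision:

| class | count | mean μ | precision φ |
|---|---|---|---|
| null_unmeth | 15,000 | conversion error (0.005) | 10⁶ (≈ binomial) |
| stable | 2,000 | U(0.2, 0.8) per site | 80 |
| dmp_hyper | 200 | logit-linear, 0.15→0.45 by day 16 | 80 |
| dmp_hypo | 200 | logit-linear, 0.85→0.55 | 80 |
| vmp | 300 | U(0.35, 0.65), constant | 80→10 linearly in age |
| clock | 40 | clip(U(0.10,0.55) + 0.02·age, 0.02, 0.98) | 300 |
| lambda spike | 200 sites | binomial at 0.005 | — |

Design: 2 sexes × days 0/8/16 × 3 replicates = 18 libraries. Rationale
for the main choices: the ~15% methylated compartment matches a
sparsely methylated insect genome and keeps the BH threshold of the
methylation call in a regime where the unmethylated bulk is controlled;
coverage dispersion 20 keeps per-sample ≥10× survival near 98% so the
all-sample intersection retains ~80% of sites (a lower dispersion
collapses the intersection across 18 libraries); the unmethylated bulk
uses effectively infinite precision because non-conversion is
read-sampling noise, not biological variance (and the lambda spike is
itself binomial); the DMP day-0→16 effect of 0.30 sits comfortably
above the 0.15 call threshold without being trivial; drift precision
80→10 roughly triples the fraction variance over life. Each site class
draws from its own seeded substream (`SeedSequence([seed, class_id])`),
so resizing one class never reshuffles another, and identical configs
give byte-identical files.

A synthetic annotation tiles the chromosome with genes of 10
consecutive CpGs and assigns 2–4 background GO terms per gene plus
class-flavoured terms (probability 0.6) to genes in age-responsive
blocks, so enrichment has planted signal.

What the generator does **not** emulate: read-level artefacts
(sequencing error, mapping bias, M-bias), non-CpG contexts, spatial
correlation between neighbouring CpGs, cell-composition shifts with
age, and genome-scale site counts. Passing tests therefore demonstrate
the statistical machinery on data satisfying the models' assumptions
at desk scale — not performance on real WGBS libraries, whose
headline counts (hundreds of thousands of methylated CpGs) differ by
orders of magnitude.

## Problem sizes and determinism

The default fixture is ~17,700 genomic + 200 lambda sites × 18
libraries, chosen so a full pipeline run (including ~2,800 per-site
beta regressions) completes in about a minute on one CPU while keeping
≥ 2,000 sites in every class used for error-rate checks. All
randomness flows from explicit seeds (generator substreams, CV fold
assignment); the pipeline writes no timestamps into outputs, so a rerun
with the same config is bit-identical. Stage failures abort with the
stage name and leave `manifest.json` marked incomplete.

## Known limitations

- The VMP screen's family-wise stage is powerless at n = 18 (see the
  LM ≤ n bound above); results list the screen p-values so users can
  rank candidates even when nothing clears Holm.
- The logistic DMP test ignores beta-binomial overdispersion; an
  overdispersion-aware variant would trade power for calibration and
  is a natural extension point.
- BH q-values stand in for the original SLIM-style q-values of the
  methylKit lineage; BH is reproducible and conservative here.
- GO enrichment treats terms independently (no graph propagation), so
  parent terms can appear enriched purely through annotated children.
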