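# Methods

This note documents the models implemented in `lowpass-eval`, the default
parameter values and why they were chosen, the numerical decisions that affect
results, and what the synthetic cohort generator does and does not emulate.

## 1. Call-set comparison

**Site identity and matching.** A site is a biallelic SNV keyed by
(chrom, 1-based pos, ref, alt). Two sites match only on exact agreement of all
four fields: no strand flipping, no ref/alt swap rescue. Records sharing a
position but not alleles are classed as *conflicts* and excluded from both
sides before genotype metrics are computed — the conservative rule used when
merging a called set with a reference panel. Multiallelic or non-SNV records
are dropped at VCF ingestion with a logged count. The four classes (matched,
unique-to-A, unique-to-B, conflict) partition the union of sites; this is
property-tested.

**MAF bins.** Defaults: singletons/doubletons (MAC ≤ 2, whatever the MAF),
rare (MAF < 1%), low-frequency (1–5%), common (≥ 5%). Bin edges are
left-closed (a site at exactly 1% is low-frequency). Monomorphic sites are
excluded everywhere by convention and raise if passed.

**Rates and their axes.** Capture rate (sensitivity) is matched-truth-sites /
all-truth-sites, binned by **truth** MAF; PPV is matched-evaluated-sites /
all-evaluated-sites, binned by **evaluated** MAF. The two axes genuinely
differ (an erroneous call has no truth MAF) and the convention is recorded in
the report's attributes. Empty bins report NaN, never 0.

**Concordance.** Genotype concordance counts identical dosages over matched
sites and shared samples, excluding cells missing in either set; call rate is
reported separately so missingness is not conflated with discordance.
Minor-allele concordance restricts the comparison to cells where either set
carries at least one minor allele; the minor allele is defined from the truth
set's allele frequency (alt when AF ≤ 0.5). This penalizes the trivially
concordant hom-ref majority at rare sites. No inequality between the two
concordances holds in general, and none is asserted.

**Printed precision.** Percentages are reported at one decimal with
round-half-up (`decimal.ROUND_HALF_UP`), never truncation or banker's
rounding. Published tables occasionally truncate (28.57% printed as 28.5);
tests against such values allow one unit in the last printed digit.

## 2. Ti/Tv site quality

True SNVs genome-wide show Ti/Tv ≈ 2.0–2.1; uniformly random miscalls show
2/4 = 0.5 (2 of the 6 unordered allele pairs are transitions). The tranche
sweep orders sites by a quality score (ties broken by position for
determinism), retains the top-s fraction for each sensitivity s in a grid
(default 50 equal steps), and reports the cumulative Ti/Tv; the *dropoff* is
the smallest s whose ratio falls below 2.0. Tranches with no transversions
have an infinite ratio and are excluded from the dropoff search.

The mixture FPR estimate treats a call set as a blend of true SNVs at
`true_titv` (default 2.1, configurable — distinct from the 2.0 dropoff
criterion, which is a filter rule, not a truth value) and random errors at
0.5: `fpr = clamp((true − observed)/(true − 0.5), 0, 1)`. It is validated for
magnitude only; an observed ratio above the assumed truth clamps to 0 with a
warning.

The exome high-confidence filter keeps sites with QUAL > 200, AN exactly
2 × n_samples (100% call rate) and DP ≥ 250. The depth rule is read as ≥ (a
cut-off derived from a depth distribution); the AN rule is exact equality.

## 3. Trait preparation

Order of operations: exclusions (missing values, optional k-SD outlier cut) →
covariate residualization by least squares (intercept always included) →
rank-based inverse-normal transform with offset ranks (r − ½)/n and average
ranks for ties. The output is N(0,1) to rank precision and invariant under any
strictly monotone pre-transform. Fewer than 10 usable values or a constant
trait raise. The residualize-then-transform order is the default and
configurable; the `log` transform is the exception — it is applied *before*
residualization (least-squares residuals are centered at zero, so their log is
undefined) and the result is z-standardized instead of rank-transformed.
Every exclusion is logged with (sample, reason) so batch preparation of large
trait panels stays auditable.

## 4. Relatedness and the mixed model

**GRM variant selection.** Isolated cohorts carry pervasive close kinship;
the relatedness matrix is estimated from a well-behaved variant set: MAF ≥ 1%
(rare variants are excluded — sparse, common-enriched sets give the most
stable kinship coefficients), HWE P ≥ 10⁻⁵ (1-df chi-square against
Hardy-Weinberg proportions; monomorphic sites return P = 1), then greedy
left-to-right LD pruning: a site is dropped when its r² with any retained
site within a trailing 50-site window exceeds 0.2. The window size and r²
threshold are exposed because no canonical values exist.

**Centered GRM.** K = XcXcᵀ/p with each site mean-centered and missing cells
mean-imputed (so they contribute nothing). This is the GEMMA-style centered
matrix: its diagonal averages the mean site heterozygosity, *not* 1. For
close-relative detection the correlation-normalized matrix
π̂ᵢⱼ = Kᵢⱼ/√(KᵢᵢKⱼⱼ) is used (`KinshipMatrix.pi_hat`), under which duplicate
samples sit near 1 and first-degree-like pairs near 0.5; the close-relative
rule is π̂ > 0.1. The raw K is what enters the mixed model, unthresholded.

**Null model.** y = Wα + u + e with u ~ N(0, σ²_g K), e ~ N(0, σ²_e I). On
the eigenbasis of K the covariance is diagonal in the variance ratio
δ = σ²_g/σ²_e, so the restricted likelihood is profiled to a 1-D function of
δ, maximized by a 100-point log₁₀ grid on [10⁻⁵, 10⁵] (plus δ = 0) followed by
bounded Brent refinement to 10⁻⁶. REML (not ML) is used so σ²_e matches the
OLS residual variance in the K = I limit, where δ is unidentifiable and the
fit degenerates exactly to ordinary regression — an oracle equivalence the
tests enforce to 10⁻⁸ relative.

**Score test.** Each variant is tested with the 1-df score statistic
T = (xᵀPy)²/(xᵀPx), P the null-covariance projection removing W, referred to
χ²₁ — no per-variant refit, which keeps genome scans at a single matrix
product. Variants with minor allele count ≤ 2 are removed first (strictly
MAC > 2): singleton and doubleton genotypes at 1× are too unreliable for
single-point association. Missing dosages are mean-imputed per site.

**Genomic control.** λ_median = median(χ²)/0.45494 (the χ²₁ median).
Statistics are divided by λ only when λ > 1 — deflation is left untouched,
since the correction exists to absorb residual inflation. Fewer than 100
tests make the median estimate unstable and raise.

## 5. Signal extraction and cross-study comparison

Variants with P strictly below 5×10⁻⁷ are clustered greedily: the smallest-P
unassigned variant becomes an index (ties broken by chrom, pos) and absorbs
all selected variants on its chromosome within ±500 kb (the "1 Mb window"
read as total span). Every selected variant belongs to exactly one signal;
the clustering equals a brute-force O(n²) oracle on instances up to 200
variants (tested).

A signal is looked up in another study by its index key; if absent, by the
best LD tag — the minimum P among that study's variants within ±500 kb whose
r² with the index dosages exceeds 0.8, computed in the querying dataset.
Signals with neither are *absent-and-untagged*. A signal is *true* when the
higher-depth reference study shows P < 5×10⁻⁵ (two orders of magnitude of
attenuation allowed) at the index variant or, when the index is absent from
the reference, at any member variant — signals are regional, not single-SNV.

The design comparison tabulates per-study truth fractions and, per MAF bin,
each study's true signals not recapitulated by the other (best available
cross-reference P ≥ 5×10⁻⁵ or none), split into absent-and-untagged versus
present-or-tagged-but-not-associated. The one-sided two-proportion z test
with Yates continuity correction compares the not-recapitulated fractions;
its z² equals scipy's Yates-corrected chi-square (tested), and on the
published 2/52 vs 20/108 table it gives P = 0.011.

## 6. The synthetic cohort generator

The generator is a *stated world*: its defaults are fixed once, for scientific
plausibility, and are never adjusted to make a test pass.

- **Allele-frequency spectrum**: Beta(0.2, 4) folded to the minor allele and
  truncated below at 1/(2N) by rejection. This puts the majority of sites
  below 1% MAF, the qualitative shape of sequencing-era site-frequency
  spectra. A point-mass option supports degenerate fixtures.
- **Genotypes**: per-site Binomial(2, f) under HWE. Family blocks share
  parental allele draws: each member allele copies a block allele with
  probability √r, making the within-block genotype correlation r in
  expectation (r = 0.5 behaves like first-degree relatives under π̂). This is
  deliberately not a pedigree simulator — it exists to exercise the π̂ > 0.1
  thresholding and mixed-model calibration, not to model meiosis.
- **Sequencing**: reads per cell ~ Poisson(λ); each read supports alt with
  probability ε, ½, 1−ε for truth dosage 0, 1, 2. The caller maximizes the
  read likelihood per cell (flat genotype prior by default; an HWE AF-weighted
  prior is available), leaves zero-read cells missing, breaks ties toward the
  smaller dosage, and drops sites whose calls carry no alt allele — so
  cohort-monomorphic sites in the sequenced universe can surface as
  false-positive sites through read error, which is what gives the low-depth
  arm a non-trivial PPV-by-MAF profile.
- **Imputation channel**: operates on genotypes per MAF bin, not haplotypes.
  Each output cell equals truth with the bin's accuracy, else one of the two
  other genotypes uniformly; truth sites missing from the raw calls are
  restored with a per-bin fill rate; output call rate is 100%. Defaults
  (rare 0.99, low-frequency 0.97, common 0.995 accuracy; fill 0.5/0.95/1.0)
  make per-cell concordance ≈ 0.97 at the calibration bin while the derived
  rare-bin minor-allele concordance lands near 0.5 — the qualitative profile
  of refinement pipelines. The channel is applied to the truth site universe
  only: false-positive call sites have no reference haplotypes and are not
  imputable.
- **Traits**: y = Σβⱼg̃ⱼ + u + e with variance-standardized causal dosages
  (β² = variance share), u ~ MVN(0, h²·K/mean diag K) via jittered Cholesky,
  iid Gaussian residual; unit total variance in expectation.
- **Depths and sizes**: the simulated arms default to 1× (low) and 22×
  (high-depth reference) with ε = 0.01 per read; the desk-scale acceptance
  run uses ε = 0.002, an effective post-QC miscall rate, so the
  false-positive channel at 1,000 samples neither vanishes nor saturates.
  The chip arm samples sites with MAF ≥ 5% with probability ∝ MAF and copies
  truth genotypes (chip error rate defaults to 0 — benchmark arrays are
  treated as error-free, an assumption, since no chip error figure is
  standard).

**What a green test does and does not establish.** The simulator has no LD
(sites are independent draws), no haplotypes or phasing, no recombination, no
reference-panel structure, and its imputation channel errs independently per
cell. Tests established here therefore validate the *metric definitions and
inference machinery* — that capture/PPV/concordance are computed correctly,
that the LMM calibrates under family relatedness, that tagging and truth
classification behave as specified — not that any real pipeline achieves
particular numbers. Data-dependent published percentages (95.2% capture, 97%
concordance, the 8.9–95.1% PPV profile) are magnitude anchors, reproducible
only from the deposited cohort data. LD-tag lookups in particular are
exercised through constructed correlated fixtures, since the generator's
independent sites carry no background LD.

## 7. Numerical and edge-case policy

- All generators are bit-reproducible from (seed, config); independent RNG
  streams are derived per stage via `SeedSequence` spawn keys so adding one
  stage never shifts another's draws.
- Zero denominators: empty bins → NaN (undefined, never 0); zero-variance
  dosages → NaN statistics; empty site tables and monomorphic sites raise.
- K is validated symmetric and PSD to −10⁻⁸·λ_max; eigenvalues are clipped at
  0.
- Ties: average ranks in the inverse-normal transform; smaller dosage in the
  caller; (chrom, pos) ordering in tranche sweeps and signal indexing.
- The caller guards log(0) at ε = 0 with a 10⁻¹² floor, so error-free
  simulations remain exact in the argmax.

## 8. Known limitations

- No INDELs or structural variants anywhere (SNVs only, by design).
- No genome-build lift-over; cross-set comparison assumes one coordinate
  system.
- The LMM is single-variance-component, autosomal, with hard-call dosages;
  dosage uncertainty is not propagated.
- The proportion test is asymptotic (Yates-corrected z); exact tests are out
  of scope at the signal counts involved.
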