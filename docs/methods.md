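# Methods

This note documents the models, estimators, defaults and numerical choices
behind `tepopgen`, and what its synthetic-data experiments do and do not
establish about real data.

## Synthetic genotypes

Genotypes are drawn directly from inbreeding-adjusted Hardy–Weinberg
proportions rather than by simulating generations of selfing: for allele
frequency q and effective inbreeding F,

    P(het) = 2q(1−q)(1−F),   P(hom alt) = q² + q(1−q)F.

F is the only quantity the downstream analysis consumes, so direct draws make
the planted truth exact.  Two consequences are handled explicitly:

* **Feasibility of outbreeding.** P(hom) ≥ 0 requires
  F ≥ −min(q/(1−q), (1−q)/q).  For populations planted at F < 0, allele
  frequencies of non-purifying loci are truncated to the feasible interval
  [−F/(1−F), 1/(1−F)] so the planted F is exact at every locus; purifying
  loci keep their rare alleles and have F clamped at the bound instead (their
  heterozygosity is negligible either way).
* **The TE effect.** SNPs whose nearest TE belongs to a designated
  "TE-effect" superfamily, lies downstream (strand-aware) and within
  3,500 bp — the distance out to which TE-borne methylation and mutation
  effects are reported to reach — get
  F_eff = min(F, max(0, F − δ_TE)), i.e. a pure excess of heterozygosity
  that is strongest in selfing populations and absent in outcrossed ones.
  Default δ_TE = 0.6 with TE-effect superfamilies {Copia, Harbinger}.

Planted locus classes control the across-population frequency structure:
neutral loci follow a Balding–Nichols divergence model (default F_ST 0.05
around ancestral frequencies uniform on [0.25, 0.75] — the lower bound keeps
moderate outbreeding representable without truncation); balancing loci sit
at intermediate frequency (0.4–0.6) with near-zero divergence (F_ST 0.005);
divergent loci get per-population deviations standardized per locus so their
across-population frequency SD equals the configured value (default 0.35)
exactly up to boundary clipping; purifying loci are rare (ancestral MAF
0.02–0.10), low-divergence, and tagged 0-fold.  Default class mix: 80%
neutral, 5% balancing, 12% divergent, 3% purifying — the balancing and
divergent shares match the genome-wide outlier rates reported for the system
this generator emulates.

The TE landscape places, per superfamily, a configured number of TEs
(default 80 for each of 13 superfamilies) with lognormal lengths
(median ≈ 800 bp, clipped to [100, 30000]) uniformly on an 8 Mb chromosome,
strands uniform, overlaps permitted (TE islands).  At these defaults a random
SNP is ~3.5 kb from its nearest TE, matching the scale reported for the
emulated genome.  Fixture emission (VCF, GFF3, TSVs) is byte-deterministic in
the seed.

What the generator does **not** emulate: linkage (SNPs are unlinked by
construction, as in a one-SNP-per-RAD-locus panel), sequence content,
genotyping error and depth variation, non-reference TE insertions, any
mechanistic mutation or transposition process, and selection acting through
fitness.  Tests that pass on these fixtures therefore validate the
statistical machinery — estimator algebra, calibration, power against the
planted covariance structure — not the biological claims themselves.

## Estimators

* **Per-sample F_IS** = 1 − H_o/H_e, with H_o the sample's heterozygous
  fraction across loci and H_e the mean unbiased expected heterozygosity
  2p̂q̂·m/(m−1), p̂ from the sample's own population and m = 2n allele copies
  (Nei's small-sample correction; with the per-individual correction n/(n−1)
  the estimator is biased by ≈ +1/(2n) at F = 0).  Populations of size 1 get
  a missing value.
* **Per-locus θ** is Weir & Cockerham (1984), computed from per-population
  allele frequencies and observed heterozygote frequencies via the a/b/c
  variance components; slightly negative values at undifferentiated loci are
  expected and kept.
* **Relatedness clusters** are k-means (10 restarts, fixed seed) on sample
  scores of the leading PCs of the per-SNP standardized genotype matrix
  (scale √(2p(1−p))).  Defaults mirror the emulated panels (7 clusters for
  the European lineage, 6 for the North American); labels are renumbered by
  first appearance so runs are reproducible.

## PCA–Mahalanobis scan

Each SNP's standardized genotypes are regressed on the first K PC score
vectors (default K = 3, the study constant; the validation power experiment
uses K = 5 because its 6-deme design has five between-population axes).  The
K regression z-scores per SNP are combined into a squared Mahalanobis
distance under a minimum-covariance-determinant estimate of the z-score
covariance (empirical covariance for small panels).  Distances are rescaled
by the genomic inflation factor median(D²)/median(χ²_K) and converted to
p-values by the χ²_K tail; q-values are Benjamini–Hochberg (chosen over a
π₀-estimating q-value for its lack of tuning choices).  Outliers: q < 0.01.
Constant genotype columns are rejected (they should have been filtered).

## Bayesian F_ST decomposition

The logistic model F_ST(i,j) = 1/(1+exp(−(α_i+β_j))) with locus effects α_i
and population effects β_j; alt-allele counts at locus i in population j are
beta-binomial with mean μ_i (the ancestral frequency) and overdispersion set
by F_ST(i,j).  Priors: α ~ N(0, 1.8²), β ~ N(−1, 1.8²), μ uniform; a
reversible-jump move toggles each α with prior odds 10 for neutrality, using
the prior as the birth proposal (so proposal and prior cancel in the
acceptance ratio).  μ moves on the logit scale with the Jacobian term.
Proposal scales adapt blockwise toward ~30% acceptance during pilot blocks
(default 10 × 1,000 sweeps) and are frozen before burn-in (5,000) and
sampling (25,000 thinned by 10).  Reported per locus: posterior-mean α
(zero while excluded), posterior inclusion frequency p, log₁₀ posterior odds
log₁₀(p/(1−p)) with p clipped away from 0/1 by half a kept-sample, and a
Bayesian FDR (mean posterior neutrality probability of the selected set).
A locus effect is "significant" when log₁₀PO > 0.5 and the Bayesian FDR of
the selected set is ≤ 0.05.  Convergence is monitored by split-chain PSRF on
the β samples; PSRF > 1.1 logs a warning and is recorded in the run log.
Identical seeds give identical chains.

The desk-scale validation experiments use reduced chains (5 pilot blocks of
400, burn-in 1,500, 6,000 sweeps thinned by 5) on ~1,200-SNP simple random
subsamples; the subsample must preserve the mostly-neutral genome-wide
composition, since the decomposition absorbs differentiation into β when
outliers dominate.

## Classification and the purifying rule

Balancing = significant locus effect with α < 0; divergent = significant
locus effect with α > 0, or (in the default "combined" mode) a PCA outlier
(q < 0.01) whose θ exceeds the SNP-set median; neutral otherwise.  A
"bayescan-only" mode restricts calls to the decomposition arm.

Negative-α SNPs become purifying-selection candidates when (i) their MAF is
below the median MAF of neutral-class SNPs, and (ii) at the group level the
median MAF of 0-fold negative-α SNPs is below that of 4-fold ones — or the
SNP itself is 0-fold with MAF below the 4-fold median.  The group-level
reading is the default because per-SNP codon-fold information is sparse in
reduced-representation panels; a per-SNP variant sits behind
`group_level=False`.  Without fold annotation the decision falls back to (i)
alone with a logged warning.  Positive-α and neutral SNPs are never flagged.

## The heterozygosity model ladder

The response is the heterozygote count out of the cell's sample count, one
row per SNP × relatedness cluster, binomial with the cloglog link
log(−log(1−p)).  Relatedness enters as fixed cluster intercepts by default —
with few clusters and thousands of rows the fixed- and random-intercept fits
agree closely — and a one-variance-component random intercept is available
(`cluster_handling='random'`): joint penalized IRLS over (β, u) nested in a
1-D Laplace-approximate profile likelihood for σ².  Distance to the nearest
TE enters in kb, linear plus quadratic, both reported.

* Models 0a/0b (samples with F_IS > 0.6 / < 0.6):
  heterozygosity ~ sense + superfamily:sense + distance + distance², with
  CACTA as the superfamily reference level.  The sense main effect makes the
  pure interaction identifiable; the superfamily×sense coefficients are then
  per-sense contrasts against CACTA.
* **TE Effect membership**: a superfamily joins the H_TE group when its
  downstream contrast is significantly positive (Wald p < 0.05, uncorrected,
  matching the field's reporting convention) in the inbred subset (0a) and
  not significantly positive in the outcrossed subset (0b).  The sense
  strata that count are configurable (default: downstream only).
* Model 1 (all samples): distance×TE-effect + TE-effect×sense +
  distance×sense.
* Models 2a/2b: F_IS × selection + sense × selection on the H_TE and H_0
  subsets; F_IS enters as the mean per-sample value of the cell's samples
  (the aggregation is a package choice).
* Model 3 (independent outcrossing lineage): TE-effect + sense, fitted
  separately on the F_IS > −0.3 and F_IS < −0.3 subsets to separate mating
  system from demography.

Numerical choices: IRLS to tolerance 1e-10 (max 200 iterations); aliased
design columns are dropped by pivoted QR and reported; |coefficient| > 15 on
the linear scale is treated as separation and triggers a warning plus a
Firth-style weakly ridge-penalized refit (λ = 1e-3 on the IRLS information).
The analysis-of-deviance table is type II: each term is tested by likelihood
ratio against the model containing all terms that do not contain it; the
statistic reported is the deviance drop per degree of freedom.

**Specificity of the membership rule.**  With 12 non-reference superfamilies
tested at an uncorrected two-sided 5% level (positive direction ≈ 2.5% per
family), the probability that *no* superfamily enters the group when no
effect exists has a nominal ceiling of 0.975¹² ≈ 0.74.  On the validation
fixtures the observed empty-set rate is ~85% — higher than nominal because
Wald tests on the low heterozygote counts of strongly inbred subsets are
conservative — so an occasional one-superfamily false positive is an
expected behaviour of the uncorrected rule, not a defect of the fit; users
who need exact-set specificity should correct the membership tests for
multiplicity (and accept the corresponding loss of power).

## Cross-lineage comparison, enrichment, essentiality

Outlier proportions are computed per superfamily × orientation stratum
(upstream/downstream; strata with no SNPs omitted, fewer than 5 flagged
low-confidence) and correlated between lineages by Pearson's r over
superfamilies present in both (at least 3 required).  Shared outliers are
matched by chromosome and position.  GO enrichment is a one-sided
hypergeometric (Fisher) test per term at the gene level (SNPs deduplicated
to genes to avoid pseudo-replication; a SNP-level switch exists), classic
independent-term semantics with BH correction, terms with fewer than two
foreground genes skipped; the universe is the background set with the
foreground folded in.  Gene essentiality (family copy number, Ka/Ks) is
compared across selection class × orientation by two-way type-II ANOVA on
log1p-transformed responses (raw scale available).

## Validation battery (scripts/acceptance.py, tests/test_acceptance.py)

All experiments regenerate their inputs from a seed and run in minutes on
one CPU; sizes were fixed as the package's desk-scale study designs:

| experiment | design |
|---|---|
| F_IS recovery | 6 pops × 20 samples × 3,000 neutral SNPs, F ∈ {−0.3, 0, 0.3, 0.6, 0.9}; max |error| ≤ 0.05 |
| nearest-TE oracle | 200 random instances (up to 10³ SNPs × 10³ TEs, dense coordinates for ties/containment), exact agreement with a per-SNP linear scan |
| scan calibration | 5,000 structureless SNPs (F = 0, shared frequencies), 60 samples; λ_GC ∈ [0.8, 1.2], ≤ 2% at q < 0.01; classifier ≤ 5% calls on a 1,200-SNP subsample |
| scan power | 5,000 SNPs, 12% divergent (SD 0.35), 6 pops × 24 samples; PCA arm (K = 5) ≥ 80% at q < 0.01, decomposition arm ≥ 70% with α > 0 and log₁₀PO > 0.5 |
| purifying rule | constructed branch-covering cases vs scalar hand evaluation, exact |
| GLM oracle | three fixed datasets, IRLS vs BFGS + Newton refinement ≤ 1e-6; intercept-only closed form ≤ 1e-10 |
| TE-Effect recovery | 50 seeds × (1,734 SNPs, 6 pops × 8 samples, F = 0.8/0.0, δ = 0.6): planted pair recovered; 50 null seeds (δ = 0): empty-set rate reported (see the specificity ceiling above) |
| Fisher oracle | all hypergeometric tables with margins ≤ 50 vs explicit log-factorial tail summation |
| cross-lineage | 4-point hand-computed Pearson r (−1) to 1e-12; 50 seed-pairs of lineages sharing a planted per-superfamily signature profile, matched-stratum r > 0 |

## Known limitations

* The decomposition's priors and desk-scale chain lengths are calibrated for
  panels of 10³–10⁴ unlinked SNPs and a handful of populations; very large
  panels need the full-length chain settings (the defaults of
  `MCMCSettings`) and proportionally more time.
* The PCA scan's power depends on K relative to the true number of
  between-population axes; K below it leaves differentiation on uncaptured
  axes invisible to the Mahalanobis statistic.
* The random-intercept option is a Laplace/PQL-style approximation with a
  single variance component, adequate for sign and magnitude checks against
  the fixed-intercept fit, not a full GLMM.
* Sense conventions differ between annotation pipelines; both the
  strand-aware default and the genomic-orientation mode are provided, and
  nearest-only attribution inside TE islands can mask effects of the
  second-nearest TE.
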