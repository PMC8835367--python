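# Methods

This note documents the models implemented in grainmap, the choices made
where the design was genuinely open, and what the synthetic panel does and
does not emulate.

## Genotypes and filtering

Input VCFs are reduced to biallelic SNPs (multi-allelic and indel records
are skipped and counted, not split). Variants are filtered to MAF >= 5% and
missing rate <= 20% (both configurable); surviving missing calls are
imputed by the per-variant mode, ties broken toward the smaller dosage.
Mode imputation preserves the allele-frequency spectrum at desk scale and
keeps the package free of a reference-panel imputation dependency; the
pre-imputation missingness mask is retained so haplotype calling can leave
affected materials unassigned instead of trusting imputed calls.
Coordinates are 1-based inclusive everywhere; variant ids follow the
`chr<NN>_<pos>` convention when the VCF ID field is empty.

## Phenotype statistics

Broad-sense heritability is the entry-mean one-way random-effects ANOVA
estimate within one environment:

    sigma_G^2 = (MS_between - MS_within) / r,   H^2 = sigma_G^2 / (sigma_G^2 + MS_within / r)

with r the mean replicate count, clamped to [0, 1]. No formula is attached
to the reference heritability table this package reproduces the mean row
of, so the standard entry-mean estimator was chosen; it is invariant to
per-environment affine rescaling, which the tests check. Requirements: >= 2
replicates for >= 10 materials; a single-replicate design is rejected
because the between/within decomposition is undefined.

Normality uses the one-sample Kolmogorov-Smirnov test against a normal with
the sample's own moments (>= 8 values required). Trait correlations are
pairwise-complete Pearson r on per-material means; entries with < 3
complete pairs are NaN. Mahalanobis distances between group centroids use
the pooled within-group covariance and are non-negative by construction;
canonical variates are the eigenvectors of Sw^-1 Sb ordered by eigenvalue.

## Kinship, PCA, LD

Kinship is VanRaden's genomic relationship matrix, Z Z' / (2 sum p(1-p))
with Z the dosage matrix centered at 2p. PCA operates on centered dosage
with a fixed sign convention (largest-magnitude loading positive). LD is
genotypic r^2 — the squared Pearson correlation of dosage vectors — which
coincides with haplotype r^2 on inbred material and requires no phasing.
The decay curve averages r^2 in contiguous 5-kb bins; the decay distance is
the first point where the binned mean falls to half the curve's *maximum
bin mean* (not the r^2 at distance zero), linearly interpolated between bin
midpoints; a curve that never reaches half-maximum is reported as
unresolved (>= the scan range) rather than extrapolated. An optional
per-bin subsampling cap (seeded) bounds runtime on dense panels.

## Mixed-model scan

The null model per trait x environment is y = Xb + g + e with
g ~ N(0, sigma_g^2 K). REML estimation is one-dimensional on the eigenbasis
of K over h = sigma_g^2 / (sigma_g^2 + sigma_e^2): a 41-point coarse grid
(the profiled REML surface can be multimodal) followed by bounded local
refinement (xatol 1e-8). An optimum within 1e-4 of the h = 0 boundary is
accepted as sigma_g^2 = 0 with a warning. Covariates default to an
intercept plus the top 3 PCs (the reference analysis uses "PCA scores"
without stating k; 3 is the common choice and is configurable).

The scan fixes the variance ratio from the null fit (P3D/EMMAX), whitens
y, X and all dosage columns with D^-1/2 U', and tests each SNP by ordinary
regression in the whitened space with the residual variance re-estimated
per SNP (Wald t, two-sided). Consequences checked by tests: at h = 0 the
scan equals OLS to better than six significant digits, and at any h it
equals a brute-force GLS with explicit covariance inversion. Monomorphic
variants are skipped and logged. PVE is the standard effect-variance share,
100 * effect^2 * Var(dosage) / Var(y); no definition is attached to the
reference tables, and this is the conventional one.

Significance is Bonferroni at alpha = 0.1 over the number of variants
scanned. The effective test count is configurable because dense panels
with strong LD motivate smaller effective counts; the default is the
conservative literal count.

## QTL construction

Significant SNPs spawn +/- decay-distance windows (default 125 kb, the
panel-appropriate convention; the configurable default deliberately follows
the applied value rather than the measured ~65 kb, since downstream
interval arithmetic is what the package reproduces). Windows merge when
they overlap *or touch* (end + 1 = start): touching windows from adjacent
SNPs are one association signal, and treating them otherwise would split
QTLs on a 1-bp technicality. Merging is idempotent; intervals are built
from all significant SNPs, not only peaks, which is how merged spans wider
than a single +/-125 kb window arise. Cross-environment identity is span
overlap of the merged per-environment detections; naming is
`q<TRAIT><chrom>` with an `.k` suffix by ascending start only when a
trait x chromosome carries several QTLs. The four importance criteria are
ORed: repeated across >= 2 environments; strict span overlap with a known
gene (abutting does not count); >= 3 significant member SNPs ("successive
peaks" is not defined quantitatively in the source material — a member-run
threshold, default 3, operationalizes it); peak PVE >= 10%.

## Haplotype screening

Group I is significant amino-acid/splicing SNPs, group II significant
promoter SNPs. The promoter window is 2 kb upstream of the TSS,
strand-aware and configurable — no definition of "promoter region" is
given in the source material. Haplotypes are genotype strings, not phased
haplotypes: homozygote base letters with IUPAC codes at heterozygous sites,
so a heterozygote class (e.g. `WRYYK`) is its own class; materials missing
a call at any grouped SNP are excluded from that gene's analysis rather
than imputed. Classes with < 6 members are dropped. Two retained classes
are compared by Welch's t-test (robust to unequal class variances; the
source says only "t-test"), three or more by one-way ANOVA; compact
letters come from all pairwise Welch tests with Bonferroni correction at
the configured alpha (0.01), computed as maximal cliques of the
not-significantly-different graph. Candidate genes are those with a
significant haplotype test in at least the configured number of
environments; judging "functional correlation" is left to the reader — the
output carries each gene's annotation text.

## Allele combinations

A gene's alleles pool its significant SNPs across *all* traits and
environments, so one partition serves every analysis; labels A, B, C ... go
by descending class size. The < 6-member retention rule is applied at the
allele level as well as the combination level, mirroring the haplotype
rule. Rankings use per-material means over environments and replicates.

The additivity gap compares each combination's observed mean with the
additive prediction from marginal allele deviations, with a seeded
bootstrap (500 resamples over materials) percentile interval. Two caveats
are inherent to the statistic and documented here deliberately. First,
marginal deviations absorb part of any true interaction: with interacting
allele frequencies f1, f2 (independent assortment), only a factor
(1-f1)(1-f2) of a planted cell effect survives in the gap, so the gap is a
lower bound on interaction magnitude; it recovers most of the effect only
when the interacting combination is rare. Second, when an allele class
co-occurs exclusively with one partner allele (common on single-chromosome
panels with many rare classes in LD), its gap reflects the partner's
marginal effect — confounding, not epistasis. The null-coverage test
therefore uses an independently assorted panel with adequately sized
cells, and the family-wise "all intervals cover zero" check uses
Bonferroni-adjusted per-interval levels so its coverage is >= 95% by
construction.

## Synthetic panel

The generator emulates the features downstream stages depend on, at the
scale the test suite uses (400 materials, 2,000 SNPs over 2 Mb unless a
test states otherwise — sizes chosen so the whole suite runs in minutes on
one CPU):

- **LD structure** by founder mosaics: each material copies segments from a
  20-founder pool with Poisson switch points (default 1e-5 per bp).
  Short-range mean r^2 plateaus near 1/n_founders and decays with distance;
  the decay distance falls as the switch rate rises, which is the property
  the LD stage needs. This is not a coalescent model: allele-frequency
  spectra, recombination hotspots and deep population history are not
  represented.
- **Inbreeding**: materials are fully homozygous by default (dosage in
  {0, 2}), matching inbred cultivars; a heterozygosity fraction exists
  solely to exercise IUPAC haplotype handling.
- **Causal architecture**: named genes carry large-effect SNPs of chosen
  consequence classes (including antagonistic GL/GW pleiotropy at one SNP,
  reproducing the negative GL-GW correlation), over a 100-SNP polygenic
  background (effect SD 0.02 trait units). Genetic values are exactly
  dosage x effects.
- **Phenotypes**: value = trait baseline + genetic value + per-environment
  shift (SD 0.15) + noise, 4 environments x 3 replicates. Per-environment
  noise is set so the *entry-mean* heritability equals the configured
  target — the same basis the ANOVA estimator uses, so recovery is exact in
  expectation; the default targets are the published per-environment
  values. A target of exactly 0 drops the genetic term. There is no
  genotype-by-environment interaction and no population structure: the
  emulated panel is panmictic, and the tests assert the *absence* of PC
  clustering accordingly. Passing tests therefore show correctness of the
  statistical machinery on a well-specified panel, not robustness to
  structure, GxE, or ascertainment effects in real resequencing data.

## Numerical conventions

Ties in the per-variant imputation mode go to the smaller dosage; QTL peak
ties (equal p) go to the smaller position; allele-label ties (equal class
size) are broken lexicographically by haplotype string; PCA signs are fixed
by the largest-magnitude loading. Degenerate inputs fail loudly:
constant phenotypes, monomorphic-only kinship, singular pooled covariance
in CVA, and zero planted genetic variance with a positive heritability
target all raise errors rather than returning NaNs. The REML surface is
profiled, so scans are deterministic; the only stochastic outputs
(bootstrap intervals, subsampled LD bins) take explicit seeds.

## Known limitations

Genotype imputation is mode-based, not reference-panel-based; the
Bonferroni effective-test count is left to the user on dense panels;
"functional correlation" of candidates is not automated; the additivity gap
under-measures interactions absorbed by marginals (above); and the
synthetic panel's LD ceiling (1/n_founders) is lower than real short-range
LD in selfing species, which only matters if one tries to read absolute
r^2 levels — distances and orderings are the validated quantities.
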