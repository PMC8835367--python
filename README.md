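# grainmap

Post-variant-calling analysis pipeline for rice grain-shape GWAS panels:
mixed-linear-model association scans, LD-decay estimation, QTL interval
construction and merging, candidate-gene haplotype screening, and multi-gene
allele-combination analysis — the chain a quantitative geneticist runs
between "I have filtered SNPs and replicated phenotypes" and "here are my
candidate genes and the allele stacks worth breeding toward".

It is aimed at researchers working with inbred diversity panels (the
motivating system is several hundred indica rice cultivars measured for
grain length GL, width GW, length/width ratio GLWR, circumference GC and
area GS across 2 sites x 2 years), and at method developers who need a
fully synthetic but LD-structured test bed: the package ships a generator
that emulates such a panel end to end, so every stage is testable without
any external download.

## The models at the core

**Association scan (MLM, EMMA/P3D).** For each trait x environment, the
per-material means y follow

    y = Xb + g + e,    g ~ N(0, sigma_g^2 K),    e ~ N(0, sigma_e^2 I)

with K the VanRaden genomic relationship matrix and X an intercept plus top
principal components. The heritability parameter h = sigma_g^2 /
(sigma_g^2 + sigma_e^2) is estimated once per scan by REML on the
eigenbasis of K; each SNP is then tested by GLS with the variance ratio
held fixed (the P3D/EMMAX approximation), giving the per-SNP effect, SE,
Wald p, and PVE(%) = 100 * effect^2 * Var(dosage) / Var(y). Significance is
Bonferroni: p < alpha / n_tests with alpha = 0.1 by default.

**LD decay.** r^2 is the squared Pearson correlation of dosage vectors,
averaged in 5-kb distance bins; the decay distance is where the binned
curve first falls to half its maximum (linear interpolation between bins).

**QTL calling.** Each significant SNP spawns the interval pos +/- 125 kb
(the configured decay distance); overlapping or touching intervals merge;
detections from different environments whose spans overlap are one QTL,
named `q<TRAIT><chrom>[.k]`. A QTL is *important* if it (1) repeats across
environments, (2) overlaps a reported gene, (3) has a run of >= 3
significant member SNPs, or (4) has peak PVE >= 10%.

**Haplotype screening.** Inside important QTLs, significant SNPs are
grouped per gene: group I (amino-acid/splicing changes) and group II
(promoter). Materials get genotype-string haplotypes over the grouped SNPs
(IUPAC codes for heterozygotes, e.g. `WRYYK`); classes with fewer than 6
members are dropped; retained classes are compared by Welch's t-test (2
classes) or one-way ANOVA (>= 3) with a compact-letter display at p < 0.01.

**Allele combinations.** Each gene's *allele* partition pools its
significant SNPs over all traits and environments (so it is identical in
every analysis); materials are labeled by their combination across genes
(e.g. `GS3A-GW5B`), combinations with < 6 materials are discarded, the
rest are ranked per trait with ANOVA + letters, and departure from
additivity is quantified as

    gap(c) = mean(c) - (grand mean + sum of per-gene allele deviations)

with a seeded bootstrap interval per combination.

## Worked example

```bash
python examples/02_ld_and_gwas.py
```

prints (seed 1):

```
LD half-decay distance: 38.7 kb (first bin mean r^2 = 0.051)
Null-model REML: sigma2_g/(sigma2_g+sigma2_e) = 0.773
Scanned 1982 SNPs; 11 pass Bonferroni (alpha 0.1).
Top SNP chr01_123604: effect +0.533 mm per alt allele, SE 0.030, p 1.66e-51, PVE 54.6%
Planted causal SNP was chr01_123604 (true effect +0.55 mm) — recovered.
QTL qGL1: 1:1-505874, peak chr01_123604, criteria ['successive_peaks', 'pve_ge_threshold']
```

Reading this: pairwise r^2 halves within ~39 kb, so a +/-125 kb window
comfortably covers the region tagged by any significant SNP; the null model
attributes 77% of variance of grain length to the kinship term; the scan
ranks the planted major gene first with an effect estimate (+0.533 mm per
alt allele) close to the simulated truth (+0.55), and the merged interval
around it passes two of the four importance criteria.
`examples/01_phenotypes_and_heritability.py` (heritability table,
correlations, bimodality) and `examples/03_haplotypes_and_combinations.py`
(candidate genes, allele stacks) narrate the other stages.

The same pipeline is scriptable from a shell:

```bash
grainmap simulate --seed 1 --out panel/
grainmap run --vcf panel/genotypes.vcf --pheno panel/phenotypes.tsv \
             --genes panel/genes.gff3 --effects panel/effects.tsv --out out/
```

writing per-stage TSVs (`heritability.tsv`, `assoc_*.tsv`, `qtls.tsv`,
`candidates.tsv`, `combinations_*.tsv`); `gwas`, `qtl`, `haplotype` and
`combos` run individual stages on the association tables of a previous run.

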