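"""Candidate-gene haplotype screening and allele-combination analysis.

Runs the full pipeline on the default synthetic panel: group I/II SNP
classification inside important QTLs, haplotype tests with compact letters,
then the two-gene allele-combination ranking with additivity gaps.
"""

from grainmap.pipeline import (PipelineConfig, run_candidate_screen,
                               run_combos_for_genes, run_gwas, run_qtl)
from grainmap.simulate import simulate_dataset

ds = simulate_dataset(seed=1)
cfg = PipelineConfig()

scans = run_gwas(ds.genotypes, ds.phenotypes, cfg)
qtls = run_qtl(scans, ds.genotypes, cfg)
candidates, tests = run_candidate_screen(qtls, scans, ds.genes,
                                         ds.genotypes, ds.phenotypes, cfg)

print("== Candidate genes (significant haplotype test in >=1 environment) ==")
for c in candidates:
    print(f"  {c.gene_id}: group {'/'.join(c.groups)}, "
          f"significant in {len(c.environments)}/4 environments, traits {c.traits}")
print("Group I = significant coding/splicing SNPs; group II = significant "
      "promoter SNPs. Both planted genes should appear.\n")

genes = [g for g in ds.genes if g.gene_id in {c.gene_id for c in candidates}]
result = run_combos_for_genes(genes, scans, ds.genotypes, ds.phenotypes, cfg,
                              traits=["GL"])
combos = result["combinations"]
print(f"== Allele combinations: {combos.n_observed} observed of "
      f"{combos.n_possible} possible; {len(combos.counts)} retained (n >= 6) ==")
ranking = result["rankings"]["GL"].head(5)
print(ranking.round(3).to_string(index=False))
print("The letter column is a compact-letter display: combinations sharing "
      "no letter differ at p < 0.01. The top and bottom rows are the extreme "
      "combinations a breeder would pyramid toward (or away from).")
gaps = result["additivity"]["GL"]
n_cover = int(((gaps["ci_low"] <= 0) & (gaps["ci_high"] >= 0)).sum())
print(f"\nAdditivity gaps: {n_cover}/{len(gaps)} bootstrap intervals cover 0.")
print("The planted model is additive, but on a single-chromosome panel many "
      "rare allele classes co-occur with only one partner allele, and such "
      "confounded cells show nonzero gaps without real epistasis — compare "
      "the clean independent-assortment design in the test suite, where all "
      "intervals cover 0.")
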