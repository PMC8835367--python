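"""End-to-end orchestration: GWAS per trait x environment, QTL calling,
candidate-gene screening and allele-combination analysis, driven by one
config object.  The CLI is a thin wrapper around these functions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from . import combos as combos_mod
from . import gwas, popstruct, qtl as qtl_mod
from .core import GeneModel, GenotypeMatrix, GrainmapError
from .haplotypes import (CandidateGene, classify_snps, call_haplotypes,
                         haplotype_test, screen_candidates)
from .io import material_means

log = logging.getLogger("grainmap")


@dataclass
class PipelineConfig:
    maf_min: float = 0.05
    missing_max: float = 0.20
    alpha: float = 0.1
    n_tests: int | None = None  # effective test count for Bonferroni; default = SNPs scanned
    ld_decay_kb: float = 125.0
    pve_threshold: float = 10.0
    min_group_n: int = 6
    haplotype_alpha: float = 0.01
    promoter_kb: float = 2.0
    n_pcs: int = 3
    min_peak_run: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise GrainmapError(f"unknown config keys {bad}; allowed: {sorted(known)}")
        return cls(**raw)

    @property
    def decay_bp(self) -> int:
        return int(self.ld_decay_kb * 1000)


def align_phenotype(pheno: pd.DataFrame, geno: GenotypeMatrix, trait: str,
                    environment: str) -> np.ndarray:
    """Per-material trait means for one environment, aligned to the genotype
    matrix's material order (materials without a phenotype are fatal)."""
    means = material_means(pheno, trait, environment)
    missing = [m for m in geno.materials if m not in means.index]
    if missing:
        raise GrainmapError(
            f"{len(missing)} materials lack {trait}/{environment} phenotypes "
            f"(first: {missing[0]})"
        )
    return means.loc[geno.materials].to_numpy(dtype=float)


def run_gwas(geno: GenotypeMatrix, pheno: pd.DataFrame, config: PipelineConfig,
             traits=None, environments=None) -> dict[tuple[str, str], list[gwas.AssociationRecord]]:
    """MLM scan for every available trait x environment.

    Kinship, its eigendecomposition and the PC covariates are computed once
    and shared across scans (the P3D practice).
    """
    traits = list(traits) if traits is not None else sorted(pheno["trait"].unique())
    environments = (list(environments) if environments is not None
                    else sorted(pheno["environment"].unique()))
    K = popstruct.kinship(geno)
    pcs = popstruct.pca(geno, k=config.n_pcs) if config.n_pcs > 0 else None

    scans: dict[tuple[str, str], list[gwas.AssociationRecord]] = {}
    for trait in traits:
        for env in environments:
            sub = pheno[(pheno["trait"] == trait) & (pheno["environment"] == env)]
            if sub.empty:
                continue
            y = align_phenotype(pheno, geno, trait, env)
            fit = gwas.fit_null_model(y, K, covariates=pcs)
            records = gwas.scan(geno, y, fit, trait=trait, environment=env)
            gwas.significant_snps(records, alpha=config.alpha, n_tests=config.n_tests)
            scans[(trait, env)] = records
            log.info("gwas %s/%s: %d SNPs scanned, %d significant (h2=%.3f)",
                     trait, env, len(records),
                     sum(r.is_significant for r in records), fit.h2)
    if not scans:
        raise GrainmapError("no trait x environment combinations with phenotype data")
    return scans


def run_qtl(scans, geno: GenotypeMatrix, config: PipelineConfig,
            known: pd.DataFrame | None = None,
            chrom_lengths: dict[str, int] | None = None) -> dict[str, list[qtl_mod.Qtl]]:
    """Merge significant SNPs into named QTLs per trait and keep the
    important ones (four-criterion filter)."""
    chrom_lengths = chrom_lengths or geno.chrom_lengths()
    by_trait: dict[str, list[gwas.AssociationRecord]] = {}
    for (trait, _env), records in scans.items():
        by_trait.setdefault(trait, []).extend(r for r in records if r.is_significant)
    out: dict[str, list[qtl_mod.Qtl]] = {}
    for trait, sig in sorted(by_trait.items()):
        detections = qtl_mod.detect_qtls(sig, config.decay_bp, chrom_lengths)
        named = qtl_mod.name_qtls(detections, trait)
        qtl_mod.annotate_known_genes(named, known)
        important = qtl_mod.filter_important(named, pve_threshold=config.pve_threshold,
                                             min_peak_run=config.min_peak_run)
        out[trait] = important
        log.info("qtl %s: %d significant SNPs -> %d QTLs -> %d important",
                 trait, len(sig), len(named), len(important))
    return out


def genes_in_qtl(q: qtl_mod.Qtl, genes: list[GeneModel]) -> list[GeneModel]:
    return [g for g in genes
            if qtl_mod._chrom_label(g.chrom) == qtl_mod._chrom_label(q.chrom)
            and g.start <= q.end and g.end >= q.start]


def run_candidate_screen(qtls_by_trait, scans, genes: list[GeneModel],
                         geno: GenotypeMatrix, pheno: pd.DataFrame,
                         config: PipelineConfig) -> tuple[list[CandidateGene], pd.DataFrame]:
    """Haplotype analysis of every gene with grouped SNPs inside an important
    QTL; returns the candidate list and a tidy per-test table."""
    genes_by_id = {g.gene_id: g for g in genes}
    environments = sorted({env for (_t, env) in scans})

    # per trait x env significant variant ids
    sig_ids: dict[tuple[str, str], set] = {
        key: {r.variant_id for r in records if r.is_significant}
        for key, records in scans.items()
    }

    gene_results: dict[str, dict] = {}
    rows = []
    for trait, qtls in qtls_by_trait.items():
        for q in qtls:
            for gene in genes_in_qtl(q, genes):
                union_sig = set().union(*(sig_ids.get((trait, env), set())
                                          for env in environments))
                grouped = [gs for gs in classify_snps(gene, union_sig) if gs.variant_ids]
                if not grouped:
                    continue
                vids = sorted({v for gs in grouped for v in gs.variant_ids})
                assignment = call_haplotypes(gene.gene_id, vids, geno,
                                             min_group_n=config.min_group_n)
                info = gene_results.setdefault(gene.gene_id, {"groups": [], "tests": []})
                info["groups"].extend(gs.group for gs in grouped)
                for env in environments:
                    if (trait, env) not in scans:
                        continue
                    res = haplotype_test(assignment, pheno, trait, env,
                                         alpha=config.haplotype_alpha)
                    info["tests"].append(res)
                    rows.append({
                        "qtl": q.name, "gene": gene.gene_id,
                        "groups": "".join(sorted({gs.group for gs in grouped})),
                        "trait": trait, "environment": env, "test": res.test,
                        "p": res.p,
                        "classes": ";".join(f"{h}:{n}" for h, n in sorted(res.class_counts.items())),
                        "letters": ";".join(f"{h}:{res.letters.get(h, '')}"
                                            for h in sorted(res.class_counts)),
                    })
    candidates = screen_candidates(gene_results, genes_by_id,
                                   alpha=config.haplotype_alpha)
    table = pd.DataFrame(rows, columns=["qtl", "gene", "groups", "trait", "environment",
                                        "test", "p", "classes", "letters"])
    return candidates, table


def run_combos_for_genes(genes: list[GeneModel], scans, geno: GenotypeMatrix,
                         pheno: pd.DataFrame, config: PipelineConfig,
                         traits=None) -> dict:
    """Allele-combination analysis for the given genes.

    Pools each gene's significant SNPs over every scan (all traits and
    environments), defines alleles, assigns combinations (n >= min_group_n)
    and, per trait, ranks extremes and computes additivity gaps.
    """
    pooled: dict[str, set] = {g.gene_id: set() for g in genes}
    for (_trait, _env), records in scans.items():
        for r in records:
            if not r.is_significant:
                continue
            for g in genes:
                if g.snp_effects.get(r.variant_id) is not None or \
                        (qtl_mod._chrom_label(g.chrom) == qtl_mod._chrom_label(r.chrom)
                         and (g.contains(r.pos) or g.in_promoter(r.pos))):
                    pooled[g.gene_id].add(r.variant_id)
    definitions = []
    for g in genes:
        if not pooled[g.gene_id]:
            raise GrainmapError(f"gene {g.gene_id} has no significant SNPs in any scan")
        definitions.append(combos_mod.define_alleles(g.gene_id, pooled[g.gene_id], geno,
                                                     min_n=config.min_group_n))
    combinations = combos_mod.assign_combinations(definitions, min_n=config.min_group_n)
    traits = list(traits) if traits is not None else sorted(pheno["trait"].unique())
    rankings, gaps = {}, {}
    for trait in traits:
        if len(combinations.counts) >= 2:
            rankings[trait] = combos_mod.rank_extremes(combinations, pheno, trait,
                                                       alpha=config.haplotype_alpha)
            gaps[trait] = combos_mod.additivity_gap(combinations, pheno, trait,
                                                    seed=config.seed)
    return {"definitions": definitions, "combinations": combinations,
            "rankings": rankings, "additivity": gaps}
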