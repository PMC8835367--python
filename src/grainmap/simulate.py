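"""Synthetic rice-panel generator.

Emulates the features of the study population that the downstream stages
depend on: several hundred inbred (homozygous) indica materials, linkage
disequilibrium decaying over tens of kb, a handful of large-effect causal
genes on a polygenic background, and replicated phenotypes from 2 sites x
2 years with per-environment broad-sense heritabilities in the ranges the
study reports.

Genotypes are founder-mosaic copies: each material's haplotype is stitched
from a small founder pool with recombination switch points placed as a
Poisson process along the chromosome, which gives tunable LD decay without
a coalescent simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneModel, GenotypeMatrix, GrainmapError, Variant, variant_id

#: Default environments: 2 sites (Ezhou, Gongan) x 2 years.
DEFAULT_ENVS = ("2017EZ", "2017GA", "2018EZ", "2018GA")

#: Per-environment broad-sense heritability targets per trait (the study's
#: printed per-environment values; entry-mean basis).
DEFAULT_H2 = {
    "2017EZ": {"GL": 0.561198, "GW": 0.587232, "GLWR": 0.816784, "GC": 0.435194, "GS": 0.102882},
    "2017GA": {"GL": 0.790264, "GW": 0.842533, "GLWR": 0.863557, "GC": 0.750632, "GS": 0.403186},
    "2018EZ": {"GL": 0.417942, "GW": 0.593973, "GLWR": 0.780337, "GC": 0.439132, "GS": 0.220128},
    "2018GA": {"GL": 0.682506, "GW": 0.755747, "GLWR": 0.802726, "GC": 0.651486, "GS": 0.519685},
}

#: Trait baselines for indica grains (mm, mm, ratio, mm, mm^2).
TRAIT_BASE = {"GL": 8.5, "GW": 2.6, "GLWR": 3.2, "GC": 20.0, "GS": 17.0}


@dataclass(frozen=True)
class CausalSpec:
    """One planted causal gene effect: additive ``effect`` (trait units per
    alt allele) carried by a SNP of the given consequence class."""

    gene_id: str
    trait: str
    effect: float
    consequence: str = "amino_acid_change"


@dataclass
class SimulationConfig:
    n_materials: int = 400
    n_variants: int = 2000
    chrom_length_bp: int = 2_000_000
    chrom: str = "1"
    n_founder_haplotypes: int = 20
    copying_switch_rate: float = 1e-5  # expected switches per bp
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_genes: int = 8
    gene_length_bp: int = 6000
    promoter_bp: int = 2000
    causal: tuple[CausalSpec, ...] = (
        # a GS3-like major grain-length gene, antagonistic on GL and GW
        CausalSpec("GeneA", "GL", 0.55, "amino_acid_change"),
        CausalSpec("GeneA", "GW", -0.12, "amino_acid_change"),
        # a GW5-like grain-width gene with a promoter causal SNP
        CausalSpec("GeneB", "GW", 0.25, "promoter"),
        CausalSpec("GeneB", "GL", -0.20, "promoter"),
        CausalSpec("GeneA", "GLWR", 0.30, "amino_acid_change"),
        CausalSpec("GeneB", "GLWR", -0.22, "promoter"),
        CausalSpec("GeneA", "GC", 0.80, "amino_acid_change"),
    )
    background_n_snps: int = 100
    background_sd: float = 0.02  # per-allele background effect SD, trait units
    h2_per_env: dict = field(default_factory=lambda: {e: dict(v) for e, v in DEFAULT_H2.items()})
    envs: tuple[str, ...] = DEFAULT_ENVS
    n_reps: int = 3
    env_effect_sd: float = 0.15
    heterozygosity: float = 0.0  # fraction of materials with two independent haplotypes
    seed: int = 0

    def __post_init__(self):
        for name in ("n_materials", "n_variants", "chrom_length_bp", "n_founder_haplotypes", "n_reps"):
            if getattr(self, name) < 1:
                raise GrainmapError(f"{name} must be >= 1")
        for env, h2s in self.h2_per_env.items():
            vals = h2s.values() if isinstance(h2s, dict) else [h2s]
            for h2 in vals:
                if not (0 <= h2 < 1):
                    raise GrainmapError(f"h2 must be in [0, 1), got {h2} for {env}")

    def h2(self, env: str, trait: str) -> float:
        spec = self.h2_per_env[env]
        return spec[trait] if isinstance(spec, dict) else float(spec)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.trait for c in self.causal)) or ("GL",)


@dataclass
class CausalModel:
    """Planted truth: per-trait effect vectors over the variant axis and the
    resulting genetic values (dosage @ effects, exactly)."""

    causal_variants: dict  # (gene_id, trait) -> (variant_id, effect)
    effects: dict  # trait -> np.ndarray over variants
    genetic_values: pd.DataFrame  # materials x traits

    @property
    def traits(self) -> list[str]:
        return list(self.effects)


def _mosaic_haplotypes(founders: np.ndarray, positions: np.ndarray, n: int,
                       switch_rate: float, length_bp: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` mosaic haplotypes by copying founder segments with Poisson
    switch points at ``switch_rate`` per bp."""
    n_f, m = founders.shape
    out = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        n_sw = rng.poisson(switch_rate * length_bp)
        cuts = np.sort(rng.integers(1, length_bp + 1, size=n_sw))
        bounds = np.concatenate([[0], np.searchsorted(positions, cuts, side="right"), [m]])
        src = rng.integers(0, n_f, size=n_sw + 1)
        for k in range(n_sw + 1):
            out[i, bounds[k]:bounds[k + 1]] = founders[src[k], bounds[k]:bounds[k + 1]]
    return out


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Founder-mosaic diploid genotypes; fully inbred by default (the two
    haplotypes of a material identical, dosage in {0, 2})."""
    if config.copying_switch_rate <= 0:
        raise GrainmapError("copying_switch_rate must be > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    m, L = config.n_variants, config.chrom_length_bp
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=m, replace=False))
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    founders = (rng.random((config.n_founder_haplotypes, m)) < freqs).astype(np.int8)

    hap1 = _mosaic_haplotypes(founders, positions, config.n_materials,
                              config.copying_switch_rate, L, rng)
    if config.heterozygosity > 0:
        hap2 = _mosaic_haplotypes(founders, positions, config.n_materials,
                                  config.copying_switch_rate, L, rng)
        outbred = rng.random(config.n_materials) < config.heterozygosity
        hap2[~outbred] = hap1[~outbred]
    else:
        hap2 = hap1
    dosage = (hap1 + hap2).astype(np.int8)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    alt_idx = (ref_idx + alt_shift) % 4
    variants = [
        Variant(chrom=config.chrom, pos=int(p), ref=bases[r], alt=bases[a])
        for p, r, a in zip(positions, ref_idx, alt_idx)
    ]
    materials = [f"M{i:04d}" for i in range(config.n_materials)]
    return GenotypeMatrix(materials=materials, variants=variants, dosage=dosage,
                          missing=np.zeros_like(dosage, dtype=bool))


def simulate_gene_models(config: SimulationConfig, geno: GenotypeMatrix,
                         rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Place non-overlapping genes along the chromosome and tag the SNPs in
    each gene body with consequence classes (promoter-window SNPs are tagged
    ``promoter`` positionally).

    Each causal spec's gene is guaranteed at least one SNP of the required
    class: if the gene body / promoter window happens to contain none, the
    nearest eligible SNP is relabeled.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    L, G = config.chrom_length_bp, config.n_genes
    slot = L // G
    positions = geno.positions
    genes: list[GeneModel] = []
    for g in range(G):
        start = g * slot + (slot - config.gene_length_bp) // 2
        start = max(start, config.promoter_bp + 1)
        end = start + config.gene_length_bp - 1
        strand = "+" if g % 2 == 0 else "-"
        gene = GeneModel(
            gene_id=f"Gene{chr(ord('A') + g)}" if g < 26 else f"Gene{g}",
            chrom=config.chrom, strand=strand, start=start, end=end,
            promoter_bp=config.promoter_bp,
        )
        for j in np.nonzero((positions >= gene.start) & (positions <= gene.end))[0]:
            cls = rng.choice(["amino_acid_change", "splicing_change", "other"], p=[0.3, 0.1, 0.6])
            gene.snp_effects[geno.variants[j].id] = str(cls)
        plo, phi = gene.promoter_window()
        for j in np.nonzero((positions >= plo) & (positions <= phi))[0]:
            gene.snp_effects[geno.variants[j].id] = "promoter"
        genes.append(gene)

    by_id = {g.gene_id: g for g in genes}
    for spec in config.causal:
        gene = by_id.get(spec.gene_id)
        if gene is None:
            raise GrainmapError(f"causal spec names unknown gene {spec.gene_id}")
        if any(c == spec.consequence for c in gene.snp_effects.values()):
            continue
        # relabel the SNP nearest the relevant window so the class exists
        if spec.consequence == "promoter":
            lo, hi = gene.promoter_window()
        else:
            lo, hi = gene.start, gene.end
        center = (lo + hi) // 2
        j = int(np.argmin(np.abs(positions - center)))
        gene.snp_effects[geno.variants[j].id] = spec.consequence
    return genes


def plant_effects(geno: GenotypeMatrix, genes: list[GeneModel],
                  causal_spec) -> CausalModel:
    """Assemble per-trait additive effect vectors from the causal spec and
    compute exact genetic values (dosage @ effects).

    For each spec the carrier SNP is the gene's eligible SNP (matching
    consequence class) with MAF closest to 0.5 — deterministic, so two specs
    on the same gene and class share one SNP (supporting antagonistic
    pleiotropy, e.g. opposite-sign effects on GL and GW).
    """
    by_id = {g.gene_id: g for g in genes}
    maf = geno.maf()
    m = geno.n_variants
    effects: dict[str, np.ndarray] = {}
    causal_variants: dict = {}
    for spec in causal_spec:
        gene = by_id.get(spec.gene_id)
        if gene is None:
            raise GrainmapError(f"causal spec names unknown gene {spec.gene_id}")
        eligible = [vid for vid, cls in gene.snp_effects.items()
                    if cls == spec.consequence and vid in geno._index]
        if not eligible:
            raise GrainmapError(
                f"gene {spec.gene_id} has no variant of class {spec.consequence}"
            )
        vid = max(eligible, key=lambda v: (maf[geno.index_of(v)], v))
        j = geno.index_of(vid)
        effects.setdefault(spec.trait, np.zeros(m))
        effects[spec.trait][j] += spec.effect
        causal_variants[(spec.gene_id, spec.trait)] = (vid, spec.effect)

    gvals = {t: geno.dosage @ beta for t, beta in effects.items()}
    genetic_values = pd.DataFrame(gvals, index=geno.materials)
    return CausalModel(causal_variants=causal_variants, effects=effects,
                       genetic_values=genetic_values)


def add_polygenic_background(model: CausalModel, geno: GenotypeMatrix,
                             config: SimulationConfig,
                             rng: np.random.Generator | None = None) -> CausalModel:
    """Add small random effects at ``background_n_snps`` SNPs per trait (all
    configured traits, including any without a major gene)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    m = geno.n_variants
    traits = set(model.traits) | set(config.traits)
    effects = {t: model.effects.get(t, np.zeros(m)).copy() for t in traits}
    for t in sorted(traits):
        idx = rng.choice(m, size=min(config.background_n_snps, m), replace=False)
        effects[t][idx] += rng.normal(0.0, config.background_sd, size=len(idx))
    gvals = {t: geno.dosage @ beta for t, beta in effects.items()}
    return CausalModel(
        causal_variants=dict(model.causal_variants),
        effects=effects,
        genetic_values=pd.DataFrame(gvals, index=geno.materials),
    )


def simulate_phenotypes(geno: GenotypeMatrix, model: CausalModel,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Replicated multi-environment phenotypes in long format.

    value = baseline + genetic value + environment main effect + noise.
    The per-replicate noise SD per (trait, environment) is set so the
    entry-mean (replicate-averaged) broad-sense heritability equals the
    configured target: sigma_e^2 = n_reps * Var_G * (1 - h2) / h2.  For
    h2 = 0 the genetic term is omitted and the noise variance defaults to
    max(Var_G, 1) for scale.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    n, r = geno.n_materials, config.n_reps
    rows = []
    for trait in model.traits:
        g = model.genetic_values[trait].to_numpy()
        var_g = float(np.var(g))
        if var_g <= 1e-12 * max(1.0, float(np.mean(g)) ** 2):
            var_g = 0.0
        base = TRAIT_BASE.get(trait, 10.0)
        for env in config.envs:
            h2 = config.h2(env, trait)
            if h2 > 0 and var_g <= 0:
                raise GrainmapError(
                    f"target h2 {h2} for {trait}/{env} but planted genetic variance is 0"
                )
            env_shift = rng.normal(0.0, config.env_effect_sd)
            if h2 > 0:
                noise_sd = np.sqrt(r * var_g * (1.0 - h2) / h2)
                genetic = g
            else:
                noise_sd = np.sqrt(max(var_g, 1.0))
                genetic = np.zeros(n)
            for rep in range(1, r + 1):
                vals = base + genetic + env_shift + rng.normal(0.0, noise_sd, size=n)
                rows.append(pd.DataFrame({
                    "material": geno.materials, "trait": trait, "environment": env,
                    "replicate": rep, "value": vals,
                }))
    pheno = pd.concat(rows, ignore_index=True)
    if (pheno.loc[pheno["trait"] == "GLWR", "value"] <= 0).any():
        # GLWR is a ratio and must stay positive; the default scales keep it
        # far from 0, so this only triggers on pathological configs
        raise GrainmapError("simulated GLWR values went non-positive; reduce noise or effects")
    return pheno


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    genes: list[GeneModel]
    causal: CausalModel
    phenotypes: pd.DataFrame


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Full synthetic study: genotypes, gene models, planted causal model
    with polygenic background, and replicated phenotypes.  Deterministic
    under (config, seed)."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    geno = simulate_genotypes(config)
    genes = simulate_gene_models(config, geno)
    causal = plant_effects(geno, genes, config.causal)
    causal = add_polygenic_background(causal, geno, config)
    pheno = simulate_phenotypes(geno, causal, config)
    return SimulatedDataset(config=config, genotypes=geno, genes=genes,
                            causal=causal, phenotypes=pheno)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write VCF, GFF3, effects TSV, phenotype TSV and the true causal model
    (ground truth for tests) to ``outdir``."""
    from pathlib import Path

    from . import io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_vcf(ds.genotypes, out / "genotypes.vcf")
    io.write_gene_models(ds.genes, out / "genes.gff3", out / "effects.tsv")
    io.write_phenotypes(ds.phenotypes, out / "phenotypes.tsv")
    truth = pd.DataFrame(
        [
            {"gene_id": gid, "trait": trait, "variant_id": vid, "effect": eff}
            for (gid, trait), (vid, eff) in sorted(ds.causal.causal_variants.items())
        ]
    )
    truth.to_csv(out / "causal_truth.tsv", sep="\t", index=False)
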