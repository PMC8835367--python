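"""Shared fixtures: synthetic panels at the study's working scale (400
inbred materials) and smaller variants for expensive or file-based tests.
All fixtures are deterministic; data is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from grainmap.core import GenotypeMatrix, Variant
from grainmap.simulate import CausalSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """Default study-scale panel: 400 inbred materials, 2000 SNPs over 2 Mb,
    two antagonistic major genes plus polygenic background, 4 environments x
    3 replicates."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale panel for brute-force comparisons (50 materials)."""
    cfg = SimulationConfig(n_materials=50, n_variants=120, n_genes=2,
                           chrom_length_bp=600_000, seed=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def het_sim():
    """Panel with residual heterozygosity, for IUPAC haplotype handling."""
    cfg = SimulationConfig(n_materials=120, n_variants=300, n_genes=2,
                           chrom_length_bp=600_000, heterozygosity=0.3, seed=5)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def pipeline_run(sim):
    """GWAS -> QTL -> candidate screen on the default panel, shared across
    tests that inspect downstream results."""
    from grainmap.pipeline import (PipelineConfig, run_candidate_screen,
                                   run_gwas, run_qtl)

    cfg = PipelineConfig()
    scans = run_gwas(sim.genotypes, sim.phenotypes, cfg)
    qtls = run_qtl(scans, sim.genotypes, cfg)
    candidates, tests = run_candidate_screen(qtls, scans, sim.genes,
                                             sim.genotypes, sim.phenotypes, cfg)
    return {"config": cfg, "scans": scans, "qtls": qtls,
            "candidates": candidates, "tests": tests}


def geno_from_strings(gene_strings: dict[str, list[str]],
                      positions: dict[str, list[int]] | None = None,
                      chrom: str = "1") -> GenotypeMatrix:
    """Build a GenotypeMatrix whose haplotype strings over each gene's SNPs
    are exactly the given per-material strings.

    ``gene_strings`` maps gene_id -> list of per-material strings (all genes
    must list the same number of materials).  Ref/alt per site are inferred
    from the letters used (IUPAC codes mean heterozygous ref/alt).
    """
    from grainmap.core import IUPAC_PAIR

    iupac_to_pair = {code: pair for pair, code in IUPAC_PAIR.items()}
    n = len(next(iter(gene_strings.values())))
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    pos_counter = 1000
    for gene_id, strings in gene_strings.items():
        assert len(strings) == n
        width = len(strings[0])
        pos_list = (positions or {}).get(gene_id)
        for k in range(width):
            letters = {s[k] for s in strings}
            bases = set()
            for c in letters:
                bases |= set(iupac_to_pair.get(c, c))
            assert len(bases) <= 2, f"site {k} of {gene_id} uses >2 bases"
            if len(bases) == 1:
                bases.add({"A": "C", "C": "A"}.get(next(iter(bases)), "A"))
            ref, alt = sorted(bases)
            col = np.empty(n, dtype=np.int8)
            for i, s in enumerate(strings):
                c = s[k]
                if c == ref:
                    col[i] = 0
                elif c == alt:
                    col[i] = 2
                else:
                    assert iupac_to_pair[c] == frozenset((ref, alt))
                    col[i] = 1
            pos = pos_list[k] if pos_list else pos_counter
            pos_counter += 1000
            variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                    id=f"{gene_id}_s{k}"))
            columns.append(col)
    dosage = np.column_stack(columns)
    materials = [f"M{i:03d}" for i in range(n)]
    return GenotypeMatrix(materials=materials, variants=variants, dosage=dosage,
                          missing=np.zeros_like(dosage, dtype=bool))
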