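"""Self-contained builders used by the acceptance script: genotype matrices
with prescribed haplotype strings and a two-gene additive phenotype panel
(synthetic stand-ins mirroring the published allele classes)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from grainmap.core import IUPAC_PAIR, GenotypeMatrix, Variant

GS3_HAPS = ["AATCT", "TGCTG", "WRYYK"]
GW5_HAPS = ["CG", "TA", "TG", "YR"]
GS3_EFF = {"AATCT": 0.6, "TGCTG": 0.0, "WRYYK": 0.1}
GW5_EFF = {"CG": 0.3, "TA": 0.0, "TG": 0.1, "YR": 0.05}


def geno_from_strings(gene_strings: dict[str, list[str]], chrom: str = "1") -> GenotypeMatrix:
    """GenotypeMatrix whose per-gene haplotype strings are exactly the given
    per-material strings (IUPAC letters mean heterozygous ref/alt)."""
    iupac_to_pair = {code: pair for pair, code in IUPAC_PAIR.items()}
    n = len(next(iter(gene_strings.values())))
    variants, columns = [], []
    pos = 1000
    for gene_id, strings in gene_strings.items():
        assert len(strings) == n
        for k in range(len(strings[0])):
            letters = {s[k] for s in strings}
            bases: set[str] = set()
            for c in letters:
                bases |= set(iupac_to_pair.get(c, c))
            assert len(bases) <= 2
            if len(bases) == 1:
                bases.add({"A": "C", "C": "A"}.get(next(iter(bases)), "A"))
            ref, alt = sorted(bases)
            col = np.empty(n, dtype=np.int8)
            for i, s in enumerate(strings):
                c = s[k]
                col[i] = 0 if c == ref else 2 if c == alt else 1
            variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                    id=f"{gene_id}_s{k}"))
            columns.append(col)
            pos += 1000
    dosage = np.column_stack(columns)
    return GenotypeMatrix(materials=[f"M{i:03d}" for i in range(n)],
                          variants=variants, dosage=dosage,
                          missing=np.zeros_like(dosage, dtype=bool))


def additive_panel(seed: int):
    """240-material panel with independently assorted GS3/GW5 alleles and a
    purely additive phenotype (allele effects + N(0, 0.1) noise, 2 reps)."""
    rng = np.random.default_rng(seed)
    gs3 = sum(([h] * c for h, c in zip(GS3_HAPS, (120, 80, 40))), [])
    gw5 = sum(([h] * c for h, c in zip(GW5_HAPS, (100, 80, 40, 20))), [])
    genes = {"GS3": list(rng.permutation(gs3)), "GW5": list(rng.permutation(gw5))}
    g = geno_from_strings(genes)
    rows = []
    for i in range(240):
        mu = 8.0 + GS3_EFF[genes["GS3"][i]] + GW5_EFF[genes["GW5"][i]]
        for rep in (1, 2):
            rows.append({"material": f"M{i:03d}", "trait": "GL",
                         "environment": "E1", "replicate": rep,
                         "value": mu + rng.normal(0, 0.1)})
    return g, genes, pd.DataFrame(rows)
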