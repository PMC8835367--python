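"""Gene-based haplotype analysis inside important QTLs.

Significant SNPs in a gene are split into group I (amino-acid or splicing
changes) and group II (promoter region).  Each material's haplotype over the
grouped SNPs is its genotype string — homozygote base letters, IUPAC
ambiguity codes for heterozygotes (so the heterozygote class, e.g. WRYYK, is
its own class) — and classes carried by fewer than ``min_group_n`` materials
(default 6) are not retained.  Retained classes are compared per trait x
environment with Welch's t-test (2 classes) or one-way ANOVA (>= 3), with a
compact-letter display from pairwise Welch tests under Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenotypeMatrix, GrainmapError
from .io import material_means

GROUP_I_CLASSES = ("amino_acid_change", "splicing_change")


@dataclass
class GroupedSnpSet:
    """Significant SNPs of one gene in one screening group."""

    gene_id: str
    group: str  # "I" or "II"
    variant_ids: list[str]
    basis: dict[str, str]  # variant id -> consequence class


@dataclass
class HaplotypeAssignment:
    """Per-material genotype strings over a gene's grouped SNPs.

    ``classes`` maps haplotype string -> member count (all observed
    classes); ``retained`` lists the classes with count >= min_group_n;
    ``assignment`` maps material -> haplotype string (materials missing a
    call at any grouped SNP are absent).
    """

    gene_id: str
    variant_ids: list[str]
    assignment: dict[str, str]
    classes: dict[str, int]
    retained: list[str]
    min_group_n: int

    def materials_of(self, hap: str) -> list[str]:
        return [m for m, h in self.assignment.items() if h == hap]


@dataclass
class HaplotypeTestResult:
    gene_id: str
    trait: str
    environment: str
    test: str  # "t_test" | "anova" | "untestable"
    p: float
    class_means: dict[str, float] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)


def classify_snps(gene: GeneModel, significant_ids) -> list[GroupedSnpSet]:
    """Group I: significant SNPs causing amino-acid/splicing changes;
    group II: significant SNPs in the promoter region.  Either set may be
    empty; a SNP belongs to at most one group by construction (one
    consequence class per SNP)."""
    sig = set(significant_ids)
    g1 = [vid for vid, cls in gene.snp_effects.items() if cls in GROUP_I_CLASSES and vid in sig]
    g2 = [vid for vid, cls in gene.snp_effects.items() if cls == "promoter" and vid in sig]
    out = []
    for group, vids in (("I", g1), ("II", g2)):
        out.append(GroupedSnpSet(
            gene_id=gene.gene_id, group=group, variant_ids=sorted(vids),
            basis={v: gene.snp_effects[v] for v in vids},
        ))
    return out


def call_haplotypes(gene_id: str, variant_ids, geno: GenotypeMatrix,
                    min_group_n: int = 6) -> HaplotypeAssignment:
    """Build genotype-string haplotype classes over ``variant_ids``
    (position-sorted).  Materials with a missing call at any variant are
    left unassigned.  Deterministic and order-independent in materials."""
    if not variant_ids:
        raise GrainmapError(f"no variants to call haplotypes for gene {gene_id}")
    vids = sorted(variant_ids, key=lambda v: geno.variant(v).pos)
    assignment: dict[str, str] = {}
    for i, material in enumerate(geno.materials):
        calls = [geno.base_call(i, v) for v in vids]
        if any(c is None for c in calls):
            continue
        assignment[material] = "".join(calls)  # type: ignore[arg-type]
    classes: dict[str, int] = {}
    for hap in assignment.values():
        classes[hap] = classes.get(hap, 0) + 1
    retained = sorted((h for h, n in classes.items() if n >= min_group_n),
                      key=lambda h: (-classes[h], h))
    return HaplotypeAssignment(
        gene_id=gene_id, variant_ids=vids, assignment=assignment,
        classes=classes, retained=retained, min_group_n=min_group_n,
    )


def compact_letters(names, means: dict, significant: dict) -> dict[str, str]:
    """Compact-letter display: groups sharing no letter differ significantly.

    ``significant[(a, b)]`` says the pair differs; letters are maximal
    cliques of the complement ("not significantly different") graph, lettered
    in order of their best-ranked member (ranked by descending mean).
    """
    import networkx as nx

    names = list(names)
    G = nx.Graph()
    G.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if not significant.get((a, b), significant.get((b, a), False)):
                G.add_edge(a, b)
    order = {n: rank for rank, n in enumerate(sorted(names, key=lambda n: -means[n]))}
    cliques = sorted(nx.find_cliques(G), key=lambda c: min(order[n] for n in c))
    letters: dict[str, list[str]] = {n: [] for n in names}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for n in clique:
            letters[n].append(letter)
    return {n: "".join(sorted(ls)) for n, ls in letters.items()}


def haplotype_test(assignment: HaplotypeAssignment, pheno: pd.DataFrame,
                   trait: str, environment: str, alpha: float = 0.01) -> HaplotypeTestResult:
    """Compare retained haplotype classes on per-material trait means in one
    environment: Welch's t-test for exactly 2 classes, one-way ANOVA for
    >= 3, plus a compact-letter display from pairwise Welch tests with
    Bonferroni correction at ``alpha``."""
    means = material_means(pheno, trait, environment)
    samples: dict[str, np.ndarray] = {}
    for hap in assignment.retained:
        mats = [m for m in assignment.materials_of(hap) if m in means.index]
        vals = means.loc[mats].to_numpy(dtype=float)
        if vals.size >= 2:
            samples[hap] = vals
    if len(samples) < 2:
        return HaplotypeTestResult(
            gene_id=assignment.gene_id, trait=trait, environment=environment,
            test="untestable", p=float("nan"),
            class_means={h: float(np.mean(v)) for h, v in samples.items()},
            class_counts={h: int(v.size) for h, v in samples.items()},
        )

    haps = sorted(samples, key=lambda h: (-samples[h].size, h))
    groups = [samples[h] for h in haps]
    if len(groups) == 2:
        test = "t_test"
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    else:
        test = "anova"
        stat, p = stats.f_oneway(*groups)
    p = float(p)
    if np.isnan(p):  # all values identical in every class
        p = 1.0

    n_pairs = len(haps) * (len(haps) - 1) // 2
    sig: dict[tuple[str, str], bool] = {}
    for i, a in enumerate(haps):
        for b in haps[i + 1:]:
            pp = float(stats.ttest_ind(samples[a], samples[b], equal_var=False)[1])
            if np.isnan(pp):
                pp = 1.0
            sig[(a, b)] = pp < alpha / n_pairs
    cm = {h: float(np.mean(samples[h])) for h in haps}
    letters = compact_letters(haps, cm, sig)
    return HaplotypeTestResult(
        gene_id=assignment.gene_id, trait=trait, environment=environment,
        test=test, p=p, class_means=cm,
        class_counts={h: int(samples[h].size) for h in haps}, letters=letters,
    )


@dataclass
class CandidateGene:
    gene_id: str
    groups: list[str]  # "I", "II" or both
    environments: list[str]  # environments with a significant haplotype test
    traits: list[str]
    annotation: str = ""


def screen_candidates(gene_results: dict, genes_by_id: dict[str, GeneModel],
                      alpha: float = 0.01, min_envs: int = 1) -> list[CandidateGene]:
    """Screen genes whose haplotype classes differ significantly in at least
    ``min_envs`` environments.

    ``gene_results`` maps gene_id -> {"groups": [...], "tests":
    [HaplotypeTestResult, ...]}.  Functional-correlation triage is a human
    step: each candidate carries the gene's annotation text for review.
    """
    out: list[CandidateGene] = []
    for gene_id, info in sorted(gene_results.items()):
        sig_tests = [t for t in info["tests"] if t.test != "untestable" and t.p < alpha]
        envs = sorted({t.environment for t in sig_tests})
        if len(envs) < min_envs or not envs:
            continue
        gene = genes_by_id.get(gene_id)
        out.append(CandidateGene(
            gene_id=gene_id,
            groups=sorted(set(info["groups"])),
            environments=envs,
            traits=sorted({t.trait for t in sig_tests}),
            annotation=gene.annotation if gene else "",
        ))
    return out
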