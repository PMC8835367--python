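"""Allele definition and multi-gene allele-combination analysis.

An *allele* of a gene is a haplotype class over the union of the gene's
significant SNPs pooled across all environments and traits — so the same
partition of materials is used everywhere.  Materials are then classified by
their combination of alleles across several genes (e.g. ``GS3A-GW5B``);
combinations carried by fewer than six materials are discarded, the rest are
ranked per trait by ANOVA with compact letters, and departures from
additivity are quantified by a per-combination gap statistic with a
bootstrap interval.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, GrainmapError
from .haplotypes import call_haplotypes, compact_letters
from .io import material_means


@dataclass
class AlleleDefinition:
    """A gene's allele partition: label (A, B, ...) per haplotype string,
    ordered by descending member count; classes below ``min_n`` members are
    dropped from downstream use."""

    gene_id: str
    variant_ids: list[str]
    labels: dict[str, str]  # haplotype string -> "A", "B", ...
    counts: dict[str, int]  # label -> member count (retained labels only)
    assignment: dict[str, str]  # material -> label (retained labels only)

    @property
    def alleles(self) -> list[str]:
        return sorted(self.counts, key=lambda lab: (-self.counts[lab], lab))

    def haplotype_of(self, label: str) -> str:
        for hap, lab in self.labels.items():
            if lab == label:
                return hap
        raise GrainmapError(f"no allele {label} for gene {self.gene_id}")


def define_alleles(gene_id: str, pooled_variant_ids, geno: GenotypeMatrix,
                   min_n: int = 6) -> AlleleDefinition:
    """Call the allele partition of one gene from the pooled (union over all
    scans) significant SNPs.  Labels are assigned by descending class size
    (ties broken by string), so Hap A is always the most common allele."""
    pooled = sorted(set(pooled_variant_ids))
    if not pooled:
        raise GrainmapError(f"gene {gene_id} has no significant SNPs; cannot define alleles")
    asg = call_haplotypes(gene_id, pooled, geno, min_group_n=min_n)
    ordered = sorted(asg.classes, key=lambda h: (-asg.classes[h], h))
    labels = {hap: chr(ord("A") + i) for i, hap in enumerate(ordered)}
    retained = set(asg.retained)
    counts = {labels[h]: asg.classes[h] for h in ordered if h in retained}
    assignment = {m: labels[h] for m, h in asg.assignment.items() if h in retained}
    return AlleleDefinition(gene_id=gene_id, variant_ids=asg.variant_ids,
                            labels=labels, counts=counts, assignment=assignment)


def enumerate_combinations(definitions: list[AlleleDefinition]) -> list[tuple[str, ...]]:
    """Cartesian product of per-gene allele labels; its size is the product
    of the per-gene allele counts."""
    if not definitions:
        raise GrainmapError("need at least one allele definition")
    return list(itertools.product(*(d.alleles for d in definitions)))


def combination_label(definitions: list[AlleleDefinition], alleles: tuple[str, ...]) -> str:
    return "-".join(f"{d.gene_id}{a}" for d, a in zip(definitions, alleles))


def parse_combination_label(label: str) -> list[tuple[str, str]]:
    """Inverse of :func:`combination_label`: ``"GS3A-GW5B"`` ->
    ``[("GS3", "A"), ("GW5", "B")]``."""
    out = []
    for part in label.split("-"):
        m = re.fullmatch(r"(.+?)([A-Z])", part)
        if not m:
            raise GrainmapError(f"malformed combination label part {part!r}")
        out.append((m.group(1), m.group(2)))
    return out


@dataclass
class AlleleCombinations:
    """Material classification by multi-gene allele combination."""

    definitions: list[AlleleDefinition]
    assignment: dict[str, str]  # material -> combination label (retained only)
    counts: dict[str, int]  # retained combination label -> n
    n_possible: int
    n_observed: int
    discarded: dict[str, int] = field(default_factory=dict)  # label -> n < min_n

    @property
    def labels(self) -> list[str]:
        return sorted(self.counts, key=lambda lab: (-self.counts[lab], lab))


def assign_combinations(definitions: list[AlleleDefinition], min_n: int = 6) -> AlleleCombinations:
    """Label each material assigned an allele at *every* gene with its
    concatenated combination; combinations with fewer than ``min_n``
    materials are discarded."""
    possible = enumerate_combinations(definitions)
    assignment: dict[str, str] = {}
    materials = set(definitions[0].assignment)
    for d in definitions[1:]:
        materials &= set(d.assignment)
    for m in sorted(materials):
        alleles = tuple(d.assignment[m] for d in definitions)
        assignment[m] = combination_label(definitions, alleles)
    counts: dict[str, int] = {}
    for lab in assignment.values():
        counts[lab] = counts.get(lab, 0) + 1
    retained = {lab: n for lab, n in counts.items() if n >= min_n}
    discarded = {lab: n for lab, n in counts.items() if n < min_n}
    assignment = {m: lab for m, lab in assignment.items() if lab in retained}
    return AlleleCombinations(
        definitions=definitions, assignment=assignment, counts=retained,
        n_possible=len(possible), n_observed=len(counts), discarded=discarded,
    )


def _per_material_values(combos: AlleleCombinations, pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Per-material trait value: mean over environments and replicates,
    restricted to materials in retained combinations."""
    means = material_means(pheno, trait, environment=None)
    mats = [m for m in combos.assignment if m in means.index]
    return means.loc[mats]


def rank_extremes(combos: AlleleCombinations, pheno: pd.DataFrame, trait: str,
                  alpha: float = 0.01) -> pd.DataFrame:
    """Rank retained combinations by mean trait value with an overall one-way
    ANOVA and compact letters (pairwise Welch + Bonferroni at ``alpha``).

    Returns a DataFrame ordered best-to-worst with columns label / n / mean /
    letters / anova_p; the first and last rows are the extreme combinations.
    """
    values = _per_material_values(combos, pheno, trait)
    groups = {lab: values.loc[[m for m in combos.assignment
                               if combos.assignment[m] == lab and m in values.index]].to_numpy()
              for lab in combos.labels}
    groups = {lab: v for lab, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise GrainmapError("rank_extremes needs >= 2 retained combinations")
    labs = sorted(groups, key=lambda L: -float(np.mean(groups[L])))
    _, anova_p = stats.f_oneway(*(groups[L] for L in labs))
    anova_p = 1.0 if np.isnan(anova_p) else float(anova_p)
    n_pairs = len(labs) * (len(labs) - 1) // 2
    sig = {}
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            pp = float(stats.ttest_ind(groups[a], groups[b], equal_var=False)[1])
            if np.isnan(pp):
                pp = 1.0
            sig[(a, b)] = pp < alpha / n_pairs
    means = {L: float(np.mean(groups[L])) for L in labs}
    letters = compact_letters(labs, means, sig)
    return pd.DataFrame({
        "label": labs,
        "n": [groups[L].size for L in labs],
        "mean": [means[L] for L in labs],
        "letters": [letters[L] for L in labs],
        "anova_p": anova_p,
    })


def additivity_gap(combos: AlleleCombinations, pheno: pd.DataFrame, trait: str,
                   n_boot: int = 500, level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Departure of each combination mean from the additive prediction.

    gap(c) = observed mean of combination c
             - (grand mean + sum over genes of that gene's allele deviation),
    where an allele deviation is the mean over materials carrying the allele
    minus the grand mean (all over materials in retained combinations).
    A seeded bootstrap over materials gives a percentile interval per
    combination at ``level``.
    """
    values = _per_material_values(combos, pheno, trait)
    mats = np.array([m for m in values.index])
    v = values.to_numpy(dtype=float)
    combo_of = np.array([combos.assignment[m] for m in mats])
    allele_of = {d.gene_id: np.array([d.assignment[m] for m in mats])
                 for d in combos.definitions}
    labs = combos.labels

    def gaps(idx: np.ndarray) -> np.ndarray:
        vv, cc = v[idx], combo_of[idx]
        grand = vv.mean()
        pred = np.full(len(labs), grand)
        for gi, d in enumerate(combos.definitions):
            aa = allele_of[d.gene_id][idx]
            for li, lab in enumerate(labs):
                allele = parse_combination_label(lab)[gi][1]
                sel = aa == allele
                dev = vv[sel].mean() - grand if sel.any() else np.nan
                pred[li] += dev
        obs = np.array([vv[cc == lab].mean() if (cc == lab).any() else np.nan for lab in labs])
        return obs - pred

    observed = gaps(np.arange(len(mats)))
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(labs)))
    for b in range(n_boot):
        boot[b] = gaps(rng.integers(0, len(mats), size=len(mats)))
    q = (1.0 - level) / 2.0
    lo = np.nanpercentile(boot, 100 * q, axis=0)
    hi = np.nanpercentile(boot, 100 * (1 - q), axis=0)
    return pd.DataFrame({
        "label": labs,
        "n": [int((combo_of == lab).sum()) for lab in labs],
        "gap": observed,
        "ci_low": lo,
        "ci_high": hi,
    })
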