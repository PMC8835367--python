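"""Allele definition, combination enumeration/assignment, extreme ranking
and the additivity-gap statistic."""

import numpy as np
import pandas as pd
import pytest

from grainmap.combos import (additivity_gap, assign_combinations,
                             combination_label, define_alleles,
                             enumerate_combinations, parse_combination_label,
                             rank_extremes)
from grainmap.core import GrainmapError

from conftest import geno_from_strings

# the published allele strings of the three cloned genes
GS3_HAPS = ["AATCT", "TGCTG", "WRYYK"]
GW5_HAPS = ["CG", "TA", "TG", "YR"]
DER1_HAPS = ["T", "C", "Y"]


def panel(counts_gs3=(30, 20, 10), counts_gw5=(25, 15, 12, 8), n=60, seed=0,
          counts_der1=None):
    """Panel whose per-gene allele classes have the given sizes; gene
    memberships are assigned independently (shuffled)."""
    rng = np.random.default_rng(seed)
    gs3 = sum(([h] * c for h, c in zip(GS3_HAPS, counts_gs3)), [])
    gw5 = sum(([h] * c for h, c in zip(GW5_HAPS, counts_gw5)), [])
    genes = {"GS3": gs3, "GW5": gw5}
    if counts_der1 is not None:
        genes["OsDER1"] = sum(([h] * c for h, c in zip(DER1_HAPS, counts_der1)), [])
    for k in genes:
        assert len(genes[k]) == n
        genes[k] = list(rng.permutation(genes[k]))
    return geno_from_strings(genes), genes


class TestDefineAlleles:
    def test_three_alleles_from_observed_strings(self):
        g, _ = panel()
        vids = [v.id for v in g.variants if v.id.startswith("GS3")]
        d = define_alleles("GS3", vids, g)
        assert len(d.alleles) == 3
        assert d.labels[d.haplotype_of("A")] == "A"
        # labels ordered by descending count
        counts = [d.counts[a] for a in d.alleles]
        assert counts == sorted(counts, reverse=True)
        assert d.haplotype_of("A") == "AATCT"

    def test_four_alleles_two_snp_gene(self):
        g, _ = panel()
        vids = [v.id for v in g.variants if v.id.startswith("GW5")]
        d = define_alleles("GW5", vids, g)
        assert len(d.alleles) == 4
        assert set(d.labels) == set(GW5_HAPS)

    def test_small_classes_dropped(self):
        g, _ = panel(counts_gs3=(40, 15, 5))
        vids = [v.id for v in g.variants if v.id.startswith("GS3")]
        d = define_alleles("GS3", vids, g, min_n=6)
        assert len(d.alleles) == 2
        assert "WRYYK" not in {d.haplotype_of(a) for a in d.alleles}

    def test_no_snps_fatal(self):
        g, _ = panel()
        with pytest.raises(GrainmapError, match="GS3"):
            define_alleles("GS3", [], g)


class TestEnumerate:
    def _defs(self, *sizes):
        g, _ = panel(counts_der1=(30, 20, 10))
        names = {3: "GS3", 4: "GW5"}
        defs = []
        used = set()
        for s in sizes:
            gene = {3: ["GS3", "OsDER1"], 4: ["GW5"]}[s]
            gid = next(x for x in gene if x not in used)
            used.add(gid)
            vids = [v.id for v in g.variants if v.id.startswith(gid)]
            defs.append(define_alleles(gid, vids, g))
        return defs

    def test_three_by_four_is_twelve(self):
        defs = self._defs(3, 4)
        assert len(enumerate_combinations(defs)) == 12

    def test_three_four_three_is_thirty_six(self):
        defs = self._defs(3, 4, 3)
        assert len(enumerate_combinations(defs)) == 36

    def test_single_gene_is_its_alleles(self):
        defs = self._defs(3)
        assert enumerate_combinations(defs) == [(a,) for a in defs[0].alleles]

    def test_size_matches_full_factorial_panel(self):
        # every combination present: distinct labels == enumerated size
        import itertools

        gs3 = [h for h in GS3_HAPS for _ in range(8)]          # 24
        gw5 = [h for p in itertools.product(GS3_HAPS, GW5_HAPS) for h in [p[1]] * 2]  # 24 aligned
        gs3 = [p[0] for p in itertools.product(GS3_HAPS, GW5_HAPS) for _ in range(2)]
        g = geno_from_strings({"GS3": gs3, "GW5": gw5})
        d1 = define_alleles("GS3", [v.id for v in g.variants if v.id.startswith("GS3")], g, min_n=1)
        d2 = define_alleles("GW5", [v.id for v in g.variants if v.id.startswith("GW5")], g, min_n=1)
        combos = assign_combinations([d1, d2], min_n=1)
        assert combos.n_observed == len(enumerate_combinations([d1, d2]))


class TestAssign:
    def test_small_combination_discarded(self):
        g, genes = panel(counts_gs3=(40, 20, 0), counts_gw5=(40, 20, 0, 0), seed=1)
        d1 = define_alleles("GS3", [v.id for v in g.variants if v.id.startswith("GS3")], g)
        d2 = define_alleles("GW5", [v.id for v in g.variants if v.id.startswith("GW5")], g)
        combos = assign_combinations([d1, d2], min_n=6)
        assert all(n >= 6 for n in combos.counts.values())
        assert combos.n_observed >= len(combos.counts)

    def test_unassigned_material_excluded_everywhere(self):
        g, _ = panel()
        g.missing[0, 0] = True  # first GS3 SNP missing for M000
        d1 = define_alleles("GS3", [v.id for v in g.variants if v.id.startswith("GS3")], g)
        d2 = define_alleles("GW5", [v.id for v in g.variants if v.id.startswith("GW5")], g)
        combos = assign_combinations([d1, d2], min_n=1)
        assert "M000" not in combos.assignment

    def test_counts_bounded_by_materials(self):
        g, _ = panel()
        d1 = define_alleles("GS3", [v.id for v in g.variants if v.id.startswith("GS3")], g)
        d2 = define_alleles("GW5", [v.id for v in g.variants if v.id.startswith("GW5")], g)
        combos = assign_combinations([d1, d2], min_n=1)
        assert sum(combos.counts.values()) <= g.n_materials

    def test_label_round_trip(self):
        assert parse_combination_label("GS3A-GW5B") == [("GS3", "A"), ("GW5", "B")]
        g, _ = panel(counts_der1=(30, 20, 10))
        defs = [define_alleles(gid, [v.id for v in g.variants if v.id.startswith(gid)], g)
                for gid in ("GS3", "GW5", "OsDER1")]
        for alleles in enumerate_combinations(defs):
            label = combination_label(defs, alleles)
            assert parse_combination_label(label) == [
                (d.gene_id, a) for d, a in zip(defs, alleles)]


def additive_pheno(genes: dict[str, list[str]], effects: dict[str, dict[str, float]],
                   noise=0.05, seed=0, trait="GL", interaction=None):
    """Phenotype = 8 + sum of per-gene allele effects (+ optional
    interaction for one (hap, hap) pair) + small noise; one env, 2 reps."""
    rng = np.random.default_rng(seed)
    n = len(next(iter(genes.values())))
    rows = []
    for i in range(n):
        mu = 8.0
        for gid, haps in genes.items():
            mu += effects[gid][haps[i]]
        if interaction is not None:
            pair, c = interaction
            if tuple(genes[g][i] for g in genes) == pair:
                mu += c
        for rep in (1, 2):
            rows.append({"material": f"M{i:03d}", "trait": trait,
                         "environment": "E1", "replicate": rep,
                         "value": mu + rng.normal(0, noise)})
    return pd.DataFrame(rows)


GS3_EFF = {"AATCT": 0.6, "TGCTG": 0.0, "WRYYK": 0.1}
GW5_EFF = {"CG": 0.3, "TA": 0.0, "TG": 0.1, "YR": 0.05}


def _combos_for(g, min_n=6):
    d1 = define_alleles("GS3", [v.id for v in g.variants if v.id.startswith("GS3")], g, min_n=min_n)
    d2 = define_alleles("GW5", [v.id for v in g.variants if v.id.startswith("GW5")], g, min_n=min_n)
    return assign_combinations([d1, d2], min_n=min_n)


class TestRankExtremes:
    def test_additive_model_extremes_and_marginal_sums(self):
        g, genes = panel(counts_gs3=(80, 80, 80), counts_gw5=(80, 80, 40, 40),
                         n=240, seed=2)
        pheno = additive_pheno(genes, {"GS3": GS3_EFF, "GW5": GW5_EFF}, seed=2)
        combos = _combos_for(g)
        ranking = rank_extremes(combos, pheno, "GL")
        best = parse_combination_label(ranking.iloc[0]["label"])
        assert dict(best)["GS3"] == "A"  # AATCT is the most common -> label A
        # best combination pairs the two best marginal alleles
        d1, d2 = combos.definitions
        assert GS3_EFF[d1.haplotype_of(dict(best)["GS3"])] == max(GS3_EFF.values())
        assert GW5_EFF[d2.haplotype_of(dict(best)["GW5"])] == max(GW5_EFF.values())
        # combination means sit within noise of the additive prediction
        for _, row in ranking.iterrows():
            parts = dict(parse_combination_label(row["label"]))
            pred = 8.0 + GS3_EFF[d1.haplotype_of(parts["GS3"])] + \
                GW5_EFF[d2.haplotype_of(parts["GW5"])]
            assert row["mean"] == pytest.approx(pred, abs=0.05)

    def test_identical_distributions_share_letter(self):
        g, genes = panel(n=60, seed=3)
        pheno = additive_pheno(genes, {"GS3": {h: 0.0 for h in GS3_HAPS},
                                       "GW5": {h: 0.0 for h in GW5_HAPS}}, seed=3)
        combos = _combos_for(g)
        ranking = rank_extremes(combos, pheno, "GL")
        letters = ranking["letters"].tolist()
        assert set.intersection(*(set(l) for l in letters))

    def test_dominant_combination_gets_unique_letter(self):
        g, genes = panel(counts_gs3=(120, 120, 0), counts_gw5=(120, 120, 0, 0),
                         n=240, seed=4)
        pheno = additive_pheno(
            genes, {"GS3": {h: 0.0 for h in GS3_HAPS}, "GW5": {h: 0.0 for h in GW5_HAPS}},
            noise=0.5, seed=4, interaction=(("AATCT", "CG"), 2.0))
        combos = _combos_for(g)
        ranking = rank_extremes(combos, pheno, "GL")
        top = ranking.iloc[0]
        others = ranking.iloc[1:]
        assert all(not set(top["letters"]) & set(l) for l in others["letters"])

    def test_single_combination_fatal(self):
        g, genes = panel(counts_gs3=(60, 0, 0), counts_gw5=(60, 0, 0, 0), n=60)
        pheno = additive_pheno(genes, {"GS3": GS3_EFF, "GW5": GW5_EFF})
        combos = _combos_for(g)
        with pytest.raises(GrainmapError, match="2 retained"):
            rank_extremes(combos, pheno, "GL")


class TestAdditivityGap:
    def test_additive_null_intervals_cover_zero(self):
        g, genes = panel(counts_gs3=(120, 80, 40), counts_gw5=(100, 80, 40, 20),
                         n=240, seed=6)
        pheno = additive_pheno(genes, {"GS3": GS3_EFF, "GW5": GW5_EFF},
                               noise=0.1, seed=6)
        combos = _combos_for(g)
        k = len(combos.counts)
        # family-wise check: Bonferroni-adjusted per-interval level
        gaps = additivity_gap(combos, pheno, "GL", level=1 - 0.05 / k, seed=6)
        assert ((gaps["ci_low"] <= 0) & (gaps["ci_high"] >= 0)).all()

    def test_planted_interaction_recovered(self):
        # explicit joint allele table at n = 400: the interacting pair is
        # rare (6 of 400), so the marginal means absorb little of the
        # planted term and the gap stays close to c
        c = 0.5
        joint = {("AATCT", "CG"): 308, ("AATCT", "TA"): 43,
                 ("TGCTG", "CG"): 43, ("TGCTG", "TA"): 6}
        gs3, gw5 = [], []
        for (h1, h2), cnt in joint.items():
            gs3 += [h1] * cnt
            gw5 += [h2] * cnt
        genes = {"GS3": gs3, "GW5": gw5}
        g = geno_from_strings(genes)
        pheno = additive_pheno(genes, {"GS3": GS3_EFF, "GW5": GW5_EFF},
                               noise=0.02, seed=7, interaction=(("TGCTG", "TA"), c))
        combos = _combos_for(g)
        gaps = additivity_gap(combos, pheno, "GL", seed=7).set_index("label")
        d1, d2 = combos.definitions
        lab = f"GS3{d1.labels['TGCTG']}-GW5{d2.labels['TA']}"
        row = gaps.loc[lab]
        assert row["ci_low"] > 0 or row["ci_high"] < 0
        assert abs(row["gap"]) == pytest.approx(c, rel=0.3)

    def test_single_combination_gap_zero(self):
        g, genes = panel(counts_gs3=(60, 0, 0), counts_gw5=(60, 0, 0, 0), n=60)
        pheno = additive_pheno(genes, {"GS3": GS3_EFF, "GW5": GW5_EFF})
        combos = _combos_for(g)
        gaps = additivity_gap(combos, pheno, "GL", n_boot=50)
        assert gaps["gap"].iloc[0] == pytest.approx(0.0, abs=1e-12)
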