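"""SNP grouping, IUPAC haplotype calling, class retention and the
haplotype significance tests with compact letters."""

import numpy as np
import pandas as pd
import pytest

from grainmap.core import GeneModel, GrainmapError
from grainmap.haplotypes import (call_haplotypes, classify_snps,
                                 compact_letters, haplotype_test,
                                 screen_candidates, HaplotypeTestResult)

from conftest import geno_from_strings


@pytest.fixture
def gene():
    return GeneModel(gene_id="g1", chrom="1", strand="+", start=5000, end=9000,
                     snp_effects={"s1": "amino_acid_change", "s2": "splicing_change",
                                  "s3": "promoter", "s4": "other",
                                  "s5": "amino_acid_change"})


class TestClassify:
    def test_significant_missense_goes_to_group_one(self, gene):
        sets = {s.group: s for s in classify_snps(gene, {"s1", "s2", "s3"})}
        assert sets["I"].variant_ids == ["s1", "s2"]

    def test_significant_promoter_goes_to_group_two(self, gene):
        sets = {s.group: s for s in classify_snps(gene, {"s1", "s3"})}
        assert sets["II"].variant_ids == ["s3"]

    def test_non_significant_missense_in_neither(self, gene):
        sets = {s.group: s for s in classify_snps(gene, {"s3"})}
        assert "s5" not in sets["I"].variant_ids and "s1" not in sets["I"].variant_ids

    def test_groups_disjoint(self, gene):
        sets = classify_snps(gene, {"s1", "s2", "s3", "s4", "s5"})
        ids = [v for s in sets for v in s.variant_ids]
        assert len(ids) == len(set(ids))
        assert "s4" not in ids  # class "other" screened out


class TestCallHaplotypes:
    def test_homozygous_calls_concatenate(self):
        g = geno_from_strings({"g1": ["AATCT"] * 6 + ["TGCTG"] * 6})
        asg = call_haplotypes("g1", [v.id for v in g.variants], g)
        assert set(asg.classes) == {"AATCT", "TGCTG"}
        assert asg.retained == ["AATCT", "TGCTG"]

    def test_heterozygous_calls_use_iupac(self):
        g = geno_from_strings({"g1": ["AATCT"] * 6 + ["TGCTG"] * 6 + ["WRYYK"] * 6})
        asg = call_haplotypes("g1", [v.id for v in g.variants], g)
        assert "WRYYK" in asg.classes

    def test_small_class_not_retained(self):
        g = geno_from_strings({"g1": ["AATCT"] * 10 + ["TGCTG"] * 5})
        asg = call_haplotypes("g1", [v.id for v in g.variants], g, min_group_n=6)
        assert asg.classes["TGCTG"] == 5
        assert asg.retained == ["AATCT"]

    def test_missing_call_leaves_material_unassigned(self):
        g = geno_from_strings({"g1": ["AATCT"] * 8})
        g.missing[0, 2] = True
        asg = call_haplotypes("g1", [v.id for v in g.variants], g)
        assert "M000" not in asg.assignment
        assert sum(asg.classes.values()) == 7

    def test_material_order_independence(self):
        g = geno_from_strings({"g1": ["AATCT", "TGCTG"] * 6})
        asg1 = call_haplotypes("g1", [v.id for v in g.variants], g)
        perm = np.arange(g.n_materials)[::-1]
        from grainmap.core import GenotypeMatrix

        g2 = GenotypeMatrix(materials=[g.materials[i] for i in perm],
                            variants=g.variants, dosage=g.dosage[perm],
                            missing=g.missing[perm])
        asg2 = call_haplotypes("g1", [v.id for v in g2.variants], g2)
        assert asg1.classes == asg2.classes
        assert asg1.assignment == asg2.assignment

    def test_absent_variant_fatal(self):
        g = geno_from_strings({"g1": ["AATCT"] * 6})
        with pytest.raises(GrainmapError, match="ghost"):
            call_haplotypes("g1", ["ghost"], g)

    def test_inbred_panel_has_no_iupac_codes(self, sim):
        geno = sim.genotypes
        vids = geno.variant_ids[:5]
        asg = call_haplotypes("x", vids, geno)
        assert not set("RYSWKM") & {c for h in asg.classes for c in h}

    def test_het_panel_codes_match_het_entries(self, het_sim):
        geno = het_sim.genotypes
        vids = geno.variant_ids[:4]
        asg = call_haplotypes("x", vids, geno)
        idx = [geno.index_of(v) for v in vids]
        for i, mat in enumerate(geno.materials):
            if mat not in asg.assignment:
                continue
            hap = asg.assignment[mat]
            for k, j in enumerate(idx):
                assert (hap[k] in "RYSWKM") == (geno.dosage[i, j] == 1)


def _pheno_for(classes: dict[str, np.ndarray], trait="GL", env="E1"):
    """One record per material, values per class."""
    rows, mats = [], {}
    i = 0
    for hap, vals in classes.items():
        mats[hap] = []
        for v in vals:
            m = f"M{i:03d}"
            rows.append({"material": m, "trait": trait, "environment": env,
                         "replicate": 1, "value": float(v)})
            mats[hap].append(m)
            i += 1
    return pd.DataFrame(rows), mats


def _assignment(mats: dict[str, list[str]]):
    from grainmap.haplotypes import HaplotypeAssignment

    assignment = {m: hap for hap, ms in mats.items() for m in ms}
    classes = {hap: len(ms) for hap, ms in mats.items()}
    return HaplotypeAssignment(gene_id="g1", variant_ids=["v"],
                               assignment=assignment, classes=classes,
                               retained=[h for h, n in classes.items() if n >= 6],
                               min_group_n=6)


class TestHaplotypeTest:
    def test_identical_classes_share_letter_with_p_one(self):
        vals = np.arange(10.0)
        pheno, mats = _pheno_for({"AA": vals, "TT": vals.copy()})
        res = haplotype_test(_assignment(mats), pheno, "GL", "E1")
        assert res.test == "t_test"
        assert res.p == pytest.approx(1.0, abs=1e-9)
        assert res.letters["AA"] == res.letters["TT"]

    def test_two_sd_shift_detected_with_distinct_letters(self):
        rng = np.random.default_rng(4)
        pheno, mats = _pheno_for({"AA": rng.normal(10, 1, 50),
                                  "TT": rng.normal(12, 1, 50)})
        res = haplotype_test(_assignment(mats), pheno, "GL", "E1")
        assert res.p < 0.01
        assert not set(res.letters["AA"]) & set(res.letters["TT"])

    def test_three_classes_anova_and_selective_letters(self):
        rng = np.random.default_rng(5)
        pheno, mats = _pheno_for({"AA": rng.normal(10, 1, 40),
                                  "TT": rng.normal(10, 1, 40),
                                  "GG": rng.normal(14, 1, 40)})
        res = haplotype_test(_assignment(mats), pheno, "GL", "E1")
        assert res.test == "anova"
        # brute-force pairwise Welch confirms which pairs differ
        from scipy import stats

        vals = {h: pheno.set_index("material").loc[ms, "value"].to_numpy()
                for h, ms in mats.items()}
        for a, b in [("AA", "TT"), ("AA", "GG"), ("TT", "GG")]:
            p = stats.ttest_ind(vals[a], vals[b], equal_var=False)[1]
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (p >= 0.01 / 3)

    def test_fewer_than_two_retained_classes_untestable(self):
        pheno, mats = _pheno_for({"AA": np.arange(10.0), "TT": np.arange(3.0)})
        res = haplotype_test(_assignment(mats), pheno, "GL", "E1")
        assert res.test == "untestable"


class TestCompactLetters:
    def test_significant_pairs_share_no_letter(self):
        names = ["a", "b", "c", "d"]
        means = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        sig = {("a", "c"): True, ("a", "d"): True, ("b", "d"): True}
        letters = compact_letters(names, means, sig)
        for (x, y), s in sig.items():
            assert not (set(letters[x]) & set(letters[y]))
        # non-significant neighbours do share one
        assert set(letters["a"]) & set(letters["b"])


class TestScreenCandidates:
    def _result(self, gene, env, p, trait="GL"):
        return HaplotypeTestResult(gene_id=gene, trait=trait, environment=env,
                                   test="anova", p=p)

    def test_gene_significant_in_all_environments(self):
        envs = ["2017EZ", "2017GA", "2018EZ", "2018GA"]
        results = {"GS3like": {"groups": ["II"],
                               "tests": [self._result("GS3like", e, 1e-5) for e in envs]}}
        cands = screen_candidates(results, {})
        assert len(cands) == 1 and len(cands[0].environments) == 4

    def test_gene_without_significant_test_excluded(self):
        results = {"dull": {"groups": ["I"],
                            "tests": [self._result("dull", "E1", 0.5)]}}
        assert screen_candidates(results, {}) == []

    def test_empty_input(self):
        assert screen_candidates({}, {}) == []

    def test_pipeline_recovers_planted_genes(self, pipeline_run):
        names = {c.gene_id for c in pipeline_run["candidates"]}
        assert {"GeneA", "GeneB"} <= names
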