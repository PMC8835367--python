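"""Readers and writers for the standard formats the pipeline touches.

Genotypes come in as VCF (diploid, biallelic SNPs), gene models as GFF3 plus
a consequence-class TSV, phenotypes as a long-format TSV, and the known-gene
list as TSV.  All tabular outputs are plain TSV.  Coordinates are 1-based
inclusive everywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONSEQUENCE_CLASSES, TRAITS, GeneModel, GenotypeMatrix, GrainmapError, Variant

log = logging.getLogger("grainmap")

_BASES = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, maf_min: float = 0.05, missing_max: float = 0.20) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`, applying the standard
    MAF >= ``maf_min`` and missing-rate <= ``missing_max`` variant filters.

    Non-SNP and multi-allelic records are skipped (counted in the log).
    Genotypes still missing after filtering are imputed by the per-variant
    mode (ties broken toward the smaller dosage); the pre-imputation
    missingness mask is preserved on the returned matrix.  Variant ids are
    synthesized as ``chr<NN>_<pos>`` when the VCF ID field is ``.``.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise GrainmapError(f"cannot read VCF: {path} does not exist")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise GrainmapError(f"cannot read VCF {path}: {exc}") from exc

    materials = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types)
        dos = np.full(gt.shape, -1, dtype=np.int8)
        dos[gt == 0] = 0
        dos[gt == 1] = 1
        dos[gt == 3] = 2
        vid = rec.ID if rec.ID not in (None, ".", "") else ""
        variants.append(Variant(chrom=str(rec.CHROM), pos=rec.POS, ref=rec.REF, alt=rec.ALT[0], id=vid))
        rows.append(dos)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise GrainmapError(f"no biallelic SNP records in {path}")

    dosage = np.vstack(rows).T  # materials x variants
    missing = dosage < 0
    n_in = dosage.shape[1]

    miss_frac = missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(~missing, dosage, 0).sum(axis=0) / (2.0 * np.maximum((~missing).sum(axis=0), 1))
    maf = np.minimum(p, 1.0 - p)
    fail_missing = miss_frac > missing_max
    fail_maf = maf < maf_min
    keep = ~(fail_missing | fail_maf)
    n_missing_removed = int(fail_missing.sum())
    n_maf_removed = int(fail_maf.sum())
    log.info(
        "read_vcf: %d variants in; %d failed missing-rate > %g; %d failed MAF < %g; %d retained",
        n_in, n_missing_removed, missing_max, n_maf_removed, maf_min, int(keep.sum()),
    )
    if not keep.any():
        raise GrainmapError(
            f"no variants survive filtering ({n_in} in; {n_missing_removed} failed "
            f"missing-rate > {missing_max}; {n_maf_removed} failed MAF < {maf_min})"
        )

    dosage = dosage[:, keep]
    missing = missing[:, keep]
    variants = [v for v, k in zip(variants, keep) if k]

    # mode imputation of residual missing entries
    for j in np.nonzero(missing.any(axis=0))[0]:
        col = dosage[:, j]
        obs = col[~missing[:, j]]
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes smallest index on ties
        col[missing[:, j]] = mode
    dosage = dosage.astype(np.int8)

    return GenotypeMatrix(materials=materials, variants=variants, dosage=dosage, missing=missing)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT-only genotype fields.

    Entries flagged missing in ``geno.missing`` are emitted as ``./.`` so a
    read/write/read cycle round-trips the retained variants.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in sorted(geno.chrom_lengths().items()):
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.materials) + "\n")
        for j, v in enumerate(geno.variants):
            calls = []
            for i in range(geno.n_materials):
                if geno.missing is not None and geno.missing[i, j]:
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(geno.dosage[i, j])])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["material", "trait", "environment", "replicate", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the long-format phenotype TSV (material / trait / environment /
    replicate / value) with strict validation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GrainmapError(f"phenotype file {path} lacks columns {missing_cols}")
    df = df[PHENO_COLUMNS].copy()
    bad_traits = sorted(set(df["trait"]) - set(TRAITS))
    if bad_traits:
        raise GrainmapError(f"unknown trait labels {bad_traits}; allowed: {list(TRAITS)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        line = int(values.index[values.isna()][0]) + 2  # header is line 1
        raise GrainmapError(f"non-numeric phenotype value at line {line} of {path}")
    df["value"] = values.astype(float)
    if not np.isfinite(df["value"]).all():
        raise GrainmapError("phenotype values must be finite")
    if (df.loc[df["trait"] == "GLWR", "value"] <= 0).any():
        raise GrainmapError("GLWR values must be positive")
    dup = df.duplicated(subset=["material", "trait", "environment", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise GrainmapError(
            "duplicate phenotype record for "
            f"({row['material']}, {row['trait']}, {row['environment']}, rep {row['replicate']})"
        )
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)


def material_means(pheno: pd.DataFrame, trait: str, environment: str | None = None) -> pd.Series:
    """Per-material phenotype mean for one trait, within one environment or
    pooled across environments (replicates always averaged)."""
    sub = pheno[pheno["trait"] == trait]
    if environment is not None:
        sub = sub[sub["environment"] == environment]
    if environment is None:
        # mean of per-environment means, so unbalanced replication does not
        # weight environments unevenly
        env_means = sub.groupby(["material", "environment"])["value"].mean()
        return env_means.groupby("material").mean()
    return sub.groupby("material")["value"].mean()


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(gff_path, effects_path=None, promoter_bp: int = 2000) -> list[GeneModel]:
    """Read gene features from GFF3 and attach per-SNP consequence classes
    from the effects TSV (columns: variant_id, gene_id, consequence).

    Effects rows referencing absent genes are dropped with a warning;
    variants without an effects row default to class ``other``.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique")
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        note = feat.attributes.get("Note", [""])[0]
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=str(feat.seqid),
            strand=feat.strand if feat.strand in "+-" else "+",
            start=feat.start,
            end=feat.end,
            promoter_bp=promoter_bp,
            annotation=note,
        )
    if effects_path is not None:
        eff = pd.read_csv(effects_path, sep="\t", dtype=str)
        need = {"variant_id", "gene_id", "consequence"}
        if not need.issubset(eff.columns):
            raise GrainmapError(f"effects file must have columns {sorted(need)}")
        bad = sorted(set(eff["consequence"]) - set(CONSEQUENCE_CLASSES))
        if bad:
            raise GrainmapError(f"unknown consequence classes {bad}; allowed: {list(CONSEQUENCE_CLASSES)}")
        for _, row in eff.iterrows():
            gene = genes.get(row["gene_id"])
            if gene is None:
                log.warning("effects row for absent gene %s dropped (variant %s)", row["gene_id"], row["variant_id"])
                continue
            gene.snp_effects[row["variant_id"]] = row["consequence"]
    return list(genes.values())


def write_gene_models(genes: list[GeneModel], gff_path, effects_path=None) -> None:
    """Write gene models as GFF3 (and optionally their SNP effects TSV)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";Note={g.annotation}"
            fh.write(f"{g.chrom}\tgrainmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
    if effects_path is not None:
        rows = [
            {"variant_id": vid, "gene_id": g.gene_id, "consequence": cls}
            for g in genes
            for vid, cls in sorted(g.snp_effects.items())
        ]
        pd.DataFrame(rows, columns=["variant_id", "gene_id", "consequence"]).to_csv(
            effects_path, sep="\t", index=False
        )


def read_known_genes(path) -> pd.DataFrame:
    """Known-gene list TSV: gene_id, chrom, start, end, traits (';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    need = {"gene_id", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise GrainmapError(f"known-gene file must have columns {sorted(need)}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise GrainmapError("known-gene list has start > end")
    if "traits" not in df.columns:
        df["traits"] = ""
    return df


# ---------------------------------------------------------------------------
# Association / QTL tables
# ---------------------------------------------------------------------------

SCAN_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "trait", "environment",
    "effect", "se", "p", "pve_pct", "significant",
]


def write_scan_table(records, path) -> None:
    """Per trait x environment association scan as flat TSV."""
    rows = [
        {
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref, "alt": r.alt, "trait": r.trait, "environment": r.environment,
            "effect": r.effect, "se": r.se, "p": r.p, "pve_pct": r.pve_pct,
            "significant": int(r.is_significant),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scan_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GrainmapError(f"scan table {path} lacks columns {missing_cols}")
    return df


ASSOC_COLUMNS = [
    "QTL", "Env", "Trait", "CHRO", "Position", "Peak-SNP", "Ref-Alt",
    "Effect", "SE", "P", "PVE(%)",
]


def write_association_table(records, path, extra_columns: bool = False) -> None:
    """Write QTL detections in the published table layout.

    ``records`` is an iterable of objects/dicts with fields qtl, env, trait,
    chrom, start, end, peak_id, ref, alt, effect, se, p, pve_pct (and, when
    ``extra_columns`` is set, criteria/known_genes/members).  Effect and SE
    are printed to 3 decimals, PVE to 2.
    """
    rows = []
    for r in records:
        get = r.get if isinstance(r, dict) else lambda k, _r=r: getattr(_r, k)
        row = {
            "QTL": get("qtl"),
            "Env": get("env"),
            "Trait": get("trait"),
            "CHRO": get("chrom"),
            "Position": f"{int(get('start'))}-{int(get('end'))}",
            "Peak-SNP": get("peak_id"),
            "Ref-Alt": f"{get('ref')}/{get('alt')}",
            "Effect": f"{get('effect'):.3f}",
            "SE": f"{get('se'):.3f}",
            "P": f"{get('p'):.6g}",
            "PVE(%)": f"{get('pve_pct'):.2f}",
        }
        if extra_columns:
            row["Criteria"] = get("criteria")
            row["Cloned Gene"] = get("known_genes")
            row["Members"] = get("members")
        rows.append(row)
    cols = ASSOC_COLUMNS + (["Criteria", "Cloned Gene", "Members"] if extra_columns else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
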